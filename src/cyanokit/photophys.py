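"""Photophysiology calculators: rETR, P-I curve fitting, pools, kinetics, spectra.

Rapid light curves (RLCs) probe short-term PSII light response: at each
actinic irradiance step I (umol photons m^-2 s^-1) the effective PSII
quantum yield Phi_PSII is measured, and the relative electron transport
rate is rETR = Phi_PSII x I. The rETR-vs-I curve is fitted with the
three-parameter Eilers-Peeters photosynthesis-irradiance model

    P(I) = I / (a I^2 + b I + c),    a > 0, c > 0, b + 2 sqrt(a c) > 0,

which rises linearly at low light (initial slope s = 1/c), peaks at the
optimum intensity I_m = sqrt(c/a) with maximum photosynthesis
P_m = 1/(b + 2 sqrt(a c)), and declines beyond it (photoinhibition).
The characteristic (light-saturation onset) intensity is
I_k = c/(b + 2 sqrt(a c)) = P_m / s. These closed forms follow from the
model's calculus: P'(0) = 1/c and the maximum of P over I > 0 is attained
where a I^2 = c.

The module also provides:

* Beer-Lambert functional-pool estimation: a complex's concentration from
  its maximal differential absorbance, c = dA / (eps * l), with the
  study-standard extinction coefficients PSI 70, cytochrome b6f 18, and
  plastocyanin (PC) 4.7 mM^-1 cm^-1;
* half-time estimation of rereduction rises (threshold crossing of the
  baseline-to-plateau midpoint with linear interpolation) and conversion to
  a first-order rate, rate = ln 2 / t_half, one electron per complex per
  turnover;
* 77-K fluorescence emission preprocessing: 3-scan averaging, restriction
  to the 670-740 nm window, and, for 620-nm excitation only, subtraction of
  an exponential baseline trend fitted on the window flanks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from cyanokit.errors import DomainError, EstimationError, FitError

#: Default extinction coefficients, mM^-1 cm^-1, by complex.
EXTINCTION_COEFFICIENTS = {"PSI": 70.0, "b6f": 18.0, "PC": 4.7}

DEFAULT_PATH_LENGTH_CM = 1.0


# ---------------------------------------------------------------------------
# Light-response curves and the Eilers-Peeters fit


@dataclass
class LightResponseCurve:
    """Irradiance ladder with per-step PSII yield and/or rETR.

    irradiance : umol photons m^-2 s^-1, strictly increasing
    phi_psii   : effective PSII quantum yield per step, in [0, 1]
    retr       : relative electron transport rate per step (a.u.)
    fv_fm      : optional dark-adapted maximum quantum yield
    """

    irradiance: np.ndarray
    phi_psii: np.ndarray | None = None
    retr: np.ndarray | None = None
    fv_fm: float | None = None

    def __post_init__(self) -> None:
        self.irradiance = np.asarray(self.irradiance, dtype=float)
        if self.irradiance.ndim != 1 or self.irradiance.size == 0:
            raise DomainError("irradiance must be a non-empty 1-D array")
        if np.any(np.diff(self.irradiance) <= 0):
            raise DomainError("irradiance must be strictly increasing")
        for name in ("phi_psii", "retr"):
            value = getattr(self, name)
            if value is not None:
                value = np.asarray(value, dtype=float)
                if value.shape != self.irradiance.shape:
                    raise DomainError(
                        f"{name} length {value.size} does not match "
                        f"irradiance length {self.irradiance.size}"
                    )
                setattr(self, name, value)
        if self.phi_psii is not None and (
            np.any(self.phi_psii < 0) or np.any(self.phi_psii > 1)
        ):
            raise DomainError("phi_psii values must lie in [0, 1]")


def compute_retr(curve: LightResponseCurve) -> LightResponseCurve:
    """Fill rETR = Phi_PSII x I elementwise; returns a new curve."""
    if curve.phi_psii is None:
        raise DomainError("compute_retr requires phi_psii")
    return replace(curve, retr=curve.phi_psii * curve.irradiance)


def ep_model(irradiance, a: float, b: float, c: float):
    """Eilers-Peeters response P(I) = I / (a I^2 + b I + c)."""
    irradiance = np.asarray(irradiance, dtype=float)
    return irradiance / (a * irradiance**2 + b * irradiance + c)


@dataclass
class EilersPeetersResults:
    """Fitted Eilers-Peeters coefficients with derived photosynthetic parameters.

    Derived quantities (closed forms of the model):

    * ``s``   — initial slope (light-use efficiency, a.u.) = 1/c
    * ``p_m`` — maximum photosynthesis (a.u.) = 1/(b + 2 sqrt(a c))
    * ``i_m`` — optimum intensity (umol photons m^-2 s^-1) = sqrt(c/a)
    * ``i_k`` — characteristic intensity = c/(b + 2 sqrt(a c)) = p_m / s
    """

    a: float
    b: float
    c: float
    residual_ss: float
    nobs: int
    bse: dict[str, float] = field(default_factory=dict)
    model: "EilersPeetersModel | None" = None

    def __post_init__(self) -> None:
        if self.a <= 0 or self.c <= 0:
            raise FitError(
                "fitted coefficients left the admissible region (need a > 0, c > 0)",
                diagnostics={"a": self.a, "b": self.b, "c": self.c},
            )
        if self.b + 2.0 * math.sqrt(self.a * self.c) <= 0:
            raise FitError(
                "fitted coefficients violate b + 2 sqrt(a c) > 0",
                diagnostics={"a": self.a, "b": self.b, "c": self.c},
            )

    @property
    def s(self) -> float:
        return 1.0 / self.c

    @property
    def p_m(self) -> float:
        return 1.0 / (self.b + 2.0 * math.sqrt(self.a * self.c))

    @property
    def i_m(self) -> float:
        return math.sqrt(self.c / self.a)

    @property
    def i_k(self) -> float:
        return self.c / (self.b + 2.0 * math.sqrt(self.a * self.c))

    def predict(self, irradiance) -> np.ndarray:
        return ep_model(irradiance, self.a, self.b, self.c)

    def summary(self) -> str:
        lines = [
            "Eilers-Peeters photosynthesis-irradiance fit",
            "=" * 46,
            f"observations: {self.nobs}    residual SS: {self.residual_ss:.6g}",
            "",
            f"{'param':<6}{'estimate':>14}{'std err':>14}",
        ]
        for name in ("a", "b", "c"):
            se = self.bse.get(name)
            se_s = f"{se:>14.4g}" if se is not None and np.isfinite(se) else f"{'--':>14}"
            lines.append(f"{name:<6}{getattr(self, name):>14.6g}{se_s}")
        lines += [
            "",
            "derived parameters",
            f"  s   (initial slope, a.u.)          = {self.s:.6g}",
            f"  P_m (maximum photosynthesis, a.u.) = {self.p_m:.6g}",
            f"  I_m (optimum intensity)            = {self.i_m:.6g}",
            f"  I_k (characteristic intensity)     = {self.i_k:.6g}",
        ]
        return "\n".join(lines)


class EilersPeetersModel:
    """Nonlinear least-squares model for an rETR light-response curve.

    Usage mirrors the statsmodels Model/Results split::

        model = EilersPeetersModel(curve)       # or (irradiance, retr)
        res = model.fit()
        print(res.summary())

    The fit minimises sum_i (rETR_i - P(I_i))^2, unweighted, starting from
    data-driven initial values: the initial slope from the first two points,
    P_m from the curve maximum and I_m from its argmax, inverted through the
    closed forms to (a, b, c). Coefficients a and c are kept positive by
    bounds; the b + 2 sqrt(a c) > 0 condition is checked post-fit.
    """

    def __init__(self, curve_or_irradiance, retr=None):
        if isinstance(curve_or_irradiance, LightResponseCurve):
            curve = curve_or_irradiance
            if curve.retr is None:
                if curve.phi_psii is None:
                    raise DomainError("curve carries neither retr nor phi_psii")
                curve = compute_retr(curve)
            self.irradiance = curve.irradiance
            self.retr = curve.retr
        else:
            self.irradiance = np.asarray(curve_or_irradiance, dtype=float)
            self.retr = np.asarray(retr, dtype=float)
        if self.retr is None or self.retr.shape != self.irradiance.shape:
            raise DomainError("irradiance and retr must have equal length")
        if np.unique(self.irradiance).size < 4:
            raise DomainError("need at least 4 distinct irradiances to fit 3 parameters")

    def start_params(self) -> tuple[float, float, float]:
        I, P = self.irradiance, self.retr
        s0 = (P[1] - P[0]) / (I[1] - I[0]) if I[1] > I[0] else P[0] / I[0]
        if not np.isfinite(s0) or s0 <= 0:
            s0 = max(P.max() / I[P.argmax()], 1e-6) if P.max() > 0 else 1e-3
        pm0 = max(P.max(), 1e-9)
        im0 = max(I[P.argmax()], I[0])
        c0 = 1.0 / s0
        a0 = c0 / im0**2
        b0 = 1.0 / pm0 - 2.0 * math.sqrt(a0 * c0)
        return a0, b0, c0

    def fit(self, maxfev: int = 10000) -> EilersPeetersResults:
        a0, b0, c0 = self.start_params()
        tiny = 1e-300

        def residuals(theta):
            return ep_model(self.irradiance, *theta) - self.retr

        result = optimize.least_squares(
            residuals,
            x0=[a0, b0, c0],
            bounds=([tiny, -np.inf, tiny], [np.inf, np.inf, np.inf]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=maxfev,
        )
        if not result.success:
            raise FitError(
                f"Eilers-Peeters fit did not converge: {result.message}",
                diagnostics={"x": result.x.tolist(), "cost": float(result.cost)},
            )
        a, b, c = result.x
        rss = float(2.0 * result.cost)
        bse = self._standard_errors(result, rss)
        return EilersPeetersResults(
            a=float(a), b=float(b), c=float(c), residual_ss=rss,
            nobs=self.irradiance.size, bse=bse, model=self,
        )

    def _standard_errors(self, result, rss: float) -> dict[str, float]:
        n, p = self.irradiance.size, 3
        if n <= p:
            return {}
        J = result.jac
        try:
            cov = np.linalg.inv(J.T @ J) * (rss / (n - p))
        except np.linalg.LinAlgError:
            return {}
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        return {"a": float(se[0]), "b": float(se[1]), "c": float(se[2])}


def fit_ep(curve: LightResponseCurve) -> EilersPeetersResults:
    """Fit the Eilers-Peeters model to a light-response curve."""
    return EilersPeetersModel(curve).fit()


# ---------------------------------------------------------------------------
# Beer-Lambert functional pool concentrations


@dataclass(frozen=True)
class AbsorbanceDelta:
    """Maximal differential absorbance of one electron-transport complex.

    ``epsilon`` is the molar extinction coefficient in mM^-1 cm^-1 (defaults
    per complex: PSI 70, b6f 18, PC 4.7); ``path_length`` in cm.
    """

    complex_name: str
    delta_a: float
    epsilon: float | None = None
    path_length: float = DEFAULT_PATH_LENGTH_CM

    def resolved_epsilon(self) -> float:
        if self.epsilon is not None:
            return self.epsilon
        try:
            return EXTINCTION_COEFFICIENTS[self.complex_name]
        except KeyError:
            raise DomainError(
                f"no default extinction coefficient for complex "
                f"{self.complex_name!r}; supply epsilon explicitly"
            )


def pool_concentration(x: AbsorbanceDelta) -> float:
    """Concentration (nM) of a complex from its maximal differential absorbance.

    Beer-Lambert: c = dA / (eps * l). With eps in mM^-1 cm^-1 and l in cm
    the quotient is in mM; the result is returned in nM (x 1e6).
    """
    eps = x.resolved_epsilon()
    if eps <= 0:
        raise DomainError(f"extinction coefficient must be positive, got {eps}")
    if x.path_length <= 0:
        raise DomainError(f"path length must be positive, got {x.path_length}")
    if x.delta_a < 0:
        raise DomainError(f"differential absorbance must be >= 0, got {x.delta_a}")
    return 1e6 * x.delta_a / (eps * x.path_length)


# ---------------------------------------------------------------------------
# Rereduction kinetics


@dataclass(frozen=True)
class RereductionKinetics:
    """Half-time of a rereduction rise and the derived first-order rate."""

    half_time: float
    rate: float

    @classmethod
    def from_half_time(cls, half_time: float) -> "RereductionKinetics":
        return cls(half_time=half_time, rate=rate_from_halftime(half_time))


def estimate_halftime(
    time,
    signal,
    baseline_points: int = 3,
    plateau_fraction: float = 0.10,
    smooth_points: int | None = None,
) -> float:
    """Half-time of a rise: first crossing of the baseline-plateau midpoint.

    The baseline is the mean of the first ``baseline_points`` samples (the
    pre-rise level); the plateau the mean of the final ``plateau_fraction``
    of samples. The half-time is the first time the (optionally
    moving-average smoothed) signal crosses baseline + 0.5 (plateau -
    baseline) from below, with linear interpolation between the bracketing
    samples. Constant offsets cancel, so the estimate is
    translation-invariant.

    ``smooth_points`` defaults to ~1% of the trace length (minimum 1 = no
    smoothing), which suppresses premature threshold crossings on noisy
    traces without visibly biasing the crossing time.

    Raises :class:`EstimationError` when the trace has no resolvable rise or
    no plateau (still rising at the end).
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or t.size < 5:
        raise EstimationError("need matched 1-D time/signal arrays with >= 5 samples")
    if np.any(np.diff(t) <= 0):
        raise EstimationError("time values must be strictly increasing")
    n = t.size
    if smooth_points is None:
        smooth_points = max(1, n // 100)
    if smooth_points > 1:
        kernel = np.ones(smooth_points) / smooth_points
        y_s = np.convolve(y, kernel, mode="same")
        # edges of a 'same' convolution are damped; restore them from raw data
        half = smooth_points // 2
        y_s[:half] = y[:half]
        y_s[-half or None:] = y[-half or None:]
    else:
        y_s = y

    baseline = float(np.mean(y[: max(1, baseline_points)]))
    n_plateau = max(1, int(round(plateau_fraction * n)))
    plateau = float(np.mean(y[-n_plateau:]))
    amplitude = plateau - baseline
    spread = float(np.std(y[-n_plateau:]))
    if amplitude <= 0 or amplitude <= 2.0 * spread:
        raise EstimationError(
            "no resolvable rise above baseline",
            diagnostics={"baseline": baseline, "plateau": plateau, "amplitude": amplitude},
        )
    # plateau check: the final decile must not still be climbing appreciably;
    # a settled exponential's last two decile means differ by <1% of the rise,
    # a still-rising ramp's by ~10%, so 5% separates them cleanly
    prev = np.mean(y[-2 * n_plateau : -n_plateau]) if n >= 2 * n_plateau else baseline
    if (plateau - prev) > 0.05 * amplitude:
        raise EstimationError(
            "trace has not reached a plateau (still rising at the end)",
            diagnostics={"plateau": plateau, "previous_decile_mean": float(prev)},
        )
    threshold = baseline + 0.5 * amplitude
    above = y_s >= threshold
    crossings = np.nonzero(~above[:-1] & above[1:])[0]
    if above[0]:
        raise EstimationError("signal starts above the half-rise threshold")
    if crossings.size == 0:
        raise EstimationError("signal never crosses the half-rise threshold")
    i = int(crossings[0])
    y0, y1 = y_s[i], y_s[i + 1]
    frac = (threshold - y0) / (y1 - y0) if y1 != y0 else 0.0
    return float(t[i] + frac * (t[i + 1] - t[i]))


def rate_from_halftime(half_time: float) -> float:
    """First-order rereduction rate (e-/s): ln 2 / t_half.

    Convention: exponential recovery with one electron transferred per
    complex per turnover, so the rate constant k = ln 2 / t_half is reported
    directly as electrons per second per complex.
    """
    if half_time <= 0:
        raise DomainError(f"half-time must be positive, got {half_time}")
    return math.log(2.0) / half_time


# ---------------------------------------------------------------------------
# 77-K fluorescence emission spectra


@dataclass
class EmissionSpectrum:
    """A 77-K fluorescence emission spectrum (possibly multi-scan).

    ``intensity`` may be 1-D (single scan / already averaged) or 2-D with
    one row per scan on the common wavelength grid. ``excitation`` is the
    excitation wavelength in nm (435 targets chlorophyll, 620 the
    phycobilisome).
    """

    wavelength: np.ndarray
    intensity: np.ndarray
    excitation: float
    n_scans: int = 1

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.wavelength) <= 0):
            raise DomainError("wavelength grid must be strictly increasing")
        if self.intensity.shape[-1] != self.wavelength.size:
            raise DomainError("intensity grid does not match wavelength grid")


ANALYSIS_WINDOW_NM = (670.0, 740.0)
BASELINE_FLANKS_NM = ((670.0, 675.0), (735.0, 740.0))


def _exp_trend(lam, alpha, beta, gamma, lam0):
    return alpha * np.exp(beta * (lam - lam0)) + gamma


def preprocess_spectrum(
    spec: EmissionSpectrum,
    window: tuple[float, float] = ANALYSIS_WINDOW_NM,
    baseline_flanks: tuple[tuple[float, float], tuple[float, float]] = BASELINE_FLANKS_NM,
) -> EmissionSpectrum:
    """Average scans, restrict to 670-740 nm, and baseline-correct 620-nm spectra.

    Multi-scan intensities are averaged pointwise. The grid is then
    restricted to the analysis window (which it must cover). For 620-nm
    excitation only, an exponential trend y = alpha exp(beta (lam - lam_lo))
    + gamma is least-squares fitted to the window flanks (by default
    670-675 and 735-740 nm, clear of the emission peaks) and subtracted.
    Intensities are never normalised to the maximum, preserving magnitude
    differences between samples.
    """
    intensity = spec.intensity
    n_scans = spec.n_scans
    if intensity.ndim == 2:
        n_scans = intensity.shape[0]
        intensity = intensity.mean(axis=0)
    lo, hi = window
    if spec.wavelength[0] > lo or spec.wavelength[-1] < hi:
        raise DomainError(
            f"wavelength grid [{spec.wavelength[0]}, {spec.wavelength[-1]}] does "
            f"not cover the analysis window [{lo}, {hi}]"
        )
    mask = (spec.wavelength >= lo) & (spec.wavelength <= hi)
    lam = spec.wavelength[mask]
    y = intensity[mask]
    if int(round(spec.excitation)) == 620:
        y = y - _fit_baseline(lam, y, baseline_flanks)
    return EmissionSpectrum(
        wavelength=lam, intensity=y, excitation=spec.excitation, n_scans=n_scans
    )


def _fit_baseline(lam, y, flanks) -> np.ndarray:
    sel = np.zeros(lam.shape, dtype=bool)
    for lo, hi in flanks:
        sel |= (lam >= lo) & (lam <= hi)
    if sel.sum() < 4:
        raise EstimationError("too few flank samples to fit an exponential baseline")
    lam_f, y_f = lam[sel], y[sel]
    lam0 = lam_f[0]
    gamma0 = float(y_f.min())
    alpha0 = float(max(y_f[0] - gamma0, 1e-12))
    span = lam_f[-1] - lam_f[0]
    tail = max(float(y_f[-1] - gamma0), 1e-12)
    beta0 = math.log(tail / alpha0) / span if span > 0 else 0.0

    def residuals(theta):
        return _exp_trend(lam_f, *theta, lam0) - y_f

    result = optimize.least_squares(residuals, x0=[alpha0, beta0, gamma0], max_nfev=5000)
    if not result.success:
        raise EstimationError(
            "exponential baseline fit failed", diagnostics={"message": result.message}
        )
    return _exp_trend(lam, *result.x, lam0)
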
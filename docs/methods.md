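# Methods

This note records how each stage computes what it computes, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that shape edge-case behaviour.

## Genome descriptors and assembly-level similarity

Descriptors are computed case-insensitively over all contigs: total
length, contig count, GC% and per-base fractions. GC% and the base
fractions use unambiguous bases (A/C/G/T) as the denominator; every other
IUPAC code counts only toward `ambiguous_count`. This mirrors the k-mer
stage's stance of excluding ambiguity rather than diluting composition
with it, and makes the conservation identity Σ base counts +
ambiguous_count = total_length hold exactly.

Two scalar similarities compare assemblies:

* `size_similarity = 100 · min(L_a, L_b)/max(L_a, L_b)` — symmetric,
  100 iff equal lengths.
* `composition_similarity = 100 − mean_b |f_a(b) − f_b(b)|` over the four
  base fractions in percentage points. "Composition similarity" has no
  single canonical definition in comparative genomics; this mean-absolute-
  difference form was chosen because it is symmetric, bounded, equals 100
  exactly for identical compositions, and degrades linearly in the
  composition gap. Under symmetric A/T and G/C splits it reduces to
  100 − |GC_a − GC_b|/2.

GFF3 features are read with a deliberately small 9-column parser so that
malformed input is reported with its line number (wrong column count,
end < start, unknown strand). Gene naming precedence is `gene` > `Name` >
`locus_tag`; the product comes from `product`. Coordinates stay 1-based
inclusive throughout the package; conversion to Python string offsets
happens only inside sequence-slicing code.

## k-mer profiles and similarity

Profiles are built per contig with a stride-1 sliding window; windows
containing any non-A/C/G/T character are skipped entirely (no expansion of
ambiguity codes), windows never span contig joins, and only the forward
strand is profiled — no reverse-complement canonicalisation, since the
comparison is between assemblies in their deposited orientation.
Internally windows are 2-bit packed with numpy for speed (k ≤ 32), but the
public profile is a plain k-mer→count mapping.

Jaccard is computed on presence/absence; cosine on raw counts over the key
union (scale-invariant, so counts and relative frequencies agree). The
per-k report covers k = 3–6 by default and exposes the arithmetic means
across k for headline reporting; whether a published single value is a
mean over k or one representative k, both are recoverable from the per-k
table. At genome scale all 4^k ≤ 4096 words occur in both genomes, so
Jaccard saturates at 1 for k ≤ 6 — the discriminating metric there is the
cosine of the frequency vectors.

## Promoter windows and the Rre1 consensus survey

For a plus-strand gene the promoter window is [start−500, start−1]; for a
minus-strand gene [end+1, end+500] reverse-complemented, so the returned
sequence always reads 5′→3′ toward the translation start on the coding
strand. Windows are clipped at contig edges (`truncated`), never trimmed
at neighbouring genes (a fixed-width window is the surveyed object, not an
operon model), and windows shorter than the 7-base motif are flagged
unscannable. "Gene start" means the annotated coordinate start for +
genes and the coordinate end for − genes.

Scanning uses `re` with a lookahead wrapper so overlapping occurrences are
all reported, case-insensitively. Only the oriented promoter strand is
scanned by default — the consensus is not palindromic — with
`both_strands=True` available where a reverse-strand survey is wanted.
Hits carry the 1-based offset in the oriented window, the distance
upstream of the gene start (1 = immediately adjacent), the matched string,
and the forward-strand contig coordinate of the match's lowest-coordinate
base.

Functional categories are matched in a fixed order (photosynthesis →
respiration → TCA → HSP) by case-insensitive substring against gene name
and product; the first match wins, anything else is "uncategorized". The
shipped keyword lists reconstruct the gene families a heat-stress survey
targets (psa*/psb*/pet*/ferredoxin/plastocyanin; cox/cyd/quinol oxidase;
citrate synthase/icd/sdh/frd; clpB/groEL/groES/dnaJ/dnaK/hsp*), and are
plain data on `CategoryScheme`, editable per run. Generic words like
"cytochrome" are deliberately absent from the photosynthesis list so that
"cytochrome c oxidase" resolves to respiration.

On uniform random sequence the consensus matches a given position with
probability (1/4)⁵ · (1/2) = 1/2048; this analytic rate anchors the
chance-hit tests.

## Eilers–Peeters photosynthesis–irradiance fitting

rETR is Φ_PSII × I elementwise. The model P(I) = I/(aI² + bI + c) is
fitted by unweighted nonlinear least squares (`scipy.optimize.
least_squares`, trust-region reflective, tolerances 1e−14) with a > 0 and
c > 0 enforced by bounds and the admissibility condition b + 2√(ac) > 0
checked post-fit; violations raise a `FitError` carrying the optimiser's
diagnostics rather than returning a silent answer.

Initialisation is data-driven: s₀ from the slope of the first two points,
P_m₀ from the curve maximum, I_m₀ from the argmax irradiance, inverted
through the closed forms c₀ = 1/s₀, a₀ = c₀/I_m₀², b₀ = 1/P_m₀ − 2√(a₀c₀).
The derived parameters s = 1/c, P_m = 1/(b + 2√(ac)), I_m = √(c/a),
I_k = P_m/s follow from the model's calculus (dP/dI at 0; the stationary
point of P at aI² = c); the test suite re-derives them symbolically with
sympy. Standard errors come from the Gauss–Newton covariance
(JᵀJ)⁻¹ · RSS/(n−p). The fit is exposed statsmodels-style:
`EilersPeetersModel(curve).fit()` returns an `EilersPeetersResults` with
`params`, `bse`, `predict` and `summary()`.

Whether to fit rETR or quantum yield against irradiance is a genuine
choice; rETR is fitted here, matching how such curves are displayed and
parameterised (P_m in rETR units).

## Beer–Lambert pools, half-times, and rates

`pool_concentration` inverts Beer–Lambert: c = ΔA/(ε·l), ε in mM⁻¹ cm⁻¹
(defaults PSI 70, b₆f 18, PC 4.7), path length 1 cm by default, result in
nM. The round trip pool_concentration(c·ε·l) = c is exact to machine
precision.

`estimate_halftime` is a model-free midpoint-crossing estimator: baseline
= mean of the first 3 samples (the pre-rise level), plateau = mean of the
final 10%, half-time = first time the signal crosses baseline +
0.5·(plateau − baseline) from below, linearly interpolated between the
bracketing samples. A light moving average (~1% of the trace length)
suppresses premature threshold crossings on noisy traces; its bias on an
exponential is O(w²·y″) ≈ 10⁻⁴ of the amplitude at the defaults. Constant
offsets cancel (translation invariance). Degenerate traces are rejected
with diagnostics: no resolvable rise (amplitude within 2 SD of the
plateau noise) or no plateau (final decile mean exceeding the previous
decile's by >5% of the rise — a settled exponential gives <1%, a ramp
~10%).

`rate_from_halftime` fixes the conversion at k = ln 2 / t½, i.e. a
first-order recovery with one electron per complex per turnover. This is
a documented convention: the external dark-pulse method it stands behind
publishes no formula, and any per-turnover stoichiometry would only scale
the reported e⁻/s axis.

## 77-K spectrum preprocessing

Scans on a common wavelength grid are averaged pointwise, then restricted
to 670–740 nm (the edge regions carry a sloping baseline below 670 nm and
instrumental far-red artifacts above 740 nm). For 620-nm excitation only,
an exponential trend y = α·e^{β(λ−670)} + γ is least-squares fitted on the
window flanks (670–675 and 735–740 nm, clear of the PSII/PSI emission
peaks; widths configurable) and subtracted. The shifted-exponent
parameterisation keeps the fit numerically tame at λ ≈ 700. Intensities
are never normalised to the maximum, preserving magnitude differences
between samples.

## Comparative-Ct expression

Technical replicates are averaged within each biological replicate before
ΔCt = Ct_target − Ct_reference is formed per replicate; ΔΔCt subtracts the
calibrator condition's mean ΔCt and fold = 2^(−ΔΔCt) with amplification
efficiency fixed at 2 (no efficiency correction). SEM is propagated by the
delta method, sem_fold = fold · ln 2 · sem_ΔΔCt, with the two conditions'
replicate SEMs combined in quadrature; the calibrator's own row reports
fold 1 with a √2-inflated self-referenced spread. Because ΔCt is formed
within each sample, a global Ct shift of any sample (loading or efficiency
drift) cancels exactly — this invariance is tested.

## Synthetic data: what it emulates, and what it does not

All generators are seed-deterministic (`numpy.random.default_rng`) and
return machine-readable truth alongside the data.

**Genomes** are i.i.d. base samples at a target GC (default 42.09%, a
realistic *Microcystis* value); at megabase scale the realised GC
concentrates within ±0.5 points by binomial concentration. Genes are laid
out in disjoint blocks (window + gene + pad) with a configurable strand
mix, so promoter windows never overlap one another or a gene body and
every planted motif is attributable to exactly one gene;
names/products are drawn from the category vocabulary plus decoys so the
classifier has known labels. Plants substitute bases at fixed coordinates
(lengths never shift). When plants are present, the generator guarantees
that consensus matches inside promoter windows are *exactly* the planted
truth: pre-existing chance matches are disrupted by single-base edits
before planting, matches induced at plant junctions are disrupted
afterwards (never touching planted bases), and matches formed where
consistent overlapping plants compose are added to the ledger. With zero
plants the background is untouched so chance hits follow the analytic
1/2048 law. Not emulated: codon structure, dinucleotide bias, operons,
repeats, real intergenic architecture — so passing tests demonstrate
coordinate/strand/orientation correctness and recovery logic, not
performance on real genomic base composition.

**Light curves** sample P(I) on a 12-step ladder spanning 10–2400 µmol
photons m⁻² s⁻¹ with additive Gaussian noise; defaults (a, b, c) =
(1e−5, 0.005, 2.22) give s ≈ 0.45, P_m ≈ 69, I_m ≈ 471 — a realistic
mid-light-adapted cyanobacterial curve. Φ_PSII is back-computed as
rETR/I (clipped to [0, 1]). Noise is homoscedastic; real RLC noise grows
toward high light, which is not modelled.

**Rereduction traces** are A(1 − e^{−kt}) + noise with k = ln 2/t½,
sampled over ten half-times (default t½ = 20 ms, a realistic
soluble-carrier time scale; 2001 points). Real traces carry actinic
artefacts and drifting baselines that are not modelled beyond a constant
offset.

**Ct tables** encode Ct = base_ct − log₂(level) + noise with the reference
gene at constant level, three technical within three biological replicates
by default and σ = 0.2 cycles. Default true folds (petJ ≈ 3.71 up,
sdh ≈ 0.09 down, icdh ≈ 0.86, groES ≈ 0.84) are realistic heat-stress
responses: strong induction of the cytochrome c₆ carrier and strong TCA
repression. PCR inhibition, efficiency differences between amplicons and
plate effects are not modelled.

## Problem sizes

The test suite and acceptance script run at sizes chosen to exercise the
asymptotics without waste: 1-Mb genomes for saturation checks, ~2 Mb of
uniform sequence for the chance-hit law (expected ≈ 1000 hits, 4σ band),
50 planted fixtures of 60 kb × 10 genes, a 27-point (a, b, c) recovery
grid spanning two decades per coefficient, and 100–200-seed noise
ensembles for the estimator-bias medians. The whole suite completes in
well under a minute.

## Known limitations

* The alignment-derived similarity scores some genome comparisons also
  report (direct sequence similarity, composite similarity scores) are not
  alignment-free quantities and are out of scope; only the descriptor- and
  k-mer-based measures are implemented.
* The motif survey is presence/placement only — no positional weight
  matrices, motif discovery, or enrichment statistics.
* `estimate_halftime` assumes a single monotone rise to a plateau;
  multiphasic kinetics should be fitted with an explicit model instead.
* The ΔΔCt implementation fixes amplification efficiency at 2; tables from
  poorly validated primer pairs need an efficiency-corrected method.
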
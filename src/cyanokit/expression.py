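"""Relative transcript abundance by the comparative threshold-cycle method.

qPCR threshold cycles (Ct) are converted to fold changes with housekeeping
and calibrator normalisation (the ddCt scheme, amplification efficiency
fixed at 2):

    dCt   = Ct_target - Ct_reference          (per biological replicate)
    ddCt  = mean dCt(condition) - mean dCt(calibrator condition)
    fold  = 2^(-ddCt)

The reference (housekeeping) gene defaults to phosphoenolpyruvate
carboxylase (*ppc*). Technical replicates, when present, are averaged
within each biological replicate before dCt is formed. The SEM of the fold
change is propagated by the delta method: sem_fold = fold x ln 2 x
sem_ddCt, with sem_ddCt combining the replicate spreads of the two
conditions in quadrature. Because dCt is formed within each sample, a
global Ct shift of a sample (loading or efficiency drift) cancels exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cyanokit.errors import CyanokitError, DomainError

DEFAULT_REFERENCE_GENE = "ppc"

REQUIRED_COLUMNS = ("strain", "condition", "gene", "replicate", "ct")


@dataclass
class CtTable:
    """Long-format Ct records with the normalisation scheme attached.

    ``data`` columns: strain, condition, gene, replicate (biological),
    optional tech_rep, ct. ``reference_gene`` must be present for every
    (strain, condition, replicate); ``calibrator_condition`` for every
    (strain, gene).
    """

    data: pd.DataFrame
    reference_gene: str = DEFAULT_REFERENCE_GENE
    calibrator_condition: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise DomainError(f"Ct table lacks required columns: {', '.join(missing)}")
        if (self.data["ct"] <= 0).any():
            raise DomainError("all Ct values must be positive")
        if not self.calibrator_condition:
            raise DomainError("a calibrator condition must be named")
        if self.reference_gene not in set(self.data["gene"]):
            raise CyanokitError(
                f"reference gene {self.reference_gene!r} absent from the table"
            )
        if self.calibrator_condition not in set(self.data["condition"]):
            raise CyanokitError(
                f"calibrator condition {self.calibrator_condition!r} absent from the table"
            )


@dataclass(frozen=True)
class FoldChange:
    """Relative expression of one gene in one strain and condition."""

    gene: str
    strain: str
    condition: str
    delta_ct: float
    delta_delta_ct: float
    fold: float
    sem: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise DomainError("fold change must be positive")


def _collapse_technical(data: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates within each biological replicate."""
    keys = ["strain", "condition", "gene", "replicate"]
    return data.groupby(keys, as_index=False)["ct"].mean()


def relative_expression(table: CtTable) -> list[FoldChange]:
    """Compute 2^(-ddCt) fold changes for every (strain, gene, condition).

    The calibrator condition is included in the output with fold = 1 by
    construction (ddCt referenced to itself). Raises a structural error
    naming the gap when the reference gene or calibrator condition is
    missing for some cell.
    """
    collapsed = _collapse_technical(table.data)
    ref = collapsed[collapsed["gene"] == table.reference_gene].set_index(
        ["strain", "condition", "replicate"]
    )["ct"]

    results: list[FoldChange] = []
    targets = collapsed[collapsed["gene"] != table.reference_gene]
    for (strain, gene), block in targets.groupby(["strain", "gene"], sort=True):
        dct_by_condition: dict[str, np.ndarray] = {}
        for condition, sub in block.groupby("condition", sort=True):
            dcts = []
            for _, row in sub.iterrows():
                key = (strain, condition, row["replicate"])
                if key not in ref.index:
                    raise CyanokitError(
                        f"reference gene {table.reference_gene!r} missing for "
                        f"strain {strain!r}, condition {condition!r}, "
                        f"replicate {row['replicate']!r}"
                    )
                dcts.append(row["ct"] - float(ref.loc[key]))
            dct_by_condition[condition] = np.asarray(dcts, dtype=float)
        if table.calibrator_condition not in dct_by_condition:
            raise CyanokitError(
                f"calibrator condition {table.calibrator_condition!r} missing for "
                f"gene {gene!r} in strain {strain!r}"
            )
        cal = dct_by_condition[table.calibrator_condition]
        cal_mean = float(cal.mean())
        cal_sem = _sem(cal)
        for condition, dcts in sorted(dct_by_condition.items()):
            mean_dct = float(dcts.mean())
            ddct = mean_dct - cal_mean
            if condition == table.calibrator_condition:
                sem_ddct = math.sqrt(2.0) * cal_sem  # self-referenced spread
            else:
                sem_ddct = math.hypot(_sem(dcts), cal_sem)
            fold = 2.0 ** (-ddct)
            results.append(
                FoldChange(
                    gene=gene,
                    strain=strain,
                    condition=condition,
                    delta_ct=mean_dct,
                    delta_delta_ct=ddct,
                    fold=fold,
                    sem=fold * math.log(2.0) * sem_ddct,
                )
            )
    return results


def _sem(values: np.ndarray) -> float:
    if values.size <= 1:
        return 0.0
    return float(values.std(ddof=1) / math.sqrt(values.size))


def fold_change_table(folds: list[FoldChange]) -> pd.DataFrame:
    """Tabulate fold changes (gene x strain x condition) for TSV export."""
    return pd.DataFrame(
        [
            {
                "gene": f.gene,
                "strain": f.strain,
                "condition": f.condition,
                "delta_ct": f.delta_ct,
                "delta_delta_ct": f.delta_delta_ct,
                "fold": f.fold,
                "sem": f.sem,
            }
            for f in folds
        ],
        columns=["gene", "strain", "condition", "delta_ct", "delta_delta_ct", "fold", "sem"],
    )
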
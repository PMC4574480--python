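"""Genotype-expression correlation and relative qPCR quantification.

``eqtl_correlation`` is the standard per-SNP Pearson correlation of allele
dosage against expression, with the two-sided p from the t transform on
n-2 degrees of freedom. ``ddct_fold_change`` implements the Livak
2^(-ddCt) method: each replicate's target Ct is normalized to the
housekeeping reference, condition means of the resulting dCt are
differenced, and the fold change is 2 to the minus that difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EqtlResult:
    snp_id: str
    gene_id: str
    r: float
    p: float
    n: int


def eqtl_correlation(
    dosage, expression, snp_id: str = "", gene_id: str = ""
) -> EqtlResult:
    """Pearson correlation of allele dosage with expression.

    Missing dosages (NaN) are dropped pairwise; needs >= 3 complete pairs
    and non-constant inputs.
    """
    dosage = np.asarray(dosage, dtype=float)
    expression = np.asarray(expression, dtype=float)
    if dosage.shape != expression.shape:
        raise ValueError("dosage and expression must have equal length")
    keep = ~(np.isnan(dosage) | np.isnan(expression))
    d, e = dosage[keep], expression[keep]
    if d.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(d) == 0 or np.ptp(e) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(d, e)
    return EqtlResult(snp_id, gene_id, float(r), float(p), int(d.size))


_QPCR_COLS = {"gene_id", "condition", "ct_target", "ct_reference"}


def ddct_fold_change(table: pd.DataFrame, control_label: str = "control") -> pd.DataFrame:
    """Per-gene 2^(-ddCt) fold change of each non-control condition.

    dCt = ct_target - ct_reference per replicate; ddCt = mean dCt(treated)
    - mean dCt(control); fold = 2^(-ddCt). Per-replicate folds (each
    treated replicate against the control mean dCt) give the SEM across
    independent experiments.
    """
    if not _QPCR_COLS.issubset(table.columns):
        raise ValueError(f"qPCR table must have columns {sorted(_QPCR_COLS)}")
    if not np.isfinite(table[["ct_target", "ct_reference"]].to_numpy()).all():
        raise ValueError("non-finite Ct values")
    table = table.copy()
    table["dct"] = table["ct_target"] - table["ct_reference"]
    rows = []
    for gene, sub in table.groupby("gene_id", sort=True):
        conditions = set(sub["condition"])
        if control_label not in conditions:
            raise ValueError(f"{gene}: missing condition {control_label!r}")
        ctrl_dct = sub.loc[sub["condition"] == control_label, "dct"]
        for cond in sorted(conditions - {control_label}):
            treated_dct = sub.loc[sub["condition"] == cond, "dct"]
            ddct = treated_dct.mean() - ctrl_dct.mean()
            folds = 2.0 ** (-(treated_dct - ctrl_dct.mean()))
            n = len(folds)
            sem = folds.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
            rows.append(
                {
                    "gene_id": gene,
                    "condition": cond,
                    "ddct": float(ddct),
                    "fold_change": float(2.0 ** (-ddct)),
                    "fold_sem": float(sem) if np.isfinite(sem) else np.nan,
                    "n_replicates": n,
                }
            )
        if conditions == {control_label}:
            raise ValueError(f"{gene}: no non-control condition")
    return pd.DataFrame(rows)
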
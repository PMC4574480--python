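"""Group statistics on larval phenotype measurement tables.

One row per larva with its biliary-epithelial-cell (BEC) cluster sizes,
filopodia/preductule length measurements, total and EdU-positive BEC
counts, and categorical severity / dye-accumulation scores. The summaries
here are the ones figure panels report: per-cell cluster-class percentages,
mean +/- SEM lengths, categorical scoring tabulations, proliferation
fractions, and the equal-variance unpaired two-tailed t-test at alpha 0.05.
"""

from __future__ import annotations


import numpy as np
import pandas as pd
from scipy import stats

CLUSTER_CLASSES = ("single", "doublet", "triplet", "4_or_more")
SCHEMES = {
    "severity": ("normal", "intermediate", "severe"),
    "ped6": ("absent", "small_faint", "normal"),
}


def _group_rows(table: pd.DataFrame, group: str) -> pd.DataFrame:
    sub = table[table["group"] == group]
    if sub.empty:
        raise ValueError(f"no larvae in group {group!r}")
    return sub


def cluster_class_proportions(
    table: pd.DataFrame, group: str, per_larva: bool = False
) -> pd.Series:
    """Percentage of BECs found as singles, doublets, triplets, or >=4 clusters.

    Percentages are per cell (a cluster of 5 contributes 5 cells to the
    ">=4" class), pooled across all larvae of the group. ``per_larva=True``
    instead averages each larva's own percentage vector, weighting larvae
    equally regardless of cell count.
    """
    sub = _group_rows(table, group)

    def vector(sizes) -> np.ndarray:
        sizes = np.asarray(list(sizes), dtype=int)
        if (sizes < 1).any():
            raise ValueError("cluster sizes must be >= 1")
        cells = np.array(
            [
                sizes[sizes == 1].sum(),
                sizes[sizes == 2].sum(),
                sizes[sizes == 3].sum(),
                sizes[sizes >= 4].sum(),
            ],
            dtype=float,
        )
        return cells

    if per_larva:
        mats = []
        for sizes in sub["cluster_sizes"]:
            cells = vector(sizes)
            mats.append(100.0 * cells / cells.sum())
        pct = np.mean(mats, axis=0)
    else:
        cells = np.sum([vector(s) for s in sub["cluster_sizes"]], axis=0)
        pct = 100.0 * cells / cells.sum()
    return pd.Series(pct, index=CLUSTER_CLASSES)


def length_summary(table: pd.DataFrame, group: str) -> tuple[float, float, int]:
    """Mean, SEM (sd/sqrt(n), n-1 denominator), and n of pooled lengths."""
    sub = _group_rows(table, group)
    values = np.concatenate([np.asarray(v, dtype=float) for v in sub["lengths_um"]])
    n = values.size
    if n < 2:
        raise ValueError("SEM undefined for fewer than 2 measurements")
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(n)), int(n)


def ttest_unpaired(group_a, group_b, alpha: float = 0.05):
    """Equal-variance unpaired two-tailed t-test.

    Returns (t, df, p, significant-at-alpha). The statistic uses the pooled
    variance with df = n_a + n_b - 2; zero pooled variance is an error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled == 0:
        raise ValueError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(pooled * (1.0 / a.size + 1.0 / b.size))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p), bool(p < alpha)


def category_proportions(table: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Per-group percentages for a categorical scoring scheme, with n.

    ``scheme`` is a column name ("severity" or "ped6"); categories follow
    the scheme's fixed order and every larva must carry a known label.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    levels = SCHEMES[scheme]
    unknown = set(table[scheme]) - set(levels)
    if unknown:
        raise ValueError(f"unknown {scheme} label(s): {sorted(unknown)}")
    rows = []
    for group, sub in table.groupby("group", sort=True):
        n = len(sub)
        counts = sub[scheme].value_counts()
        row = {"group": group, "n": n}
        for level in levels:
            row[level] = 100.0 * counts.get(level, 0) / n
        rows.append(row)
    return pd.DataFrame(rows)


def edu_fraction(table: pd.DataFrame, group: str) -> tuple[float, float, pd.Series]:
    """Percentage of EdU-positive BECs per larva; group mean +/- SEM.

    Returns (mean_pct, sem_pct, per-larva percentages indexed by larva_id).
    """
    sub = _group_rows(table, group)
    if (sub["bec_total"] <= 0).any():
        raise ValueError("bec_total must be positive for every larva")
    if (sub["edu_positive"] > sub["bec_total"]).any():
        raise ValueError("edu_positive exceeds bec_total")
    pct = 100.0 * sub["edu_positive"] / sub["bec_total"]
    pct.index = sub["larva_id"]
    n = len(pct)
    sem = float(pct.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return float(pct.mean()), sem, pct
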
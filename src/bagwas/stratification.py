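"""Population-stratification PCA and rectangular sample gating.

Genotypes are standardized the Eigenstrat way — centered by twice the panel
allele frequency and scaled by sqrt(p(1-p)) — before a singular value
decomposition. Missing dosages are mean-imputed per SNP; monomorphic SNPs
carry no ancestry information and are dropped. Samples are then carried
forward through a closed rectangular gate on a chosen component pair,
mirroring how co-clustered cases and controls are selected by eye on a
PC1/PC2 plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, SampleRecord


@dataclass
class PcaResult:
    component_scores: np.ndarray  # (n_samples, k)
    explained_variance: np.ndarray  # (k,) proportions of total variance
    loadings: np.ndarray  # (n_snps_used, k)
    snp_ids: list[str]  # SNPs that entered the decomposition

    @property
    def k(self) -> int:
        return self.component_scores.shape[1]


@dataclass
class GateSpec:
    """Closed rectangle on a pair of components (1-based indices)."""

    comp_x: int = 1
    comp_y: int = 2
    x_min: float = -np.inf
    x_max: float = np.inf
    y_min: float = -np.inf
    y_max: float = np.inf

    def __post_init__(self) -> None:
        if not (self.x_min <= self.x_max and self.y_min <= self.y_max):
            raise ValueError("gate bounds must satisfy min <= max on both axes")


def standardize_genotypes(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigenstrat-standardized genotype matrix and the kept-SNP index.

    Missing entries are imputed with the per-SNP mean dosage; columns are
    centered by 2*p_hat and scaled by sqrt(p_hat*(1-p_hat)) where p_hat is
    the panel frequency of the counted allele. Monomorphic columns
    (p_hat in {0, 1} or no calls) are excluded.
    """
    dos = matrix.dosage.copy()
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(dos, axis=0)
    p_hat = mean / 2.0
    keep = np.isfinite(p_hat) & (p_hat > 0.0) & (p_hat < 1.0)
    if not keep.any():
        raise ValueError("all SNPs are monomorphic; PCA undefined")
    dos = dos[:, keep]
    mean = mean[keep]
    p = p_hat[keep]
    nan_mask = np.isnan(dos)
    if nan_mask.any():
        dos[nan_mask] = np.broadcast_to(mean, dos.shape)[nan_mask]
    x = (dos - 2.0 * p) / np.sqrt(p * (1.0 - p))
    return x, np.flatnonzero(keep)


def pca_genotypes(matrix: GenotypeMatrix, k: int = 2) -> PcaResult:
    """Principal components of the standardized genotype matrix.

    Scores are U*S from the SVD of the standardized matrix; explained
    variance proportions come from the squared singular values. The sign of
    each component is fixed by making its largest-magnitude SNP loading
    positive, so results do not depend on the SVD implementation.
    """
    if matrix.n_samples < 2 or matrix.n_snps < 2:
        raise ValueError("PCA needs at least 2 samples and 2 SNPs")
    x, kept = standardize_genotypes(matrix)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    u, s, vt = u[:, :k], s[:k], vt[:k]
    for i in range(k):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    total = (x ** 2).sum()
    explained = s ** 2 / total
    return PcaResult(
        component_scores=u * s,
        explained_variance=explained,
        loadings=vt.T,
        snp_ids=[matrix.snps[j].snp_id for j in kept],
    )


def scores_frame(matrix: GenotypeMatrix, pca: PcaResult) -> pd.DataFrame:
    df = pd.DataFrame(
        pca.component_scores,
        columns=[f"PC{i + 1}" for i in range(pca.k)],
    )
    df.insert(0, "sample_id", [s.sample_id for s in matrix.samples])
    df["status"] = [s.status for s in matrix.samples]
    df["cohort"] = [s.cohort_label for s in matrix.samples]
    return df


def gate_samples(
    matrix: GenotypeMatrix, pca: PcaResult, gate: GateSpec
) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Samples inside the closed gate rectangle, plus a retention report.

    The report counts retained/total per (status, cohort). An empty gate is
    a warning, not an error, so exploratory bounds can be iterated.
    """
    if max(gate.comp_x, gate.comp_y) > pca.k:
        raise ValueError("gate references a component beyond those computed")
    x = pca.component_scores[:, gate.comp_x - 1]
    y = pca.component_scores[:, gate.comp_y - 1]
    inside = (x >= gate.x_min) & (x <= gate.x_max) & (y >= gate.y_min) & (y <= gate.y_max)
    retained = [s for s, keep in zip(matrix.samples, inside) if keep]
    if not retained:
        warnings.warn("gate retained no samples", stacklevel=2)
    rows = []
    df = pd.DataFrame(
        {
            "status": [s.status for s in matrix.samples],
            "cohort": [s.cohort_label for s in matrix.samples],
            "retained": inside,
        }
    )
    report = (
        df.groupby(["status", "cohort"], sort=True)
        .agg(total=("retained", "size"), retained=("retained", "sum"))
        .reset_index()
    )
    return retained, report
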
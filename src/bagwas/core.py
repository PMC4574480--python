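"""Core domain containers shared across the pipeline stages.

Coordinate conventions: SNP positions are 1-based (as in ``.map`` files);
gene intervals are 0-based half-open (as in BED). Conversions happen only
at I/O and mapping boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

VALID_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpRecord:
    """A genotyped marker. ``allele_a1`` is the counted (panel-minor) allele."""

    snp_id: str
    chrom: str
    pos_bp: int  # 1-based
    allele_a1: str
    allele_a2: str

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"{self.snp_id}: pos_bp must be >= 1, got {self.pos_bp}")
        if self.allele_a1 == self.allele_a2:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        for a in (self.allele_a1, self.allele_a2):
            if a not in VALID_ALLELES:
                raise ValueError(f"{self.snp_id}: invalid allele {a!r}")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    status: str  # "case" | "control"
    cohort_label: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValueError(f"status must be 'case' or 'control', got {self.status!r}")


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: require start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InteractionEdge:
    """A scored, sourced interaction between two genes.

    ``tf`` edges are directed regulator -> target; other sources undirected.
    """

    gene_a: str
    gene_b: str
    source: str  # ppi_a | ppi_scored | tf | pathway
    score: float | None = None
    directed: bool = False

    def __post_init__(self) -> None:
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"edge {self.gene_a}-{self.gene_b}: score {self.score} outside [0, 1]")


class GenotypeMatrix:
    """Samples x SNPs allele-dosage matrix with missingness.

    Dosages count copies of each SNP's ``allele_a1`` and live in {0, 1, 2};
    missing entries are NaN. Rows follow ``samples``, columns ``snps``.
    """

    def __init__(
        self,
        samples: Sequence[SampleRecord],
        snps: Sequence[SnpRecord],
        dosage: np.ndarray,
    ) -> None:
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(samples), len(snps)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match {len(samples)} samples x {len(snps)} SNPs"
            )
        valid = np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosage values must be in {0, 1, 2} or NaN")
        ids = [s.snp_id for s in snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids")
        sids = [s.sample_id for s in samples]
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate sample ids")
        self.samples = list(samples)
        self.snps = list(snps)
        self.dosage = dosage

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([s.status == "case" for s in self.samples])

    def call_rate(self) -> np.ndarray:
        """Per-SNP fraction of non-missing genotypes."""
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Per-SNP frequency of allele_a1 over non-missing alleles.

        SNPs with no called genotypes get NaN.
        """
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency (min of f and 1-f)."""
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.samples, [self.snps[i] for i in index], self.dosage[:, index]
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            [self.samples[i] for i in index], self.snps, self.dosage[index, :]
        )

    def snp_index(self, snp_id: str) -> int:
        for i, s in enumerate(self.snps):
            if s.snp_id == snp_id:
                return i
        raise KeyError(snp_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.snps == other.snps
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )
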
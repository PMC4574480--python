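"""Synthetic inputs for every pipeline stage.

The genotype simulator emulates a two-center case-control panel: a planted
pair of risk SNPs in perfect LD with case/control minor-allele frequencies
fixed by the study conditions, a background of null SNPs drawn under a
Balding-Nichols population-structure model, and missing-completely-at-random
genotypes. Companion generators produce gene annotations (with one gene
placed a fixed distance upstream of the risk pair), multi-source interaction
networks with a planted module, and phenotype / qPCR / expression tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, GenotypeMatrix, InteractionEdge, SampleRecord, SnpRecord

_ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic case-control genotype panel.

    Defaults are the study conditions: 63 cases vs 1907 controls, planted
    risk-pair minor-allele frequencies 0.2857 (cases) and 0.1308 (controls),
    pair separation 2971 bp anchored at position 49442285.
    """

    seed: int = 0
    n_cases: int = 63
    n_controls: int = 1907
    n_null_snps: int = 5000
    risk_maf_case: float = 0.2857
    risk_maf_control: float = 0.1308
    ld_pair_distance_bp: int = 2971
    fst: float = 0.0
    pop_fractions: tuple[float, ...] = (1.0,)
    missing_rate: float = 0.0
    chrom_length_bp: int = 130_000_000
    n_chromosomes: int = 22
    risk_pos_bp: int = 49_442_285
    plant_risk_pair: bool = True
    chrom: str = "14"

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if self.n_null_snps < 0:
            raise ValueError("n_null_snps must be non-negative")
        for name in ("risk_maf_case", "risk_maf_control"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.5):
                raise ValueError(f"{name} must lie in [0, 0.5], got {v}")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must lie in [0, 1)")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")
        if abs(sum(self.pop_fractions) - 1.0) > 1e-9:
            raise ValueError("pop_fractions must sum to 1")
        if self.ld_pair_distance_bp <= 0 or self.chrom_length_bp <= 0:
            raise ValueError("distances must be positive")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.chrom not in {str(c + 1) for c in range(self.n_chromosomes)}:
            raise ValueError("risk chromosome must be one of the simulated chromosomes")
        if self.plant_risk_pair and (
            self.risk_pos_bp + self.ld_pair_distance_bp > self.chrom_length_bp
        ):
            raise ValueError("risk pair does not fit on the chromosome")


class SimulatedPanel(NamedTuple):
    matrix: GenotypeMatrix
    risk_snp_ids: tuple[str, ...]
    populations: np.ndarray  # per-sample subpopulation index


def _orient_to_panel_minor(dosage: np.ndarray, snps: list[SnpRecord]) -> tuple[np.ndarray, list[SnpRecord]]:
    """Flip each SNP so allele_a1 is the panel minor allele.

    Ties at frequency 0.5 orient a1 to the lexicographically smaller allele,
    matching the reader's convention so that write/read round-trips.
    """
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosage, axis=0) / 2.0
    out_snps = []
    for j, snp in enumerate(snps):
        f = freq[j]
        flip = (f > 0.5) if not np.isnan(f) else False
        if not np.isnan(f) and f == 0.5 and snp.allele_a2 < snp.allele_a1:
            flip = True
        if flip:
            dosage[:, j] = 2.0 - dosage[:, j]
            snp = SnpRecord(snp.snp_id, snp.chrom, snp.pos_bp, snp.allele_a2, snp.allele_a1)
        out_snps.append(snp)
    return dosage, out_snps


def simulate_genotypes(config: SimulationConfig) -> SimulatedPanel:
    """Draw a structured case-control genotype panel.

    Null SNPs: ancestral frequency ~ U[0.05, 0.5]; each subpopulation's
    frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) (Balding-Nichols; F = fst,
    F = 0 keeps the ancestral frequency); genotypes Binomial(2, p) within
    subpopulation (Hardy-Weinberg). The planted risk pair is drawn on
    haplotypes carrying the minor allele at BOTH SNPs with the case- or
    control-specific frequency, so the two dosage columns are identical
    (perfect LD) before missingness.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    status = np.array(["case"] * config.n_cases + ["control"] * config.n_controls)
    cohort = np.where(status == "case", "CHP", "CTRL")

    n_pops = len(config.pop_fractions)
    pops = rng.choice(n_pops, size=n, p=np.asarray(config.pop_fractions))

    m = config.n_null_snps
    anc = rng.uniform(0.05, 0.5, size=m)
    if config.fst > 0.0:
        a = anc * (1.0 - config.fst) / config.fst
        b = (1.0 - anc) * (1.0 - config.fst) / config.fst
        pop_freq = rng.beta(a, b, size=(n_pops, m))
    else:
        pop_freq = np.tile(anc, (n_pops, 1))
    dosage = rng.binomial(2, pop_freq[pops, :]).astype(float)

    # unique (chrom, pos) for null SNPs spread over a 22-chromosome genome
    # equivalent, leaving the risk-pair positions free
    reserved = {
        (config.chrom, config.risk_pos_bp),
        (config.chrom, config.risk_pos_bp + config.ld_pair_distance_bp),
    }
    loci: list[tuple[str, int]] = []
    seen = set(reserved)
    while len(loci) < m:
        need = m - len(loci)
        chroms = rng.integers(1, config.n_chromosomes + 1, size=need)
        draw = rng.integers(1, config.chrom_length_bp + 1, size=need)
        for c, p in zip(chroms, draw):
            key = (str(int(c)), int(p))
            if key not in seen:
                seen.add(key)
                loci.append(key)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    snps = [
        SnpRecord(f"null{i:06d}", loci[i][0], loci[i][1], *_ALLELE_PAIRS[pair_idx[i]])
        for i in range(m)
    ]

    risk_ids: tuple[str, ...] = ()
    if config.plant_risk_pair:
        # plant the configured allele frequencies exactly: the count of
        # minor haplotypes per cohort is fixed at round(2n * maf) and
        # assigned by random permutation (random mating), so each cohort's
        # sample frequency equals its configured value
        risk_dosage = np.zeros(n)
        for mask, maf in (
            (status == "case", config.risk_maf_case),
            (status == "control", config.risk_maf_control),
        ):
            n_hap = 2 * int(mask.sum())
            hap = np.zeros(n_hap, dtype=float)
            hap[: int(np.floor(n_hap * maf + 0.5))] = 1.0
            rng.shuffle(hap)
            risk_dosage[mask] = hap.reshape(-1, 2).sum(axis=1)
        dosage = np.column_stack([dosage, risk_dosage, risk_dosage.copy()])
        snps = snps + [
            SnpRecord("risk_a", config.chrom, config.risk_pos_bp, "A", "G"),
            SnpRecord(
                "risk_b",
                config.chrom,
                config.risk_pos_bp + config.ld_pair_distance_bp,
                "C",
                "T",
            ),
        ]
        risk_ids = ("risk_a", "risk_b")

    if config.missing_rate > 0.0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    dosage, snps = _orient_to_panel_minor(dosage, snps)
    order = np.lexsort(([s.pos_bp for s in snps], [int(s.chrom) for s in snps]))
    snps = [snps[i] for i in order]
    dosage = dosage[:, order]

    samples = [
        SampleRecord(f"S{i:05d}", status[i], cohort[i]) for i in range(n)
    ]
    return SimulatedPanel(GenotypeMatrix(samples, snps, dosage), risk_ids, pops)


PLANTED_GENE_ID = "ARF6"
PLANTED_GENE_DISTANCE_BP = 8763  # risk SNP sits this far 3' of the planted gene


def simulate_gene_annotation(
    config: SimulationConfig, n_genes: int = 10, gene_length_bp: tuple[int, int] = (2_000, 50_000)
) -> list[GeneModel]:
    """Random gene intervals on the simulated chromosome.

    Includes one planted gene whose downstream boundary lies exactly
    ``PLANTED_GENE_DISTANCE_BP`` upstream of the risk pair, mirroring the
    candidate-gene geometry the mapping stage is meant to recover.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    rng = np.random.default_rng(config.seed + 1)
    genes: list[GeneModel] = []
    if n_genes == 0:
        return genes
    # planted gene: inclusive last base at risk_pos0 - 8763 (0-based half-open end)
    pos0 = config.risk_pos_bp - 1
    end = pos0 - PLANTED_GENE_DISTANCE_BP + 1
    length = int(rng.integers(*gene_length_bp))
    start = max(0, end - length)
    genes.append(GeneModel(PLANTED_GENE_ID, config.chrom, start, end, "+"))
    for i in range(n_genes - 1):
        length = int(rng.integers(*gene_length_bp))
        start = int(rng.integers(0, max(1, config.chrom_length_bp - length)))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"G{i:04d}", config.chrom, start, start + length, strand))
    return genes


@dataclass
class NetworkSimSpec:
    """Parameters of the synthetic multi-source interaction network."""

    n_genes: int = 200
    background_edge_prob: float = 0.02
    planted_module_size: int = 20
    planted_seed_fraction: float = 0.3
    score_distribution_bounds: tuple[float, float] = (0.5, 1.0)

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.planted_module_size > self.n_genes:
            raise ValueError("planted_module_size exceeds n_genes")
        if not (0.0 <= self.background_edge_prob <= 1.0):
            raise ValueError("background_edge_prob must lie in [0, 1]")
        if not (0.0 < self.planted_seed_fraction <= 1.0):
            raise ValueError("planted_seed_fraction must lie in (0, 1]")
        lo, hi = self.score_distribution_bounds
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("score_distribution_bounds must be ordered within [0, 1]")


class SimulatedNetwork(NamedTuple):
    edges: list[InteractionEdge]
    planted_genes: list[str]
    seed_genes: list[str]
    genes: list[str]


_SOURCES = ("ppi_a", "ppi_scored", "tf", "pathway")


def simulate_network(
    spec: NetworkSimSpec, seed: int, genes: Sequence[str] | None = None
) -> SimulatedNetwork:
    """Random background edges plus a densely wired planted module.

    Background edges are Bernoulli(background_edge_prob) over gene pairs,
    with a random source label; ``ppi_scored`` edges carry a uniform score
    in ``score_distribution_bounds``. The planted module is fully connected
    to its designated seed subset through unscored ``ppi_a`` edges, so it
    survives any score cutoff.
    """
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    else:
        genes = list(genes)
        if len(genes) != spec.n_genes:
            raise ValueError("gene list length must equal spec.n_genes")
    perm = rng.permutation(spec.n_genes)
    planted = [genes[i] for i in sorted(perm[: spec.planted_module_size])]
    n_seeds = max(1, int(round(spec.planted_seed_fraction * len(planted))))
    seeds = planted[:n_seeds]

    edges: list[InteractionEdge] = []
    planted_set = set(planted)
    for s in seeds:
        for g in planted:
            if g != s and (s < g or g not in seeds):
                edges.append(InteractionEdge(s, g, "ppi_a"))

    iu, ju = np.triu_indices(spec.n_genes, k=1)
    hit = rng.random(iu.shape[0]) < spec.background_edge_prob
    src_idx = rng.integers(0, len(_SOURCES), size=iu.shape[0])
    lo, hi = spec.score_distribution_bounds
    scores = rng.uniform(lo, hi, size=iu.shape[0])
    for a, b, h, s, sc in zip(iu, ju, hit, src_idx, scores):
        if not h:
            continue
        ga, gb = genes[a], genes[b]
        if ga in planted_set and gb in planted_set:
            continue  # module wiring handled above
        source = _SOURCES[s]
        edges.append(
            InteractionEdge(
                ga,
                gb,
                source,
                score=float(sc) if source == "ppi_scored" else None,
                directed=source == "tf",
            )
        )
    return SimulatedNetwork(edges, planted, seeds, list(genes))


@dataclass
class PhenotypeGroupSpec:
    """Per-group generative settings for larval phenotype tables."""

    name: str
    n_larvae: int = 30
    class_probs: tuple[float, float, float, float] = (0.55, 0.25, 0.1, 0.1)
    clusters_per_larva: int = 12
    length_mean_um: float = 10.0
    length_sd_um: float = 1.0
    lengths_per_larva: int = 5
    edu_prob: float = 0.1
    severity_probs: tuple[float, float, float] = (0.9, 0.08, 0.02)
    ped6_probs: tuple[float, float, float] = (0.02, 0.08, 0.9)  # absent, small_faint, normal

    def __post_init__(self) -> None:
        for name, probs in (
            ("class_probs", self.class_probs),
            ("severity_probs", self.severity_probs),
            ("ped6_probs", self.ped6_probs),
        ):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if self.n_larvae <= 0:
            raise ValueError("n_larvae must be positive")


SEVERITY_LEVELS = ("normal", "intermediate", "severe")
PED6_LEVELS = ("absent", "small_faint", "normal")


class SimulatedPhenotypes(NamedTuple):
    phenotypes: pd.DataFrame
    qpcr: pd.DataFrame
    expression: pd.DataFrame


def simulate_phenotype_table(
    group_specs: Sequence[PhenotypeGroupSpec], seed: int
) -> pd.DataFrame:
    """One row per larva: cluster sizes, lengths, BEC/EdU counts, categories.

    Cluster-size classes {1, 2, 3, >=4} are drawn per cluster from the
    group's multinomial; the >=4 class realises a size uniform on 4..8.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for spec in group_specs:
        for i in range(spec.n_larvae):
            classes = rng.choice(4, size=spec.clusters_per_larva, p=np.asarray(spec.class_probs))
            sizes = [int(c) + 1 if c < 3 else int(rng.integers(4, 9)) for c in classes]
            lengths = rng.normal(spec.length_mean_um, spec.length_sd_um, size=spec.lengths_per_larva)
            bec_total = int(sum(sizes))
            edu_positive = int(rng.binomial(bec_total, spec.edu_prob))
            rows.append(
                {
                    "group": spec.name,
                    "larva_id": f"{spec.name}_{i:03d}",
                    "cluster_sizes": sizes,
                    "lengths_um": [float(x) for x in lengths],
                    "bec_total": bec_total,
                    "edu_positive": edu_positive,
                    "severity": SEVERITY_LEVELS[rng.choice(3, p=np.asarray(spec.severity_probs))],
                    "ped6": PED6_LEVELS[rng.choice(3, p=np.asarray(spec.ped6_probs))],
                }
            )
    return pd.DataFrame(rows)


def simulate_qpcr_table(
    gene_effects: dict[str, float],
    seed: int,
    n_replicates: int = 3,
    ct_reference_mean: float = 18.0,
    ct_target_mean: float = 25.0,
    ct_sd: float = 0.25,
) -> pd.DataFrame:
    """Ct tables for control vs treated with per-gene log2 fold effects.

    ``gene_effects`` maps gene -> log2 fold change in the treated condition;
    the treated target Ct mean is shifted by -log2fc (lower Ct = more
    transcript), reference Cts are shared.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene, log2fc in gene_effects.items():
        for condition in ("control", "treated"):
            shift = -log2fc if condition == "treated" else 0.0
            for r in range(n_replicates):
                rows.append(
                    {
                        "gene_id": gene,
                        "condition": condition,
                        "replicate": r + 1,
                        "ct_target": float(rng.normal(ct_target_mean + shift, ct_sd)),
                        "ct_reference": float(rng.normal(ct_reference_mean, ct_sd)),
                    }
                )
    return pd.DataFrame(rows)


def simulate_expression(
    dosage: np.ndarray, beta: float, seed: int, noise_sd: float = 1.0, baseline: float = 10.0
) -> np.ndarray:
    """Per-sample expression y = baseline + beta * dosage + N(0, noise_sd)."""
    rng = np.random.default_rng(seed)
    dosage = np.asarray(dosage, dtype=float)
    return baseline + beta * dosage + rng.normal(0.0, noise_sd, size=dosage.shape)


def simulate_phenotypes(
    group_specs: Sequence[PhenotypeGroupSpec],
    seed: int,
    gene_effects: dict[str, float] | None = None,
    expression_beta: float = -0.5,
    n_expression_samples: int = 100,
) -> SimulatedPhenotypes:
    """Bundle phenotype, qPCR, and genotype-expression tables for one run."""
    pheno = simulate_phenotype_table(group_specs, seed)
    if gene_effects is None:
        gene_effects = {"egfra": 1.0, "arf6": 0.8, "rac1": 0.5}
    qpcr = simulate_qpcr_table(gene_effects, seed + 1)
    rng = np.random.default_rng(seed + 2)
    dosage = rng.binomial(2, 0.3, size=n_expression_samples).astype(float)
    expr = simulate_expression(dosage, expression_beta, seed + 3)
    expression = pd.DataFrame(
        {"sample_id": [f"E{i:03d}" for i in range(n_expression_samples)],
         "dosage": dosage, "expression": expr}
    )
    return SimulatedPhenotypes(pheno, qpcr, expression)
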
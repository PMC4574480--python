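"""Readers and writers for the pipeline's exchange formats.

PLINK-style text genotypes (.ped/.map, missing allele code "0"), BED4+
gene annotations, TSV interaction edge lists, and TSV sample rosters.
Dosage orientation is fixed at read time: allele_a1 is the minor allele in
the full panel (ties broken toward the lexicographically smaller allele).
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, GenotypeMatrix, InteractionEdge, SampleRecord, SnpRecord

MISSING_ALLELE = "0"
_PED_META_COLS = 6


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a whitespace-delimited .ped/.map pair into a GenotypeMatrix.

    The .ped carries family id, individual id, paternal id, maternal id,
    sex, phenotype (1=control, 2=case) and then two allele columns per SNP.
    """
    map_rows = []
    for lineno, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
        chrom, snp_id, _cm, pos = parts
        map_rows.append((chrom, snp_id, int(pos)))
    n_snps = len(map_rows)

    sample_meta: list[tuple[str, str]] = []
    allele_rows: list[list[str]] = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != _PED_META_COLS + 2 * n_snps:
            raise ValueError(
                f"{ped_path}:{lineno}: expected {_PED_META_COLS + 2 * n_snps} fields "
                f"for {n_snps} SNPs, got {len(parts)}"
            )
        alleles = parts[_PED_META_COLS:]
        for a in alleles:
            if a not in "ACGT" + MISSING_ALLELE or len(a) != 1:
                raise ValueError(f"{ped_path}:{lineno}: invalid allele code {a!r}")
        status = "case" if parts[5] == "2" else "control"
        sample_meta.append((parts[1], status))
        allele_rows.append(alleles)

    n_samples = len(allele_rows)
    a_mat = np.array(allele_rows, dtype="U1").reshape(n_samples, n_snps, 2) if n_samples else np.empty((0, n_snps, 2), dtype="U1")

    snps: list[SnpRecord] = []
    dosage = np.full((n_samples, n_snps), np.nan)
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        col = a_mat[:, j, :]
        counts = Counter(col.ravel().tolist())
        counts.pop(MISSING_ALLELE, None)
        observed = sorted(counts)
        if len(observed) > 2:
            raise ValueError(f"SNP {snp_id}: more than two alleles observed")
        if len(observed) == 2:
            x, y = observed
            # minor allele first; lexicographic tie-break
            a1, a2 = (x, y) if (counts[x], x) <= (counts[y], y) else (y, x)
        elif len(observed) == 1:
            a1 = observed[0]
            a2 = next(c for c in "ACGT" if c != a1)  # placeholder partner
            a1, a2 = a2, a1  # monomorphic: observed allele is the major
        else:
            a1, a2 = "A", "C"  # fully missing column
        snps.append(SnpRecord(snp_id, chrom, pos, a1, a2))
        called = ~np.any(col == MISSING_ALLELE, axis=1) if n_samples else np.array([], bool)
        dosage[called, j] = (col[called] == a1).sum(axis=1)
    return GenotypeMatrix(
        [SampleRecord(sid, status) for sid, status in sample_meta], snps, dosage
    )


def write_plink_text(matrix: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    with open(map_path, "w") as fh:
        for s in matrix.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos_bp}\n")
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(matrix.samples):
            pheno = "2" if sample.status == "case" else "1"
            fields = [sample.sample_id, sample.sample_id, "0", "0", "0", pheno]
            for j, snp in enumerate(matrix.snps):
                d = matrix.dosage[i, j]
                if np.isnan(d):
                    fields += [MISSING_ALLELE, MISSING_ALLELE]
                else:
                    d = int(d)
                    fields += [snp.allele_a1] * d + [snp.allele_a2] * (2 - d)
            fh.write(" ".join(fields) + "\n")


def read_sample_roster(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "status"}
    if not required.issubset(df.columns):
        raise ValueError(f"roster must have columns {sorted(required)}")
    cohorts = df["cohort"] if "cohort" in df.columns else [""] * len(df)
    return [
        SampleRecord(sid, status, cohort)
        for sid, status, cohort in zip(df["sample_id"], df["status"], cohorts)
    ]


def write_sample_roster(samples: Sequence[SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "status": [s.status for s in samples],
            "cohort": [s.cohort_label for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_bed_genes(path: str | Path) -> list[GeneModel]:
    """Read BED4+ gene intervals (0-based half-open, name = gene_id)."""
    genes: list[GeneModel] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: BED4+ required (gene name missing)")
        chrom, start, end, name = parts[:4]
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from exc
        if start_i >= end_i:
            raise ValueError(f"{path}:{lineno}: start >= end")
        strand = parts[5] if len(parts) >= 6 else "."
        genes.append(GeneModel(name, chrom, start_i, end_i, strand))
    return genes


def write_bed_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_edges(path: str | Path) -> list[InteractionEdge]:
    """Read a TSV edge list (gene_a, gene_b, source, score, directed).

    Blank scores are allowed for unscored sources. Duplicate undirected
    pairs are deduplicated keeping the maximum score.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str, "source": str})
    required = {"gene_a", "gene_b", "source"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge list must have columns {sorted(required)}")
    best: dict[tuple, InteractionEdge] = {}
    for row in df.itertuples(index=False):
        score = getattr(row, "score", None)
        if score is not None and (isinstance(score, float) and np.isnan(score)):
            score = None
        if score is not None:
            score = float(score)
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"score {score} outside [0, 1] for {row.gene_a}-{row.gene_b}")
        directed = bool(int(getattr(row, "directed", 0) or 0))
        edge = InteractionEdge(row.gene_a, row.gene_b, row.source, score, directed)
        if directed:
            key = (row.gene_a, row.gene_b, row.source, True)
        else:
            key = (frozenset((row.gene_a, row.gene_b)), row.source, False)
        prev = best.get(key)
        if prev is None or (edge.score or 0.0) > (prev.score or 0.0):
            best[key] = edge
    return list(best.values())


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read a per-larva phenotype TSV (list columns semicolon-joined)."""
    df = pd.read_csv(path, sep="\t", dtype={"group": str, "larva_id": str})
    if "cluster_sizes" in df.columns:
        df["cluster_sizes"] = [
            [int(x) for x in str(v).split(";")] if str(v) else [] for v in df["cluster_sizes"]
        ]
    if "lengths_um" in df.columns:
        df["lengths_um"] = [
            [float(x) for x in str(v).split(";")] if str(v) else [] for v in df["lengths_um"]
        ]
    return df


def write_phenotype_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    for col in ("cluster_sizes", "lengths_um"):
        if col in out.columns:
            out[col] = [";".join(str(x) for x in v) for v in out[col]]
    out.to_csv(path, sep="\t", index=False)


def write_edges(edges: Sequence[InteractionEdge], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_a": [e.gene_a for e in edges],
            "gene_b": [e.gene_b for e in edges],
            "source": [e.source for e in edges],
            "score": [e.score if e.score is not None else "" for e in edges],
            "directed": [int(e.directed) for e in edges],
        }
    ).to_csv(path, sep="\t", index=False)
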
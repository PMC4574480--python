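"""SNP ranking, proximity re-ranking, and window-based SNP-to-gene mapping.

After the genome-wide scan, the top-K SNPs by p-value are re-ranked by how
many other top-K SNPs sit within a +/-10-kb window on the same chromosome —
clustered signals are more trustworthy than isolated ones, since true
associations drag their LD neighbors up the ranking while genotyping
artifacts do not. Mapping assigns each SNP to every gene whose interval,
extended by +/-20 kb, contains it.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core import GeneModel


def rank_by_p(results: pd.DataFrame, k: int = 1000) -> pd.DataFrame:
    """Top-K rows of an association table by ascending p.

    Ties are broken by (chrom, pos_bp, snp_id) so the ranking is
    deterministic. Returns min(k, n) rows with a 1-based ``p_rank``.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    required = {"snp_id", "chrom", "pos_bp", "p"}
    if not required.issubset(results.columns):
        raise ValueError(f"association table must have columns {sorted(required)}")
    if not np.isfinite(results["p"]).all():
        raise ValueError("non-finite p-values in association table")
    out = results.sort_values(["p", "chrom", "pos_bp", "snp_id"], kind="mergesort").head(k).copy()
    out["p_rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def proximity_rank(topk: pd.DataFrame, window_bp: int = 10_000) -> pd.DataFrame:
    """Re-rank top-K SNPs by their number of top-K neighbors within a window.

    ``neighbor_count`` is the number of OTHER top-K SNPs on the same
    chromosome with |delta pos| <= window_bp (boundary inclusive). Rows are
    ordered by (neighbor_count desc, p asc, chrom, pos) and assigned a
    1-based ``proximity_rank``.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    required = {"snp_id", "chrom", "pos_bp", "p"}
    if not required.issubset(topk.columns):
        raise ValueError(f"ranked table must have columns {sorted(required)}")
    out = topk.copy()
    counts = np.zeros(len(out), dtype=int)
    for _, idx in out.groupby("chrom", sort=False).indices.items():
        pos = out["pos_bp"].to_numpy()[idx]
        order = np.argsort(pos, kind="stable")
        sorted_pos = pos[order]
        lo = np.searchsorted(sorted_pos, sorted_pos - window_bp, side="left")
        hi = np.searchsorted(sorted_pos, sorted_pos + window_bp, side="right")
        counts[idx[order]] = hi - lo - 1  # exclude self
    out["neighbor_count"] = counts
    out = out.sort_values(
        ["neighbor_count", "p", "chrom", "pos_bp", "snp_id"],
        ascending=[False, True, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["proximity_rank"] = np.arange(1, len(out) + 1)
    return out


def map_snps_to_genes(
    snps: pd.DataFrame, genes: Sequence[GeneModel], window_bp: int = 20_000
) -> tuple[pd.DataFrame, list[str]]:
    """Map SNPs to genes whose +/-window-extended interval contains them.

    SNP positions are 1-based; gene intervals 0-based half-open. Distances
    are measured from the SNP to the nearest gene boundary after converting
    the half-open end to the inclusive last base, and are 0 inside the gene
    body. The boundary is inclusive: distance == window_bp still maps. A SNP
    may map to several genes; the unique gene list preserves first-hit order.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    required = {"snp_id", "chrom", "pos_bp"}
    if not required.issubset(snps.columns):
        raise ValueError(f"SNP table must have columns {sorted(required)}")
    hits = []
    for row in snps.itertuples(index=False):
        pos0 = row.pos_bp - 1
        for gene in genes:
            if gene.chrom != row.chrom:
                continue
            first, last = gene.start, gene.end - 1
            if pos0 < first:
                dist = first - pos0
            elif pos0 > last:
                dist = pos0 - last
            else:
                dist = 0
            if dist <= window_bp:
                hits.append({"snp_id": row.snp_id, "gene_id": gene.gene_id, "distance_bp": dist})
    hits_df = pd.DataFrame(hits, columns=["snp_id", "gene_id", "distance_bp"])
    unique_genes = list(dict.fromkeys(hits_df["gene_id"])) if len(hits_df) else []
    return hits_df, unique_genes
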
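"""DMC clustering per gene and hypergeometric gene-set enrichment.

A gene qualifies as a "clustered" gene when at least ``min_dmcs``
differentially methylated CpGs assigned to it (gene body or promoter) fall
inside one sliding window of ``window`` bp: on the sorted DMC positions,
``pos[i + min_dmcs - 1] − pos[i] ≤ window`` for some i (span inclusive).
Qualifying genes form the gene-of-interest (GOI) list for
over-representation analysis: for each GMT term, the tail probability
P(X ≥ k) under Hypergeometric(N, K, n), with Benjamini–Hochberg FDR across
all tested terms.

The default universe is the set of genes with at least one tested
(covered, united) CpG in gene or promoter — RRBS covers a biased subset of
the genome, and enrichment against the whole genome would overstate
significance.  A genome-wide universe can be passed explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneDMCCluster",
    "cluster_genes",
    "read_gmt",
    "hypergeometric_enrichment",
    "rank_pathways",
]


@dataclass(frozen=True)
class GeneDMCCluster:
    """Per-gene DMC tally and the densest ≤window-bp stretch of DMCs."""

    gene_id: str
    n_dmcs_total: int
    best_window: tuple[str, int, int, int] | None  # chrom, start, end, n
    qualifies: bool


def cluster_genes(records: pd.DataFrame, min_dmcs: int = 5,
                  window: int = 1000) -> list[GeneDMCCluster]:
    """Find genes whose DMCs cluster within a sliding window.

    ``records`` needs columns gene_id, chrom, pos (DMCs already filtered
    to gene/promoter).  The window slides over DMC positions only; its
    span is measured inclusively (last − first ≤ ``window``).  The best
    window is the one with most DMCs, ties broken by leftmost start.
    """
    out: list[GeneDMCCluster] = []
    if not len(records):
        return out
    df = records.dropna(subset=["gene_id"])
    for gene_id, grp in df.groupby("gene_id", sort=True):
        pos = np.sort(grp["pos"].astype(int).unique())
        chrom = grp["chrom"].iloc[0]
        best_n, best_i = 0, 0
        i = 0
        for j in range(len(pos)):
            while pos[j] - pos[i] > window:
                i += 1
            n_in = j - i + 1
            if n_in > best_n:  # strict: keeps the leftmost among ties
                best_n, best_i = n_in, i
        bw = (chrom, int(pos[best_i]), int(pos[best_i + best_n - 1]), best_n)
        out.append(GeneDMCCluster(str(gene_id), len(pos), bw,
                                  qualifies=best_n >= min_dmcs))
    return out


def read_gmt(path) -> list[tuple[str, str, set[str]]]:
    """Parse a GMT file into (term_id, description, gene set) tuples."""
    terms = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        terms.append((fields[0], fields[1], set(fields[2:])))
    return terms


def hypergeometric_enrichment(
    goi: Iterable[str], universe: Iterable[str],
    gene_sets: Sequence[tuple[str, str, set[str]]] | Mapping[str, set[str]] | str | Path,
) -> pd.DataFrame:
    """Over-representation of GOI in each gene set by the hypergeometric
    tail P(X ≥ k), with BH FDR across all tested terms.

    Terms are restricted to the universe; terms with no universe gene
    (K = 0) are skipped and counted in ``df.attrs['n_skipped']``.  A GOI
    gene outside the universe is a hard error.
    """
    goi = set(goi)
    universe = set(universe)
    stray = goi - universe
    if stray:
        raise ValueError(
            f"genes of interest not in universe: {sorted(stray)[:10]}"
            + (" ..." if len(stray) > 10 else ""))
    if isinstance(gene_sets, (str, Path)):
        gene_sets = read_gmt(gene_sets)
    elif isinstance(gene_sets, Mapping):
        gene_sets = [(t, t, set(g)) for t, g in gene_sets.items()]

    N, n = len(universe), len(goi)
    rows, skipped = [], 0
    for term_id, term_name, members in gene_sets:
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            skipped += 1
            continue
        k = len(in_universe & goi)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term_id, "term_name": term_name,
                     "k": k, "K": K, "n": n, "N": N,
                     "p_hypergeometric": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr_bh"] = multipletests(df["p_hypergeometric"], method="fdr_bh")[1]
    else:
        df["fdr_bh"] = pd.Series(dtype=float)
    df.attrs["n_skipped"] = skipped
    if skipped:
        logger.info("skipped %d terms with no universe genes", skipped)
    return df


def rank_pathways(results: pd.DataFrame, top_n: int = 5,
                  max_fdr: float = 0.05) -> pd.DataFrame:
    """Top significant terms by number of differentially methylated GOI.

    Significant terms (FDR ≤ ``max_fdr``) sorted by k descending, ties by
    FDR ascending; the first ``top_n`` are returned.
    """
    if not len(results):
        return results.copy()
    sig = results.loc[results["fdr_bh"] <= max_fdr]
    ranked = sig.sort_values(["k", "fdr_bh", "term_id"],
                             ascending=[False, True, True])
    return ranked.head(top_n).reset_index(drop=True)
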
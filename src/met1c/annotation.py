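"""Genomic feature annotation of CpG sites.

Each site receives one label per axis:

* gene axis: ``promoter`` > ``exon`` > ``intron`` > ``intergenic``
  (precedence in that order; ties across genes broken by nearest TSS);
* CpG axis: ``island`` > ``shore`` > ``open_sea``.

Gene models are read from GFF3 (``gene``/``mRNA``/``exon`` features, introns
derived as gene body minus exons); CpG islands from BED.  Internal
coordinates are 1-based inclusive; BED input (0-based half-open) is
converted at the boundary.  Promoters default to TSS ±1 kb and shores to a
2 kb island flank, the usual annotation-package conventions; both are
configurable and recorded on the index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from intervaltree import Interval, IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureIndex",
    "FeatureCall",
    "build_index",
    "annotate",
    "distribution_summary",
    "read_bed_intervals",
]

GENE_FEATURES = ("promoter", "exon", "intron", "intergenic")
CPG_CONTEXTS = ("island", "shore", "open_sea")


@dataclass(frozen=True)
class FeatureCall:
    chrom: str
    pos: int
    gene_feature: str
    cpg_context: str
    gene_id: str | None = None
    transcript_id: str | None = None


@dataclass
class FeatureIndex:
    """Per-chromosome interval trees for every feature class.

    Intervals are stored half-open on 1-based coordinates
    (``Interval(start, end + 1)``), so a site at position p overlaps the
    stored interval iff start ≤ p ≤ end.
    """

    promoters: dict[str, IntervalTree] = field(default_factory=dict)
    exons: dict[str, IntervalTree] = field(default_factory=dict)
    gene_bodies: dict[str, IntervalTree] = field(default_factory=dict)
    islands: dict[str, IntervalTree] = field(default_factory=dict)
    shores: dict[str, IntervalTree] = field(default_factory=dict)
    promoter_up: int = 1000
    promoter_down: int = 1000
    shore_width: int = 2000

    def header_comment(self) -> str:
        return (f"# promoter=TSS-{self.promoter_up}/+{self.promoter_down}bp; "
                f"shore_width={self.shore_width}bp")


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """Read a BED file into 1-based inclusive (chrom, start, end) tuples."""
    out: list[tuple[str, int, int]] = []
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["chrom", "start", "end"])
    for row in bed.itertuples(index=False):
        out.append((str(row.chrom), int(row.start) + 1, int(row.end)))
    return out


def _add(trees: dict[str, IntervalTree], chrom: str, start: int, end: int,
         data=None) -> None:
    if end < start:
        return
    trees.setdefault(chrom, IntervalTree()).add(Interval(start, end + 1, data))


def build_index(gff_path, islands_bed=None, promoter_up: int = 1000,
                promoter_down: int = 1000, shore_width: int = 2000,
                ) -> FeatureIndex:
    """Build a :class:`FeatureIndex` from a GFF3 file and an island BED.

    Promoters are computed strand-aware around the transcript TSS
    (upstream ``promoter_up`` bp through downstream ``promoter_down`` bp,
    both inclusive of the TSS position).  Transcripts with unknown strand
    are skipped with a warning.  Shores are the ``shore_width`` flanks of
    each island, clipped so that no shore base overlaps any island.
    """
    idx = FeatureIndex(promoter_up=promoter_up, promoter_down=promoter_down,
                       shore_width=shore_width)
    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    for tx in db.features_of_type("mRNA"):
        gene_id = tx.attributes.get("Parent", [tx.id])[0]
        if tx.strand == "+":
            tss = tx.start
            prom = (tss - promoter_up, tss + promoter_down)
        elif tx.strand == "-":
            tss = tx.end
            prom = (tss - promoter_down, tss + promoter_up)
        else:
            logger.warning("transcript %s has unknown strand; skipped", tx.id)
            continue
        meta = {"gene_id": gene_id, "transcript_id": tx.id, "tss": tss}
        _add(idx.promoters, tx.seqid, max(1, prom[0]), prom[1], meta)
        _add(idx.gene_bodies, tx.seqid, tx.start, tx.end, meta)
        for ex in db.children(tx, featuretype="exon"):
            _add(idx.exons, ex.seqid, ex.start, ex.end, meta)

    if islands_bed is not None:
        islands = read_bed_intervals(islands_bed)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in islands:
            _add(idx.islands, chrom, s, e)
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            island_tree = idx.islands[chrom]
            for s, e in ivs:
                for cs, ce in ((max(1, s - shore_width), s - 1),
                               (e + 1, e + shore_width)):
                    if ce < cs:
                        continue
                    # clip the shore against every island it touches
                    pieces = IntervalTree([Interval(cs, ce + 1)])
                    for hit in island_tree.overlap(cs, ce + 1):
                        pieces.chop(hit.begin, hit.end)
                    for piece in pieces:
                        _add(idx.shores, chrom, piece.begin, piece.end - 1)
    return idx


def _nearest_tss(hits, pos: int):
    """Pick the hit whose TSS is closest to pos (ties by transcript id)."""
    return min(hits, key=lambda h: (abs(pos - h.data["tss"]),
                                    h.data["transcript_id"]))


def annotate(sites: Iterable[tuple[str, int]], index: FeatureIndex,
             ) -> list[FeatureCall]:
    """Assign gene-axis and CpG-axis labels to (chrom, pos) sites."""
    calls: list[FeatureCall] = []
    empty = IntervalTree()
    for chrom, pos in sites:
        pos = int(pos)
        gene_feature, gid, tid = "intergenic", None, None
        for feature, trees in (("promoter", index.promoters),
                               ("exon", index.exons),
                               ("intron", index.gene_bodies)):
            hits = trees.get(chrom, empty).at(pos)
            if hits:
                best = _nearest_tss(hits, pos)
                gene_feature = feature
                gid = best.data["gene_id"]
                tid = best.data["transcript_id"]
                break
        if index.islands.get(chrom, empty).at(pos):
            context = "island"
        elif index.shores.get(chrom, empty).at(pos):
            context = "shore"
        else:
            context = "open_sea"
        calls.append(FeatureCall(chrom, pos, gene_feature, context, gid, tid))
    return calls


def distribution_summary(calls: Sequence[FeatureCall]) -> dict[str, dict[str, float]]:
    """Percentage of sites per class on each axis (each axis sums to 100)."""
    if not calls:
        raise ValueError("distribution_summary requires at least one call")
    n = len(calls)
    gene = {f: 0 for f in GENE_FEATURES}
    cpg = {c: 0 for c in CPG_CONTEXTS}
    for c in calls:
        gene[c.gene_feature] += 1
        cpg[c.cpg_context] += 1
    return {
        "gene_axis": {k: 100.0 * v / n for k, v in gene.items()},
        "cpg_axis": {k: 100.0 * v / n for k, v in cpg.items()},
    }
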
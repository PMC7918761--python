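"""End-to-end orchestration: generate → QC → DMC → annotate → cluster →
enrich → imprint → machine-readable summary.

``run_all`` executes the four standard contrasts — added methionine
(10 v 50 µM) within each embryonic lineage, and lineage (ICM v TE) within
each methionine level — and writes per-stage TSVs plus a versioned JSON
summary holding, per contrast, the DMC count, gain/loss split and
percentages, and the transcript/gene tallies; when ground truth is
available (synthetic runs) recovery metrics are included.  Runs are
deterministic given the seed; each stage can be re-run from its
intermediates.  Stage timings go to the logger (informational only).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from met1c import annotation as annot
from met1c import dmc as dmc_mod
from met1c import enrichment as enr
from met1c import imprint as imp
from met1c import synthetic as syn

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Paths, thresholds and contrasts for one pipeline run."""

    out_dir: str | Path
    seed: int = 0
    data_dir: str | Path | None = None          # pre-existing dataset
    design: syn.SyntheticDesign | None = None   # generate if given
    mincov: int = 5
    min_diff: float = 20.0
    max_q: float = 0.05
    cluster_min_dmcs: int = 5
    cluster_window: int = 1000
    enrich_max_fdr: float = 0.05
    imprint_alpha: float = 0.001
    min_conversion: float = 0.98
    promoter_up: int = 1000
    promoter_down: int = 1000
    shore_width: int = 2000

    def __post_init__(self) -> None:
        if self.design is None and self.data_dir is None:
            self.design = syn.SyntheticDesign(seed=self.seed)
        for t in (self.mincov, self.min_diff, self.max_q,
                  self.cluster_min_dmcs, self.cluster_window,
                  self.enrich_max_fdr, self.imprint_alpha):
            if t <= 0:
                raise ValueError("all thresholds must be positive")


# the four Table-style contrasts: (name, grouping factor, group_a, group_b,
# within-factor, within-level); "gain" means higher in group_a
CONTRASTS = (
    ("ICM_10v50", "methionine", 10, 50, "lineage", "ICM"),
    ("TE_10v50", "methionine", 10, 50, "lineage", "TE"),
    ("10uM_ICMvTE", "lineage", "ICM", "TE", "methionine", 10),
    ("50uM_ICMvTE", "lineage", "ICM", "TE", "methionine", 50),
)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"stage '{name}' failed: {e}") from e
            logger.info("stage %-12s %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def _recovery(records: pd.DataFrame, truth_set: set[tuple[str, int]]):
    called = set(zip(records["chrom"], records["pos"]))
    if not truth_set:
        return None
    tp = len(called & truth_set)
    sens = tp / len(truth_set)
    fdr = (len(called) - tp) / len(called) if called else 0.0
    return {"sensitivity": round(sens, 4), "empirical_fdr": round(fdr, 4),
            "n_true": len(truth_set), "n_called": len(called)}


def run_all(config: RunConfig) -> dict:
    """Run the full workflow; returns (and writes) the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.design is not None:
        data_dir = out / "data"
        truth = _stage("generate")(syn.generate)(config.design, data_dir)
    else:
        data_dir = Path(config.data_dir)
        tj = data_dir / "truth.json"
        if tj.exists():
            truth = syn.GroundTruth.from_json(tj)

    meta = pd.read_csv(data_dir / "samples.tsv", sep="\t")
    paths = {s: data_dir / f"{s}.cov" for s in meta["sample"]}
    matrix = _stage("read")(dmc_mod.read_coverage)(paths, meta)

    spike = truth.spikein_contig if truth else syn.SPIKEIN_CONTIG
    qc = _stage("qc")(dmc_mod.conversion_qc)(matrix, spike,
                                             config.min_conversion)
    qc.to_csv(out / "conversion_qc.tsv", sep="\t", index=False)

    index = _stage("index")(annot.build_index)(
        data_dir / "genes.gff3", data_dir / "cpg_islands.bed",
        config.promoter_up, config.promoter_down, config.shore_width)

    contrasts_out: dict[str, dict] = {}
    enrichment_out: dict[str, dict] = {}
    cluster_out: dict[str, dict] = {}
    goi_by_contrast: dict[str, list[str]] = {}

    for name, factor, a, b, wfactor, wlevel in CONTRASTS:
        within = matrix.sample_mask(**{wfactor: wlevel})
        united = dmc_mod.unite_and_filter(
            matrix, mincov=config.mincov,
            variant_mask=data_dir / "variants.bed",
            sample_mask=within, exclude_contigs=[spike])
        united = united.subset_samples(within)
        ga = united.sample_mask(**{factor: a})
        gb = united.sample_mask(**{factor: b})
        records = _stage(f"test:{name}")(dmc_mod.test_dmc)(united, ga, gb)
        called = dmc_mod.filter_dmc(records, index, config.min_diff,
                                    config.max_q)
        called.to_csv(out / f"dmc_{name}.tsv", sep="\t", index=False)
        summary = dmc_mod.summarize_direction(called)
        n_tx, n_genes = dmc_mod.count_transcripts_genes(called)
        entry = {
            "n_tested": int(len(records)),
            "n_dmc": summary.n_total,
            "n_gain": summary.n_gain, "n_loss": summary.n_loss,
            "pct_gain": summary.pct_gain, "pct_loss": summary.pct_loss,
            "n_transcripts": n_tx, "n_genes": n_genes,
        }
        if truth is not None:
            tset = (truth.treatment_dmc_set() if factor == "methionine"
                    else truth.lineage_dmc_set())
            rec = _recovery(called, tset)
            if rec:
                entry["recovery"] = rec
        contrasts_out[name] = entry

        # clustering + enrichment for the methionine contrasts
        if factor == "methionine":
            clusters = enr.cluster_genes(called, config.cluster_min_dmcs,
                                         config.cluster_window)
            goi = sorted(c.gene_id for c in clusters if c.qualifies)
            goi_by_contrast[name] = goi
            tested_calls = annot.annotate(
                zip(united.sites["chrom"], united.sites["pos"]), index)
            universe = sorted({c.gene_id for c in tested_calls
                               if c.gene_id is not None})
            results = enr.hypergeometric_enrichment(
                goi, universe, data_dir / "sets.gmt")
            results.to_csv(out / f"enrichment_{name}.tsv", sep="\t",
                           index=False)
            top = enr.rank_pathways(results, max_fdr=config.enrich_max_fdr)
            entry_cl = {"n_qualifying": len(goi)}
            if truth is not None and truth.cluster_genes:
                hit = len(set(goi) & set(truth.cluster_genes))
                entry_cl["cluster_gene_recall"] = round(
                    hit / len(truth.cluster_genes), 4)
            cluster_out[name] = entry_cl
            enrichment_out[name] = {
                "n_terms_tested": int(len(results)),
                "n_significant": int((results["fdr_bh"]
                                      <= config.enrich_max_fdr).sum()),
                "top_terms": top["term_id"].tolist(),
                "min_fdr_term": (results.loc[results["fdr_bh"].idxmin(),
                                             "term_id"]
                                 if len(results) else None),
            }

    # imprinted-gene panel
    imprint_entry = None
    panel_path = data_dir / "imprinted_panel.tsv"
    if panel_path.exists():
        genes = pd.read_csv(panel_path, sep="\t")
        united_all = dmc_mod.unite_and_filter(
            matrix, mincov=config.mincov,
            variant_mask=data_dir / "variants.bed",
            exclude_contigs=[spike])
        panel = imp.build_panel(united_all, genes)
        if len(panel):
            results = _stage("imprint")(imp.fit_panel)(panel)
            report = imp.panel_report(results, alpha=config.imprint_alpha)
            report.to_csv(out / "imprint_report.tsv", sep="\t", index=False)
            imprint_entry = {
                "n_genes": int(len(report)),
                "flagged": sorted(report.loc[
                    report[["sig_methionine", "sig_lineage",
                            "sig_interaction"]].any(axis=1), "gene_id"]),
            }

    summary = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "thresholds": {
            "mincov": config.mincov, "min_diff": config.min_diff,
            "max_q": config.max_q,
            "cluster_min_dmcs": config.cluster_min_dmcs,
            "cluster_window": config.cluster_window,
            "enrich_max_fdr": config.enrich_max_fdr,
        },
        "conversion_qc": {
            "all_passed": bool(qc["passed"].all()),
            "rates": {r["sample"]: (None if pd.isna(r["rate"])
                                    else round(float(r["rate"]), 5))
                      for _, r in qc.iterrows()},
        },
        "contrasts": contrasts_out,
        "clusters": cluster_out,
        "enrichment": enrichment_out,
        "imprint": imprint_entry,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 sort_keys=True))
    return summary
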
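"""Differential CpG methylation calling from bismark-style coverage files.

The stage chain mirrors a standard RRBS count-level workflow: parse
``.cov`` files (chrom, start, end, %methylation, methylated count,
unmethylated count; 1-based, start = end), unite sites across samples with
a minimum-coverage rule, mask known variant positions, monitor bisulfite
conversion on an unmethylated spike-in contig, test each CpG for a group
difference with a chi-squared statistic, correct with Benjamini–Hochberg,
and keep calls that are in a gene or promoter with an absolute methylation
difference above a strict threshold (default > 20 percentage points).

The per-CpG test fits a binomial-proportion model of methylated/coverage
on group membership across replicate samples and reports the 1-df
likelihood-ratio (deviance) chi-squared p-value.  Because the binomial
model with a single group factor is fitted by pooling counts within each
group, this statistic is algebraically identical to the classical G-test
on the pooled 2×2 table; both entry points are exposed (``mode="deviance"``
and ``mode="pooled"``) and agree to machine precision.

Strands are not merged; positions are compared exactly as given in the
input files.  Read-level filters (mapping quality, mate-overlap
de-duplication) act upstream of count extraction and are outside this
module's reach; counts are taken as final.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from met1c import annotation as annot

logger = logging.getLogger(__name__)

__all__ = [
    "MethylCountMatrix",
    "DirectionSummary",
    "read_coverage",
    "unite_and_filter",
    "conversion_qc",
    "test_dmc",
    "filter_dmc",
    "summarize_direction",
    "count_transcripts_genes",
]

COV_COLUMNS = ["chrom", "start", "end", "pct", "meth", "unmeth"]


@dataclass
class MethylCountMatrix:
    """Per-CpG methylated/total read counts across samples.

    ``sites`` has columns (chrom, pos, strand), sorted by (chrom, pos);
    ``meth``/``cov`` are (n_sites × n_samples) integer arrays aligned to
    ``samples`` (columns sample, lineage, methionine, replicate).
    """

    sites: pd.DataFrame
    meth: np.ndarray
    cov: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if np.any(self.meth > self.cov) or np.any(self.meth < 0):
            raise ValueError("require 0 <= methylated <= coverage")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_mask(self, **factors) -> np.ndarray:
        """Boolean sample selector, e.g. ``sample_mask(lineage="ICM")``."""
        m = np.ones(len(self.samples), dtype=bool)
        for k, v in factors.items():
            m &= (self.samples[k] == v).to_numpy()
        return m

    def subset_sites(self, idx) -> "MethylCountMatrix":
        return MethylCountMatrix(
            self.sites.iloc[idx].reset_index(drop=True),
            self.meth[idx], self.cov[idx], self.samples)

    def subset_samples(self, mask) -> "MethylCountMatrix":
        return MethylCountMatrix(
            self.sites.copy(), self.meth[:, mask], self.cov[:, mask],
            self.samples.loc[mask].reset_index(drop=True))


@dataclass(frozen=True)
class DirectionSummary:
    """Gain/loss counts and one-decimal percentages for one contrast."""

    n_total: int
    n_gain: int
    n_loss: int
    pct_gain: float
    pct_loss: float


def _read_one_cov(path) -> pd.DataFrame:
    bad: list[int] = []

    def _on_bad(line_fields):
        bad.append(len(line_fields))
        return None

    try:
        df = pd.read_csv(path, sep="\t", header=None, names=COV_COLUMNS,
                         engine="python", on_bad_lines=_on_bad,
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        logger.warning("coverage file %s is empty", path)
        return pd.DataFrame(columns=COV_COLUMNS)
    if not len(df):
        logger.warning("coverage file %s is empty", path)
        return df
    if bad:
        logger.warning("%s: skipped %d malformed lines", path, len(bad))
    malformed = df.index[df[["start", "meth", "unmeth"]].isna().any(axis=1)]
    if len(malformed):
        raise ValueError(
            f"{path}: non-numeric counts at lines "
            f"{[int(i) + 1 for i in malformed[:10]]}")
    return df


def read_coverage(paths: dict[str, str | Path] | Sequence[str | Path],
                  metadata: pd.DataFrame) -> MethylCountMatrix:
    """Read bismark ``.cov`` files into a united count matrix.

    ``paths`` maps sample name → file (or is a list aligned with
    ``metadata``, which needs columns sample/lineage/methionine/replicate).
    Sites absent from a sample get coverage 0.  Inconsistent chromosome
    naming between samples (e.g. ``chr1`` in one file, ``1`` in another)
    is a hard error.
    """
    if not isinstance(paths, dict):
        paths = dict(zip(metadata["sample"], paths))
    per_sample: dict[str, pd.DataFrame] = {}
    chrom_styles: dict[str, set[str]] = {}
    for name in metadata["sample"]:
        df = _read_one_cov(paths[name])
        per_sample[name] = df
        chrom_styles[name] = set(df["chrom"].astype(str)) if len(df) else set()

    bare = {c.removeprefix("chr") for s in chrom_styles.values() for c in s}
    for b in bare:
        styles = {c for s in chrom_styles.values() for c in s
                  if c.removeprefix("chr") == b}
        if len(styles) > 1:
            raise ValueError(
                f"inconsistent chromosome naming across samples: {sorted(styles)}")

    frames = []
    for name, df in per_sample.items():
        if not len(df):
            continue
        f = pd.DataFrame({
            "chrom": df["chrom"].astype(str),
            "pos": df["start"].astype(int),
            f"m::{name}": df["meth"].astype(int),
            f"c::{name}": (df["meth"] + df["unmeth"]).astype(int),
        }).set_index(["chrom", "pos"])
        frames.append(f)
    if frames:
        wide = pd.concat(frames, axis=1).fillna(0).astype(int).sort_index()
    else:
        wide = pd.DataFrame()
    sites = (wide.index.to_frame(index=False)
             if len(wide) else pd.DataFrame(columns=["chrom", "pos"]))
    sites["strand"] = "."
    n = len(sites)
    meth = np.zeros((n, len(metadata)), dtype=int)
    cov = np.zeros((n, len(metadata)), dtype=int)
    for j, name in enumerate(metadata["sample"]):
        if f"m::{name}" in wide.columns:
            meth[:, j] = wide[f"m::{name}"].to_numpy()
            cov[:, j] = wide[f"c::{name}"].to_numpy()
    return MethylCountMatrix(sites, meth, cov, metadata.reset_index(drop=True))


def unite_and_filter(matrix: MethylCountMatrix, mincov: int = 5,
                     variant_mask: Iterable[tuple[str, int]] | str | Path | None = None,
                     sample_mask: np.ndarray | None = None,
                     exclude_contigs: Iterable[str] = (),
                     ) -> MethylCountMatrix:
    """Retain sites covered ≥ ``mincov`` in every selected sample and not at
    a masked variant position.

    ``variant_mask`` may be a BED path or an iterable of (chrom, 1-based
    pos).  ``exclude_contigs`` drops e.g. the spike-in contig from testing.
    """
    if sample_mask is None:
        sample_mask = np.ones(len(matrix.samples), dtype=bool)
    keep = (matrix.cov[:, sample_mask] >= mincov).all(axis=1)
    if exclude_contigs:
        keep &= ~matrix.sites["chrom"].isin(set(exclude_contigs)).to_numpy()
    if variant_mask is not None:
        if isinstance(variant_mask, (str, Path)):
            masked = {(c, p) for c, s, e in annot.read_bed_intervals(variant_mask)
                      for p in range(s, e + 1)}
        else:
            masked = set(variant_mask)
        if masked:
            key = list(zip(matrix.sites["chrom"], matrix.sites["pos"]))
            keep &= ~np.array([k in masked for k in key])
    return matrix.subset_sites(np.flatnonzero(keep))


def conversion_qc(matrix: MethylCountMatrix, spikein_contig: str,
                  min_rate: float = 0.98) -> pd.DataFrame:
    """Per-sample bisulfite conversion rate from the unmethylated spike-in.

    rate = unmethylated/total reads over spike-in sites.  Samples below
    ``min_rate`` are flagged (``passed=False``), never dropped.  With no
    spike-in sites every row is marked not assessable (rate NaN).
    """
    on_spike = (matrix.sites["chrom"] == spikein_contig).to_numpy()
    rows = []
    for j, name in enumerate(matrix.samples["sample"]):
        total = int(matrix.cov[on_spike, j].sum())
        meth = int(matrix.meth[on_spike, j].sum())
        if total == 0:
            rows.append({"sample": name, "n_unmeth": 0, "n_total": 0,
                         "rate": np.nan, "passed": False,
                         "assessable": False})
            continue
        rate = (total - meth) / total
        rows.append({"sample": name, "n_unmeth": total - meth,
                     "n_total": total, "rate": rate,
                     "passed": bool(rate >= min_rate), "assessable": True})
    qc = pd.DataFrame(rows)
    if not qc["assessable"].any():
        logger.warning("conversion QC not assessable: no spike-in sites on %s",
                       spikein_contig)
    return qc


def _g_statistic(ma, ca, mb, cb):
    """Likelihood-ratio chi-squared (G) for pooled 2×2 tables, vectorised."""
    def ll(m, c):
        return xlogy(m, m) + xlogy(c - m, c - m) - xlogy(c, c)
    return 2.0 * (ll(ma, ca) + ll(mb, cb) - ll(ma + mb, ca + cb))


def _deviance_statistic(meth_a, cov_a, meth_b, cov_b):
    """Binomial deviance test of the group factor, per-sample terms.

    The group-wise MLE pools counts within each group, so the saturated
    per-sample likelihood contributions cancel and the statistic equals
    the pooled 2×2 G-test; the per-sample form is kept as the literal
    replicate-aware computation.
    """
    ma, ca = meth_a.sum(axis=1), cov_a.sum(axis=1)
    mb, cb = meth_b.sum(axis=1), cov_b.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pa = np.where(ca > 0, ma / np.maximum(ca, 1), 0.0)
        pb = np.where(cb > 0, mb / np.maximum(cb, 1), 0.0)
        p0 = (ma + mb) / np.maximum(ca + cb, 1)

    def ll_terms(meth, cov, p):
        p = p[:, None]
        return (xlogy(meth, p) + xlogy(cov - meth, 1.0 - p)).sum(axis=1)

    ll_alt = ll_terms(meth_a, cov_a, pa) + ll_terms(meth_b, cov_b, pb)
    ll_null = ll_terms(meth_a, cov_a, p0) + ll_terms(meth_b, cov_b, p0)
    return 2.0 * (ll_alt - ll_null)


def test_dmc(matrix: MethylCountMatrix, group_a: np.ndarray,
             group_b: np.ndarray, mode: str = "deviance") -> pd.DataFrame:
    """Per-CpG chi-squared differential test between two sample groups.

    ``group_a``/``group_b`` are boolean sample selectors.  Group means are
    pooled methylated/pooled coverage (percent); ``meth_diff`` is
    group A − group B in percentage points; q-values are Benjamini–
    Hochberg over all tested sites.  Sites with zero total coverage in
    either group are excluded (count in ``df.attrs['n_excluded']``).
    """
    if mode not in ("deviance", "pooled"):
        raise ValueError("mode must be 'deviance' or 'pooled'")
    if not group_a.any() or not group_b.any():
        raise ValueError("each group needs at least one sample")
    meth_a, cov_a = matrix.meth[:, group_a], matrix.cov[:, group_a]
    meth_b, cov_b = matrix.meth[:, group_b], matrix.cov[:, group_b]
    ca, cb = cov_a.sum(axis=1), cov_b.sum(axis=1)
    ok = (ca > 0) & (cb > 0)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.warning("excluded %d sites with zero group coverage", n_excluded)

    ma, mb = meth_a.sum(axis=1), meth_b.sum(axis=1)
    if mode == "pooled":
        g = _g_statistic(ma[ok], ca[ok], mb[ok], cb[ok])
    else:
        g = _deviance_statistic(meth_a[ok], cov_a[ok], meth_b[ok], cov_b[ok])
    g = np.maximum(g, 0.0)  # guard tiny negative rounding
    p = chi2.sf(g, df=1)

    mean_a = 100.0 * ma[ok] / ca[ok]
    mean_b = 100.0 * mb[ok] / cb[ok]
    diff = mean_a - mean_b
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])

    out = matrix.sites.loc[ok, ["chrom", "pos", "strand"]].reset_index(drop=True)
    out["mean_a"] = mean_a
    out["mean_b"] = mean_b
    out["meth_diff"] = diff
    out["p_value"] = p
    out["q_value"] = q
    out["direction"] = np.where(diff > 0, "gain", "loss")
    out.attrs["n_excluded"] = n_excluded
    return out


def filter_dmc(records: pd.DataFrame, feature_index: annot.FeatureIndex,
               min_diff: float = 20.0, max_q: float = 0.05) -> pd.DataFrame:
    """Keep significant in-gene/promoter calls with |diff| strictly above
    ``min_diff`` percentage points, and attach feature annotations."""
    if not len(records):
        out = records.copy()
        for col in ("feature", "cpg_context", "gene_id", "transcript_id"):
            out[col] = pd.Series(dtype=object)
        return out
    calls = annot.annotate(
        zip(records["chrom"], records["pos"]), feature_index)
    out = records.copy()
    out["feature"] = [c.gene_feature for c in calls]
    out["cpg_context"] = [c.cpg_context for c in calls]
    out["gene_id"] = [c.gene_id for c in calls]
    out["transcript_id"] = [c.transcript_id for c in calls]
    keep = ((out["q_value"] <= max_q)
            & (out["meth_diff"].abs() > min_diff)
            & out["feature"].isin(["promoter", "exon", "intron"]))
    return out.loc[keep].reset_index(drop=True)


def summarize_direction(records: pd.DataFrame | Sequence[str] | dict,
                        ) -> DirectionSummary:
    """Gain/loss counts and percentages (one decimal) for one contrast.

    Accepts a records DataFrame with a ``direction`` column, or a mapping
    ``{"gain": n, "loss": n}`` of already-tallied counts.
    """
    if isinstance(records, dict):
        n_gain, n_loss = int(records["gain"]), int(records["loss"])
    elif isinstance(records, pd.DataFrame):
        n_gain = int((records["direction"] == "gain").sum())
        n_loss = int((records["direction"] == "loss").sum())
    else:
        n_gain = sum(1 for d in records if d == "gain")
        n_loss = sum(1 for d in records if d == "loss")
    total = n_gain + n_loss
    if total == 0:
        return DirectionSummary(0, 0, 0, 0.0, 0.0)
    return DirectionSummary(
        total, n_gain, n_loss,
        round(100.0 * n_gain / total, 1), round(100.0 * n_loss / total, 1))


def count_transcripts_genes(records: pd.DataFrame) -> tuple[int, int]:
    """Distinct transcripts and genes harbouring at least one DMC."""
    if not len(records):
        return 0, 0
    tx = records["transcript_id"].dropna().nunique()
    genes = records["gene_id"].dropna().nunique()
    return int(tx), int(genes)
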
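"""Per-gene linear mixed models of imprinted-gene CpG methylation.

For each gene in a user-supplied panel the module models the per-sample,
per-CpG methylation proportion (pooled methylated/coverage) as

    y ~ replicate + methionine * lineage + (1 | CpG)

fitted by REML: individual CpG is the random intercept, replicate plus the
methionine × lineage factorial are fixed effects.  Fixed effects are
reported with Wald tests; genes are flagged when an effect reaches the
reporting threshold p < 0.001.  The response is the raw proportion (an
arcsine-square-root transform is available behind a flag).  A singular fit
(zero CpG-level variance) falls back to ordinary least squares and is
flagged as such, never silently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from met1c.dmc import MethylCountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MixedModelResult",
    "build_panel",
    "fit_gene",
    "fit_panel",
    "panel_report",
]

FORMULA = "y ~ C(replicate) + C(methionine) * C(lineage)"
# treatment coding: baseline cell is (methionine=10, lineage=ICM)
TERM_KEYS = {
    "methionine": "C(methionine)[T.50]",
    "lineage": "C(lineage)[T.TE]",
    "interaction": "C(methionine)[T.50]:C(lineage)[T.TE]",
}


@dataclass
class MixedModelResult:
    gene_id: str
    n_cpgs: int
    estimates: dict[str, float]          # per term: coefficient
    std_errors: dict[str, float]
    p_values: dict[str, float]           # Wald
    var_cpg: float                       # random-intercept variance
    var_resid: float
    cell_means: dict[str, float]         # "<lineage>_<met>" -> fitted mean
    ols_fallback: bool = False


def build_panel(matrix: MethylCountMatrix, genes: pd.DataFrame,
                min_cpgs: int = 2) -> pd.DataFrame:
    """Long-format per-CpG, per-sample proportions for the panel genes.

    ``genes`` needs columns gene_id, chrom, start, end (1-based inclusive).
    Samples with zero coverage at a site contribute no row.  Genes with
    fewer than ``min_cpgs`` covered CpGs are dropped with a warning.
    """
    rows = []
    chroms = matrix.sites["chrom"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()
    for g in genes.itertuples(index=False):
        in_gene = np.flatnonzero(
            (chroms == g.chrom) & (pos >= g.start) & (pos <= g.end))
        if len(in_gene) < min_cpgs:
            logger.warning("panel gene %s has %d covered CpGs; skipped",
                           g.gene_id, len(in_gene))
            continue
        for i in in_gene:
            for j, s in enumerate(matrix.samples.itertuples(index=False)):
                c = matrix.cov[i, j]
                if c == 0:
                    continue
                rows.append({
                    "gene": g.gene_id, "cpg": f"{chroms[i]}:{pos[i]}",
                    "sample": s.sample, "replicate": s.replicate,
                    "lineage": s.lineage, "methionine": s.methionine,
                    "y": matrix.meth[i, j] / c,
                })
    return pd.DataFrame(rows)


def fit_gene(panel_slice: pd.DataFrame, arcsine: bool = False,
             ) -> MixedModelResult:
    """Fit the random-intercept-per-CpG REML model for one gene.

    Requires ≥2 CpGs and all four methionine × lineage cells represented.
    """
    df = panel_slice.copy()
    gene_id = str(df["gene"].iloc[0])
    n_cpgs = df["cpg"].nunique()
    if n_cpgs < 2:
        raise ValueError(f"gene {gene_id}: need >= 2 CpGs, got {n_cpgs}")
    cells = df.groupby(["methionine", "lineage"]).size()
    if len(cells) < 4:
        raise ValueError(f"gene {gene_id}: missing treatment cells")
    if arcsine:
        df["y"] = np.arcsin(np.sqrt(df["y"].clip(0, 1)))

    ols_fallback = False
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(FORMULA, df, groups=df["cpg"])
            result = model.fit(reml=True)
            var_cpg = float(result.cov_re.iloc[0, 0])
            if not result.converged or var_cpg < 1e-10:
                ols_fallback = True
        except Exception:
            ols_fallback = True
    if ols_fallback:
        logger.warning("gene %s: singular mixed fit, falling back to OLS",
                       gene_id)
        result = smf.ols(FORMULA, df).fit()
        var_cpg = 0.0
        var_resid = float(result.mse_resid)
    else:
        var_resid = float(result.scale)

    params, bse, pvals = result.params, result.bse, result.pvalues
    est = {t: float(params[key]) for t, key in TERM_KEYS.items()}
    se = {t: float(bse[key]) for t, key in TERM_KEYS.items()}
    pv = {t: float(pvals[key]) for t, key in TERM_KEYS.items()}
    # replicate terms reported jointly as the largest |coefficient|
    rep_keys = [k for k in params.index if k.startswith("C(replicate)")]
    if rep_keys:
        biggest = max(rep_keys, key=lambda k: abs(params[k]))
        est["replicate"] = float(params[biggest])
        se["replicate"] = float(bse[biggest])
        pv["replicate"] = float(pvals[biggest])

    # model-based cell means, averaged over replicate levels
    grid = pd.DataFrame([
        {"replicate": r, "methionine": met, "lineage": lin}
        for r in sorted(df["replicate"].unique())
        for met in sorted(df["methionine"].unique())
        for lin in sorted(df["lineage"].unique())
    ])
    pred = np.asarray(result.predict(grid))
    grid["fit"] = pred
    cell_means = {
        f"{lin}_{met}": float(v)
        for (met, lin), v in grid.groupby(["methionine", "lineage"])["fit"].mean().items()
    }
    return MixedModelResult(gene_id, int(n_cpgs), est, se, pv,
                            float(var_cpg), var_resid, cell_means,
                            ols_fallback)


def fit_panel(panel: pd.DataFrame, arcsine: bool = False,
              ) -> list[MixedModelResult]:
    """Fit every gene in a long-format panel; unfittable genes are skipped
    with a warning."""
    results = []
    for gene_id, grp in panel.groupby("gene", sort=True):
        try:
            results.append(fit_gene(grp, arcsine=arcsine))
        except ValueError as e:
            logger.warning("skipping gene %s: %s", gene_id, e)
    return results


def panel_report(results: list[MixedModelResult], alpha: float = 0.001,
                 ) -> pd.DataFrame:
    """Heat-map-ready table: per-gene significance flags at ``alpha`` and
    the four fitted cell means."""
    if not results:
        raise ValueError("panel_report requires at least one fitted gene")
    rows = []
    for r in results:
        row = {
            "gene_id": r.gene_id, "n_cpgs": r.n_cpgs,
            "p_methionine": r.p_values["methionine"],
            "p_lineage": r.p_values["lineage"],
            "p_interaction": r.p_values["interaction"],
            "sig_methionine": r.p_values["methionine"] < alpha,
            "sig_lineage": r.p_values["lineage"] < alpha,
            "sig_interaction": r.p_values["interaction"] < alpha,
            "var_cpg": r.var_cpg, "var_resid": r.var_resid,
            "ols_fallback": r.ols_fallback,
        }
        row.update({f"mean_{k}": v for k, v in r.cell_means.items()})
        rows.append(row)
    return pd.DataFrame(rows)
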
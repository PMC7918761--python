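"""Synthetic RRBS dataset generator with known ground truth.

Emulates the structure of a blastocyst methylome experiment: 12 samples
(3 replicates × {ICM, TE} lineages × {10, 50} µM added methionine), each a
bismark-style ``.cov`` coverage file of per-CpG methylated/unmethylated
read counts, plus the annotation side-files the downstream stages need
(GFF3 gene models, CpG-island BED, variant-position BED, GMT gene sets, an
imprinted-gene panel) and a ``truth.json``/``truth_sites.tsv`` pair
recording every planted signal.

What is emulated: negative-binomial per-site coverage; bimodal baseline
methylation (CpG-island sites low, gene-body sites high); beta-binomial
replicate overdispersion; treatment-induced shifts of a fixed size
concentrated in designated affected genes, some with a dense ≥5-CpG
cluster inside a 1 kb window; a disjoint set of lineage-differential CpGs;
known variant positions to mask; and a fully unmethylated spike-in contig
whose apparent methylation equals the bisulfite conversion-failure rate.

What is not emulated: read-level artefacts (alignment, mate overlap,
quality trimming), MspI fragment geometry, strand asymmetry, and any
correlation structure between neighbouring CpGs beyond the planted
clusters.

All randomness derives from the mandatory ``seed``; the same design
produces byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticDesign",
    "GroundTruth",
    "LINEAGES",
    "METHIONINE_LEVELS",
    "sample_table",
    "generate",
    "write_annotation",
    "design_from_toml",
    "simulate_imprint_gene",
]

LINEAGES = ("ICM", "TE")
METHIONINE_LEVELS = (10, 50)
N_REPLICATES = 3
SPIKEIN_CONTIG = "lambda_spike"
SPIKEIN_LENGTH = 48_502  # λ-phage genome size


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of one synthetic experiment.

    Defaults describe the study conditions the pipeline is meant to
    exercise: coverage mean 30, n = 3 replicates per group, treatment
    shifts of 30 percentage points (mostly losses at low methionine)
    concentrated in 20 affected genes of which 8 carry a dense cluster,
    replicate-level beta-binomial overdispersion ρ = 0.01, and a 1%
    bisulfite conversion-failure rate on the unmethylated spike-in.
    """

    seed: int
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 100
    gene_length: int = 6_000
    promoter_window: int = 1_000
    n_cpg_sites: int = 6_000
    coverage_mean: float = 30.0
    coverage_dispersion: float = 8.0     # negative-binomial size parameter
    low_mode: float = 0.08               # island baseline methylation
    high_mode: float = 0.92              # gene-body/open-sea baseline
    n_affected_genes: int = 20
    effect_size: float = 30.0            # percentage points, 10 vs 50 µM
    frac_gain: float = 0.2               # fraction of affected genes gaining
    n_shifted_cpgs: int = 10             # shifted CpGs per affected gene
    n_cluster_genes: int = 8             # affected genes with a 1 kb cluster
    cluster_window: int = 1_000
    n_lineage_cpgs: int = 100            # ICM-vs-TE differential sites
    lineage_effect: float = 30.0
    n_variant_positions: int = 50
    n_spikein_sites: int = 300
    conversion_failure_rate: float = 0.01
    overdispersion: float = 0.01         # beta-binomial ρ across replicates

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit seed is mandatory")
        if not (-100 < self.effect_size < 100):
            raise ValueError("effect size must be in (-100, 100)")
        if self.coverage_mean < 5:
            raise ValueError("coverage_mean must be >= 5")
        if self.n_cpg_sites <= 0 or self.n_genes <= 0:
            raise ValueError("degenerate design: need sites and genes")
        if self.n_cluster_genes > self.n_affected_genes:
            raise ValueError("n_cluster_genes cannot exceed n_affected_genes")


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream scoring."""

    spikein_contig: str
    conversion_failure_rate: float
    variant_positions: list[tuple[str, int]]
    treatment_dmcs: list[tuple[str, int, float]]   # (chrom, pos, effect pts)
    lineage_dmcs: list[tuple[str, int, float]]
    affected_genes: list[dict]                     # gene_id, effect, clustered, window
    cluster_genes: list[str]
    panel_genes: list[str]
    site_proportions: pd.DataFrame                 # chrom, pos, p_<lineage>_<met> ×4

    def treatment_dmc_set(self) -> set[tuple[str, int]]:
        return {(c, p) for c, p, _ in self.treatment_dmcs}

    def lineage_dmc_set(self) -> set[tuple[str, int]]:
        return {(c, p) for c, p, _ in self.lineage_dmcs}

    def to_json(self, path) -> None:
        payload = {
            "spikein_contig": self.spikein_contig,
            "conversion_failure_rate": self.conversion_failure_rate,
            "variant_positions": [list(v) for v in self.variant_positions],
            "treatment_dmcs": [list(v) for v in self.treatment_dmcs],
            "lineage_dmcs": [list(v) for v in self.lineage_dmcs],
            "affected_genes": self.affected_genes,
            "cluster_genes": self.cluster_genes,
            "panel_genes": self.panel_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def from_json(path, site_proportions=None) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return GroundTruth(
            d["spikein_contig"], d["conversion_failure_rate"],
            [tuple(v) for v in d["variant_positions"]],
            [tuple(v) for v in d["treatment_dmcs"]],
            [tuple(v) for v in d["lineage_dmcs"]],
            d["affected_genes"], d["cluster_genes"], d["panel_genes"],
            site_proportions if site_proportions is not None else pd.DataFrame(),
        )


def sample_table() -> pd.DataFrame:
    """The fixed 12-sample design: 3 replicates × 2 lineages × 2 doses."""
    rows = [
        {"sample": f"{lin}_{met}_rep{r}", "lineage": lin,
         "methionine": met, "replicate": r}
        for lin in LINEAGES for met in METHIONINE_LEVELS
        for r in range(1, N_REPLICATES + 1)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genome layout


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    second_transcript: bool


def _layout_genes(design: SyntheticDesign) -> list[_Gene]:
    genes: list[_Gene] = []
    per_chrom = design.n_genes // design.n_chromosomes
    extra = design.n_genes - per_chrom * design.n_chromosomes
    gi = 0
    for ci in range(design.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n_here = per_chrom + (1 if ci < extra else 0)
        slot = (design.chrom_length - 20_000) // max(n_here, 1)
        glen = min(design.gene_length, max(slot - 4_000, 2_000))
        for k in range(n_here):
            start = 10_000 + k * slot
            end = start + glen - 1
            strand = "+" if gi % 2 == 0 else "-"
            third = glen // 3
            exons = [
                (start, start + third // 2),
                (start + third + third // 4, start + third + 3 * third // 4),
                (end - third // 2, end),
            ]
            genes.append(_Gene(f"G{gi:04d}", chrom, start, end, strand,
                               exons, second_transcript=(gi % 10 == 0)))
            gi += 1
    return genes


def _place_cpgs(design: SyntheticDesign, genes: list[_Gene],
                rng: np.random.Generator) -> pd.DataFrame:
    """Place CpG sites in genes/promoters and intergenic space."""
    n_intergenic = design.n_cpg_sites // 5
    n_genic = design.n_cpg_sites - n_intergenic
    base_per_gene = n_genic // len(genes)

    chrom_pos: list[tuple[str, int]] = []
    gene_of_site: list[str | None] = []
    for g in genes:
        lo = max(1, g.start - design.promoter_window // 2)
        hi = g.end
        pos = rng.integers(lo, hi + 1, size=base_per_gene)
        for p in np.unique(pos):
            chrom_pos.append((g.chrom, int(p)))
            gene_of_site.append(g.gene_id)
    # intergenic sites: uniform over each chromosome, rejected if near a gene
    gene_iv: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        gene_iv.setdefault(g.chrom, []).append(
            (g.start - design.promoter_window, g.end + design.promoter_window))
    for ci in range(design.n_chromosomes):
        chrom = f"chr{ci + 1}"
        want = n_intergenic // design.n_chromosomes
        got = 0
        while got < want:
            p = int(rng.integers(1, design.chrom_length))
            if any(s <= p <= e for s, e in gene_iv.get(chrom, [])):
                continue
            chrom_pos.append((chrom, p))
            gene_of_site.append(None)
            got += 1

    sites = pd.DataFrame(chrom_pos, columns=["chrom", "pos"])
    sites["gene"] = gene_of_site
    return (sites.drop_duplicates(subset=["chrom", "pos"])
                 .sort_values(["chrom", "pos"]).reset_index(drop=True))


def _make_islands(design: SyntheticDesign, genes: list[_Gene],
                  ) -> list[tuple[str, int, int]]:
    """One island around 60% of TSSs plus a few intergenic islands.

    Gene slots are far apart, so islands never overlap one another."""
    islands: list[tuple[str, int, int]] = []
    for i, g in enumerate(genes):
        if i % 5 >= 3:
            continue
        tss = g.start if g.strand == "+" else g.end
        islands.append((g.chrom, max(1, tss - 400), tss + 400))
    for ci in range(design.n_chromosomes):
        chrom = f"chr{ci + 1}"
        for k in range(3):
            s = design.chrom_length - 8_000 - 3_000 * k
            islands.append((chrom, s, s + 600))
    return sorted(islands)


# ---------------------------------------------------------------------------
# signal planting


def _plant_effects(design: SyntheticDesign, genes: list[_Gene],
                   sites: pd.DataFrame, islands, rng: np.random.Generator):
    """Assign baselines and planted effects; may append cluster CpGs.

    Returns (sites, baseline, treat_eff, lin_eff, affected_meta), with the
    effect arrays as fractions (0.30 = 30 percentage points)."""
    # genes eligible to be affected need enough body CpGs to shift
    body_counts = sites.groupby("gene")["pos"].count()
    eligible = [g for g in genes
                if body_counts.get(g.gene_id, 0) >= design.n_shifted_cpgs]
    order = rng.permutation(len(eligible))
    chosen = [eligible[i] for i in order[: design.n_affected_genes]]
    n_gain = int(round(design.frac_gain * len(chosen)))
    effects = ([design.effect_size] * n_gain
               + [-design.effect_size] * (len(chosen) - n_gain))

    affected_meta: list[dict] = []
    extra_rows: list[tuple[str, int, str]] = []
    shifted: dict[tuple[str, int], float] = {}

    for j, (g, eff) in enumerate(zip(chosen, effects)):
        clustered = j < design.n_cluster_genes
        if clustered:
            # a dense run of shifted CpGs spanning <= cluster_window bp
            span = design.cluster_window
            ws = int(rng.integers(g.start + 200, g.end - span - 200))
            offs = np.sort(rng.choice(span, size=design.n_shifted_cpgs,
                                      replace=False))
            positions = [ws + int(o) for o in offs]
            for p in positions:
                extra_rows.append((g.chrom, p, g.gene_id))
            window = [g.chrom, positions[0], positions[-1]]
        else:
            own = sites.index[sites["gene"] == g.gene_id].to_numpy()
            pick = rng.choice(own, size=design.n_shifted_cpgs, replace=False)
            positions = [int(sites.at[int(i), "pos"]) for i in pick]
            window = None
        for p in positions:
            shifted[(g.chrom, p)] = eff
        affected_meta.append({
            "gene_id": g.gene_id, "effect": float(eff),
            "clustered": bool(clustered), "n_shifted": len(positions),
            "window": window,
        })

    if extra_rows:
        extra = pd.DataFrame(extra_rows, columns=["chrom", "pos", "gene"])
        sites = (pd.concat([sites, extra], ignore_index=True)
                   .drop_duplicates(subset=["chrom", "pos"])
                   .sort_values(["chrom", "pos"]).reset_index(drop=True))

    # baselines: island sites sit at the low mode, everything else high
    from intervaltree import Interval, IntervalTree
    island_trees: dict[str, IntervalTree] = {}
    for chrom, s, e in islands:
        island_trees.setdefault(chrom, IntervalTree()).add(Interval(s, e + 1))
    empty = IntervalTree()
    in_island = np.array([
        bool(island_trees.get(c, empty).at(p))
        for c, p in zip(sites["chrom"], sites["pos"])
    ])
    n = len(sites)
    baseline = np.where(
        in_island,
        rng.beta(2.0, 2.0 * (1 - design.low_mode) / design.low_mode, size=n),
        rng.beta(2.0 * design.high_mode / (1 - design.high_mode), 2.0, size=n),
    )
    baseline = np.clip(baseline, 0.02, 0.98)

    treat_eff = np.zeros(n)
    keymap = {(c, p): i
              for i, (c, p) in enumerate(zip(sites["chrom"], sites["pos"]))}
    for (c, p), eff in shifted.items():
        i = keymap[(c, p)]
        treat_eff[i] = eff / 100.0
        # re-draw the baseline so the shifted value stays inside (0, 1)
        baseline[i] = (rng.uniform(0.75, 0.95) if eff < 0
                       else rng.uniform(0.35, 0.60))

    # lineage effect at a disjoint in-gene subset
    lin_eff = np.zeros(n)
    candidates = np.array([i for i in range(n)
                           if treat_eff[i] == 0 and sites.at[i, "gene"] is not None])
    pick = rng.choice(candidates,
                      size=min(design.n_lineage_cpgs, len(candidates)),
                      replace=False)
    signs = np.where(rng.random(len(pick)) < 0.55, 1.0, -1.0)
    for i, s in zip(pick, signs):
        lin_eff[i] = s * design.lineage_effect / 100.0
        baseline[i] = (rng.uniform(0.75, 0.95) if s < 0
                       else rng.uniform(0.35, 0.60))

    return sites, baseline, treat_eff, lin_eff, affected_meta


# ---------------------------------------------------------------------------
# count sampling and file output


def _true_proportions(baseline, treat_eff, lin_eff):
    out = {}
    for lin in LINEAGES:
        for met in METHIONINE_LEVELS:
            p = baseline.copy()
            if met == 10:
                p = p + treat_eff
            if lin == "ICM":
                p = p + lin_eff
            out[(lin, met)] = np.clip(p, 0.01, 0.99)
    return out


def _sample_counts(p_true: np.ndarray, design: SyntheticDesign,
                   rng: np.random.Generator):
    n = len(p_true)
    size = design.coverage_dispersion
    cov = rng.negative_binomial(size, size / (size + design.coverage_mean), n)
    cov = np.maximum(cov, 1)
    rho = design.overdispersion
    if rho > 0:
        conc = (1.0 - rho) / rho
        p_rep = rng.beta(p_true * conc, (1.0 - p_true) * conc)
    else:
        p_rep = p_true
    meth = rng.binomial(cov, p_rep)
    return cov, meth


def _write_cov(path: Path, chroms, positions, meth, cov) -> None:
    with open(path, "w") as fh:
        for c, p, m, t in zip(chroms, positions, meth, cov):
            u = int(t) - int(m)
            pct = 100.0 * m / t
            fh.write(f"{c}\t{p}\t{p}\t{pct:.4f}\t{int(m)}\t{u}\n")


def write_annotation(design: SyntheticDesign, genes: list[_Gene], islands,
                     variant_positions, affected_meta, panel_genes,
                     out_dir: Path) -> None:
    """Write genes.gff3, cpg_islands.bed, variants.bed, sets.gmt and the
    imprinted-gene panel TSV for one generated genome."""
    rng = np.random.default_rng(design.seed + 1)  # decoy-set sampling only
    with open(out_dir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tmet1c\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(f"{g.chrom}\tmet1c\tmRNA\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n")
            for xi, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tmet1c\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.t1.e{xi};Parent={g.gene_id}.t1\n")
            if g.second_transcript:
                # alternative promoter: transcript over exons 2-3 only
                s2 = g.exons[1][0] if g.strand == "+" else g.start
                e2 = g.end if g.strand == "+" else g.exons[1][1]
                fh.write(f"{g.chrom}\tmet1c\tmRNA\t{s2}\t{e2}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.t2;Parent={g.gene_id}\n")
                for xi, (s, e) in enumerate(g.exons, 1):
                    if s2 <= s and e <= e2:
                        fh.write(f"{g.chrom}\tmet1c\texon\t{s}\t{e}\t.\t"
                                 f"{g.strand}\t.\t"
                                 f"ID={g.gene_id}.t2.e{xi};Parent={g.gene_id}.t2\n")

    with open(out_dir / "cpg_islands.bed", "w") as fh:
        for chrom, s, e in islands:
            fh.write(f"{chrom}\t{s - 1}\t{e}\n")  # 1-based inclusive -> BED

    with open(out_dir / "variants.bed", "w") as fh:
        for chrom, p in variant_positions:
            fh.write(f"{chrom}\t{p - 1}\t{p}\n")

    affected_ids = [m["gene_id"] for m in affected_meta]
    others = [g.gene_id for g in genes if g.gene_id not in affected_ids]
    decoy_pool = others if len(others) >= 15 else [g.gene_id for g in genes]
    with open(out_dir / "sets.gmt", "w") as fh:
        if affected_ids:
            fh.write("affected_set\tdesigned differentially methylated genes\t"
                     + "\t".join(affected_ids) + "\n")
        for k in range(10):
            decoy = sorted(rng.choice(decoy_pool,
                                      size=min(15, len(decoy_pool)),
                                      replace=False))
            fh.write(f"decoy_{k:02d}\trandom background set\t"
                     + "\t".join(decoy) + "\n")

    by_id = {g.gene_id: g for g in genes}
    with open(out_dir / "imprinted_panel.tsv", "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\n")
        for gid in panel_genes:
            g = by_id[gid]
            fh.write(f"{gid}\t{g.chrom}\t{g.start}\t{g.end}\n")


def generate(design: SyntheticDesign, out_dir) -> GroundTruth:
    """Generate a full dataset directory and return its ground truth.

    Writes ``<sample>.cov`` for the 12 samples, ``samples.tsv``, the
    annotation side-files, ``truth.json`` and ``truth_sites.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(design.seed)

    genes = _layout_genes(design)
    sites = _place_cpgs(design, genes, rng)
    islands = _make_islands(design, genes)
    sites, baseline, treat_eff, lin_eff, affected_meta = _plant_effects(
        design, genes, sites, islands, rng)

    # variant positions: real CpG sites, disjoint from planted effects
    clean = np.flatnonzero((treat_eff == 0) & (lin_eff == 0))
    vpick = np.sort(rng.choice(
        clean, size=min(design.n_variant_positions, len(clean)), replace=False))
    variant_positions = [(sites.at[int(i), "chrom"], int(sites.at[int(i), "pos"]))
                         for i in vpick]

    # imprinted-style panel: two affected genes plus eight unaffected ones
    affected_ids = [m["gene_id"] for m in affected_meta]
    unaffected = [g.gene_id for g in genes if g.gene_id not in affected_ids]
    panel_genes = affected_ids[:2] + [
        str(x) for x in rng.choice(unaffected,
                                   size=min(8, len(unaffected)),
                                   replace=False)]

    props = _true_proportions(baseline, treat_eff, lin_eff)

    # spike-in contig: fully unmethylated; apparent methylation is purely
    # conversion failure
    spike_pos = np.sort(rng.choice(
        np.arange(100, SPIKEIN_LENGTH - 100), size=design.n_spikein_sites,
        replace=False))

    designtab = sample_table()
    for row in designtab.itertuples(index=False):
        key = (row.lineage, row.methionine)
        cov, meth = _sample_counts(props[key], design, rng)
        s_cov, s_meth = _sample_counts(
            np.full(design.n_spikein_sites, design.conversion_failure_rate),
            design, rng)
        chroms = list(sites["chrom"]) + [SPIKEIN_CONTIG] * design.n_spikein_sites
        positions = list(sites["pos"]) + [int(p) for p in spike_pos]
        _write_cov(out / f"{row.sample}.cov", chroms, positions,
                   np.concatenate([meth, s_meth]),
                   np.concatenate([cov, s_cov]))
    designtab.to_csv(out / "samples.tsv", sep="\t", index=False)

    write_annotation(design, genes, islands, variant_positions, affected_meta,
                     panel_genes, out)

    treatment_dmcs = [
        (sites.at[int(i), "chrom"], int(sites.at[int(i), "pos"]),
         float(treat_eff[i] * 100))
        for i in np.flatnonzero(treat_eff != 0)
    ]
    lineage_dmcs = [
        (sites.at[int(i), "chrom"], int(sites.at[int(i), "pos"]),
         float(lin_eff[i] * 100))
        for i in np.flatnonzero(lin_eff != 0)
    ]
    site_props = sites[["chrom", "pos"]].copy()
    for (lin, met), p in props.items():
        site_props[f"p_{lin}_{met}"] = np.round(p, 6)
    site_props.to_csv(out / "truth_sites.tsv", sep="\t", index=False)

    truth = GroundTruth(
        spikein_contig=SPIKEIN_CONTIG,
        conversion_failure_rate=design.conversion_failure_rate,
        variant_positions=variant_positions,
        treatment_dmcs=treatment_dmcs,
        lineage_dmcs=lineage_dmcs,
        affected_genes=affected_meta,
        cluster_genes=[m["gene_id"] for m in affected_meta if m["clustered"]],
        panel_genes=list(panel_genes),
        site_proportions=site_props,
    )
    truth.to_json(out / "truth.json")
    return truth


def design_from_toml(path) -> SyntheticDesign:
    import tomllib
    with open(path, "rb") as fh:
        return SyntheticDesign(**tomllib.load(fh))


# ---------------------------------------------------------------------------
# small Gaussian simulator for the imprinted-gene mixed model


def simulate_imprint_gene(
    seed: int, n_cpgs: int = 8, cpg_sd: float = 0.10, resid_sd: float = 0.05,
    interaction: float = 0.15, met_effect: float = 0.0, lin_effect: float = 0.0,
    grand_mean: float = 0.5,
) -> pd.DataFrame:
    """Per-CpG, per-sample methylation proportions for one gene under the
    random-intercept model the imprint module fits.

    The interaction term adds ``interaction`` to the (10 µM, ICM) cell.
    Values are clipped to [0, 1] (rarely active at the default scales).
    """
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, cpg_sd, n_cpgs)
    rep_eff = rng.normal(0.0, 0.02, N_REPLICATES)
    rows = []
    for lin in LINEAGES:
        for met in METHIONINE_LEVELS:
            for r in range(N_REPLICATES):
                mu = (grand_mean + rep_eff[r]
                      + (met_effect if met == 10 else 0.0)
                      + (lin_effect if lin == "ICM" else 0.0)
                      + (interaction if (met == 10 and lin == "ICM") else 0.0))
                y = mu + b + rng.normal(0.0, resid_sd, n_cpgs)
                for ci in range(n_cpgs):
                    rows.append({
                        "gene": "SIM", "cpg": f"cpg{ci:03d}",
                        "sample": f"{lin}_{met}_rep{r + 1}",
                        "replicate": r + 1, "lineage": lin, "methionine": met,
                        "y": float(np.clip(y[ci], 0.0, 1.0)),
                    })
    return pd.DataFrame(rows)
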
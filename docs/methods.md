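# Methods

## 1. Kinetic model of the methionine cycle

### States, inputs and stoichiometry

Four state variables (µM): methionine (Met), S-adenosylmethionine (SAM),
S-adenosylhomocysteine (SAH), homocysteine (Hcy).  Time is in hours,
fluxes in µM·h⁻¹; unit conversions are the caller's responsibility.
Folate (5-methyl-THF), betaine and adenosine are held constant — they are
inputs, not states — because the question the model answers concerns
methionine-cycle dynamics under substrate/cofactor provision, not folate
cycle dynamics.

```
dMet/dt = V_in(t) + V_MTR + V_BHMT − V_MATI − V_MATII − V_MATIII
dSAM/dt = V_MATI + V_MATII + V_MATIII − V_GNMT − V_DNMT
dSAH/dt = V_GNMT + V_DNMT − V_AHCY
dHcy/dt = V_AHCY − V_MTR − V_BHMT − V_CBS
```

Summing the four equations, every internal flux cancels:
d(Met+SAM+SAH+Hcy)/dt = V_in − V_CBS.  One-carbon backbone enters only
through the methionine input and leaves only through transsulfuration
(CBS).  This conservation law is asserted numerically (< 1e-8 µM·h⁻¹)
along every test trajectory.

### Rate laws

The rate laws encode the canonical regulatory motifs of the hepatic
methionine-cycle model family rather than any specific published
parameterisation:

| Flux | Form | Motif |
|---|---|---|
| V_MATI  | vmax·Met/(Km+Met)·Ki/(Ki+SAM) | SAM product inhibition |
| V_MATII | vmax·Met/(Km+Met)·Ki/(Ki+SAM) | low Km for Met (extra-hepatic isoform) |
| V_MATIII| vmax·Met/(Km+Met)·(1+α·SAM²/(Ka²+SAM²)) | SAM feed-forward activation |
| V_GNMT  | vmax·SAM²/(Km²+SAM²)·Ki/(Ki+SAH) | cooperative SAM overflow valve, SAH inhibited |
| V_DNMT  | vmax·SAM/(Km+SAM)·Ki/(Ki+SAH) | generic SAM-dependent transmethylation (the reported flux) |
| V_AHCY  | k_f·SAH − k_r·Hcy·Ado | reversible mass action, fixed adenosine |
| V_CBS   | k·Hcy·(SAM+SAH)²/(Ka²+(SAM+SAH)²) | transsulfuration activated by methylation load |
| V_MTR   | vmax·Hcy/(Km+Hcy)·5mTHF/(Km₂+5mTHF) | folate/B12-dependent remethylation |
| V_BHMT  | vmax·Hcy/(Km+Hcy)·Bet/(Km₂+Bet) | betaine-dependent remethylation |

An enzyme with `present = false` contributes exactly zero flux and is
bitwise-equivalent to `vmax = 0` (tested).

### Parameters

Defaults live in `src/met1c/params/default.toml` (one section per enzyme,
units µM and µM·h⁻¹).  They are package defaults tuned once for a
physiologically plausible hepatic operating point — at a constant input of
50 µM·h⁻¹ the steady state is Met ≈ 11, SAM ≈ 31, SAH ≈ 2.4, Hcy ≈ 10 µM
with transmethylation ≈ 76 µM·h⁻¹ split ≈ 80/20 between V_DNMT and
V_GNMT — not literature constants, and no claim of parameter-exact
reproduction of any published steady state is made.  Two presets encode
cell types: `hepatic` (all enzymes present) and `follicular` (MATII as the
only MAT isoform; MATI, MATIII and BHMT absent), matching the reported
expression pattern of liver versus ovarian follicle/embryo.  MATII is kept
present in the hepatic preset because its transcript is ubiquitous.

### Input protocols and the volatility metric

`InputProtocol` supports constant, step, and sinusoid methionine supply,
V_in(t) = V₀·(1 + a·sin 2πt/T) with 0 ≤ a < 1.  All three 1C provision
channels can be perturbed: the methionine input directly, and the folate
and betaine pools through the profile.

Volatility of a flux is its relative amplitude (max − min)/mean measured
at the periodically forced attractor: the simulation starts from the
constant-input steady state, the first 5 forcing periods are discarded as
transient and the next 3 analysed (both counts configurable; 5+3 is ample
at the default time scales, where transients decay within ~2 periods).
The module's core reproducible claim is an ordering, not a magnitude:
for forcing amplitudes in [0.1, 0.5] the BHMT-absent system's V_DNMT
relative amplitude strictly exceeds the BHMT-present system's (ratio ≈1.6
at the defaults).  The mechanism is buffering: BHMT recycles Hcy to Met
with a supply-independent methyl donor, damping Met (hence SAM, hence
V_DNMT) excursions when the external input swings.

### Numerics

LSODA with rtol 1e-8 / atol 1e-10; states clipped at 0 before rate
evaluation to keep the solver out of the (physically meaningless) negative
orthant; reported non-negativity is asserted to −1e-9 µM.  Steady states
are found by `scipy.optimize.root` (hybr) seeded from a 3,000 h
integration and accepted only if ‖rhs‖∞ < 1e-10 µM·h⁻¹ — otherwise an
explicit `SolverError` is raised (removing every Hcy exit route with a
positive input, for example, is flagged as non-physiological rather than
silently returning the best iterate).  The integrator limit and the root
agree to < 1e-6 µM per metabolite (tested).

## 2. Synthetic RRBS generator

The generator emulates the *structure* of a 12-library blastocyst RRBS
experiment — 3 replicates × {ICM, TE} × {10, 50 µM} — at desk scale:

* genome: 2 chromosomes × 1 Mb, 100 non-overlapping genes (3 exons,
  alternating strand, every 10th gene with a second transcript that has
  an internal alternative promoter), CpG islands at 60 % of TSSs plus a
  few intergenic ones;
* ~6,000 CpG sites (80 % in genes/promoters, 20 % intergenic);
* coverage ~ negative binomial (mean 30, size 8), truncated ≥1;
* baseline methylation bimodal: island sites low (mode 0.08), other sites
  high (mode 0.92), Beta-distributed around the modes;
* methylated counts ~ beta-binomial around the group-true proportion with
  replicate-level overdispersion ρ = 0.01 (realistic, detectable noise at
  n = 3);
* treatment signal: 20 affected genes, each with 10 CpGs shifted 30
  percentage points at 10 vs 50 µM (80 % losses — hypomethylation at low
  methionine — 20 % gains); 8 of the 20 carry their shifted CpGs inside a
  single ≤1 kb window (the designed cluster genes).  Shifted-site
  baselines are drawn from U(0.75, 0.95) for losses and U(0.35, 0.60)
  for gains so the shifted proportion stays inside (0, 1) without
  clipping;
* lineage signal: 100 disjoint in-gene CpGs shifted ±30 points between
  ICM and TE, so all four contrasts carry signal;
* 50 known-variant positions (real CpG sites, disjoint from planted
  signal) to exercise masking;
* a 48.5 kb unmethylated spike-in contig (300 sites) whose apparent
  methylation equals the simulated 1 % bisulfite conversion-failure rate;
* GMT sets: one `affected_set` holding all affected genes plus 10 random
  decoys; an "imprinted" panel of 10 genes of which 2 are affected.

Everything derives from one mandatory seed; identical designs produce
byte-identical files (integer counts, fixed float formatting).

**What passing tests do not show about real data:** the generator has no
read-level artefacts (mapping error, mate overlap, incomplete-conversion
gradients along reads), no MspI fragment geometry (coverage is i.i.d.
across sites rather than fragment-correlated), no strand asymmetry, no
correlation between neighbouring CpGs beyond the planted clusters, and
effect sizes are homogeneous.  Recovery rates measured here are therefore
upper bounds on what identical settings would achieve on real libraries.

## 3. Per-CpG differential test

For each united CpG the methylated/coverage counts are modelled as
binomial with a group factor; the reported statistic is the 1-df deviance
(likelihood-ratio) chi-squared.  Because the binomial MLE under a lone
group factor pools counts within each group, this is algebraically the
classical G-test on the pooled 2×2 table; both code paths exist
(`mode="deviance"` per-sample terms, `mode="pooled"` 2×2) and the tests
assert their identity and the match to an independently written
closed-form oracle (< 1e-10).  Group means are pooled
methylated/coverage; q-values are Benjamini–Hochberg over all tested
sites; q ≤ 0.05 is the default threshold (exposed as a flag — the
original workflow's threshold is not derivable from count data alone).
Strands are not merged; positions are compared as given.  Read-level
filters (mapping quality ≥ 20, mate-overlap de-duplication) are upstream
of count extraction and cannot be re-applied at count level; counts are
taken as final.

The DMC filter keeps q ≤ 0.05 AND |Δ| strictly > 20 percentage points AND
location in a gene body or promoter.  A 20.0-point difference is dropped
(strict inequality, tested).

**Calibration and power.**  On binomial null data (ρ = 0) the test's
type-I error at nominal 0.05 sits in [0.03, 0.07] (asserted); with the
default ρ = 0.01 the pooled statistic is anticonservative (variance
inflation ≈ 1 + (c̄−1)ρ ≈ 1.29 at coverage 30), which shows up not as
excess final false positives — the >20-point and in-gene filters absorb
them (empirical FDR ≈ 0.03) — but as reduced effective power: at Δ = 30
points, 3 replicates of coverage ~30 per group, the BH-adjusted detection
threshold sits around 21–22 points and per-site sensitivity lands near
0.80–0.86 (the acceptance script reports the measured value).  This is a
property of the study conditions, not of the implementation.

## 4. Genomic annotation

Promoter = TSS −1000/+1000 bp strand-aware; CpG shores = 2 kb island
flanks clipped against all islands — standard annotation-package defaults,
configurable and echoed in output headers.  Precedence: promoter > exon >
intron on the gene axis (ties across genes broken by nearest TSS, then
transcript id for determinism); island > shore > open sea on the CpG
axis.  Internal coordinates are 1-based inclusive; BED input is converted
at the boundary, with off-by-one tests at interval edges.  Introns are
gene body minus exons.  A brute-force per-base labelling oracle checks
thousands of random positions on every fixture.

## 5. DMC clustering and enrichment

A gene qualifies when ≥5 of its DMC positions fit in one 1 kb window:
on sorted positions, pos[i+4] − pos[i] ≤ 1000 for some i (inclusive
span).  The window slides over DMC positions only, not all CpGs — the
stricter and more literal reading; the best window is the densest, ties
leftmost.  An exhaustive window-enumeration oracle confirms the decision
on 1,000 random fixtures.

Enrichment: for each GMT term, p = P(X ≥ k) under
Hypergeometric(N, K, n), BH-corrected across tested terms; K = 0 terms
are skipped and counted.  The default universe is genes with ≥1 tested
CpG in gene/promoter, not the genome: RRBS covers a biased subset and a
genome-wide universe would inflate significance (override available).
Report ranking follows the "most differentially methylated genes of
interest" convention: significant terms (FDR ≤ 0.05) sorted by k
descending, ties by FDR ascending, top 5.

## 6. Imprinted-gene mixed models

Per gene: y ~ replicate + methionine × lineage with a random intercept
per CpG, fitted by REML (statsmodels MixedLM); y is the raw per-sample,
per-CpG methylation proportion (an arcsine-square-root option exists
behind a flag; none is applied by default because proportions here are
far from the boundaries where the transform matters).  Wald tests on the
fixed effects; the reporting threshold for flags is p < 0.001.  Genes
need ≥2 CpGs and all four treatment cells.  A boundary fit (zero CpG
variance) falls back to OLS with an explicit flag.  Cell means are
model predictions averaged over replicate levels.  Estimates are
invariant to CpG relabelling and row order, and equal the GLS solution at
the fitted variance components (both tested).  Null calibration: the
interaction false-positive rate over 500 simulated null genes lies in
[0.02, 0.09] at nominal 0.05.

Whether to model per-sample proportions or per-CpG averages was an open
choice; per-sample proportions are used because they retain replicate
information the averages would discard.

## 7. Pipeline and problem sizes

`run_all` executes the four contrasts (methionine within each lineage,
lineage within each methionine level; "gain" = higher in 10 µM or ICM),
then clustering + enrichment for the two methionine contrasts and the
imprinted-panel models, writing per-stage TSVs and a versioned
`summary.json`.  Runs are deterministic given the seed and each stage is
re-runnable from intermediates.

Default problem sizes — 6,000 CpGs, 100 genes, 12 samples, 2,000-site
null fixtures, 50-seed mixed-model recovery, 300–500-run null studies —
were chosen so a full pipeline run takes ~2 s and the entire test suite
well under a minute, while keeping Monte-Carlo standard errors small
relative to the asserted tolerances.

## 8. Known limitations

* The kinetic model is constitutive-enzyme only: the observed MAT2A
  transcriptional up-regulation at low methionine is deliberately out of
  scope, and its parameters are illustrative defaults.
* The generator's independence assumptions (Section 2) make recovery
  metrics optimistic relative to real RRBS libraries.
* The pooled chi-squared test does not model replicate overdispersion;
  beta-binomial/dispersion-shrinkage tests are out of scope by design.
* Region-level (DMR) calling beyond the 1 kb cluster rule, SLIM
  q-values, GO DAG propagation and KEGG API access are non-goals.
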
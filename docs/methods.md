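# Methods

This note documents the models, conventions and numerical choices behind
`gliotraj`, in the spirit of the methods documentation of mature trajectory
and statistics packages. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and model of the data

The package targets staged expression time courses of gliomagenesis from
engineered human neural stem cells: four stages (T0 = starting hNSCs, T1 and
T2 = one and two months post transplantation, End = end-stage tumor), bulk or
pseudo-bulk profiles per sample, and single cells labelled by sample and
stage. Eight neural cell states organise the analysis — cycling and
non-cycling embryonic NSC-like states (NSC_cc, NSC_ncc), adult-type active and
quiescent NSC states (aNSC_adult, qNSC_adult), astrocytes (AC),
oligodendrocyte-lineage states (OPC, OC) and neuroblasts/neurons (NB_Neuron) —
each represented by a gene module. The central biological object is the
persistent cycling NSC-like pool (roughly 11–17% of cells from T1 onward) and
the sequence of lineages it generates: neurons at T1, astrocytes at T2,
oligodendrocytes at End.

## ssGSEA scoring and the empirical null

Genes are ranked by expression descending, ties broken by stable
gene-identifier order so scores are platform-independent. With N genes, set
positions S and rank weights r_i = N − position_i + 1, the enrichment score is
the running sum ES = Σ_i [P_hit(i) − P_miss(i)] with P_hit weighted by r^τ
(τ = 0.25, the exponent customary for this scoring family; exposed in the
config) and P_miss the uniform out-of-set step. Ranks rather than raw values
are used as weights, making the score invariant to monotone transforms of the
profile.

The null distribution for a profile is the set of ES values of random gene
sets of matched size drawn uniformly without replacement from the profile's
genes (default 100,000 draws). Two algebraically identical forms are
implemented: the cumulative-sum definition for single scores, and a closed
form for the null —

ES = Σ_{j∈S} w_j r_j / Σ_{j∈S} w_j − Σ_{j∉S} r_j / (N − |S|),  w_j = r_j^τ

— which reduces each draw to three gathered sums and makes 100,000-draw nulls
effectively free. Because the null depends on the profile only through the
set size, signatures of equal size share one null per profile; identical
signatures therefore receive identical evidence and tie exactly. The
empirical p is upper-tail with add-one smoothing, p = (1 + #{null ≥ ES}) /
(1 + n_draws), so p = 0 is impossible and −log10 p is always finite. The
subtype call is the argmax of −log10 p; ties fall back to higher raw ES, then
lexicographic signature name, and a call decided by name alone is flagged
ambiguous.

The empirical null could also be built by permuting expression values
rather than sampling gene sets; matched-size gene-set sampling was chosen
because it preserves the profile's rank structure, which the
empirical-p interpretation requires. Calibration is verified empirically: the
p-value of a randomly drawn "true" set is uniform (KS test in the test suite
and acceptance script).

Per-cell subtype heat maps use the meta-module score (mean normalised
expression of the signature genes, z-scaled across cells), not per-cell
ssGSEA: the per-cell quantity of interest is a module intensity, and running
a 100,000-draw null per cell would be computationally disproportionate.

## Preprocessing conventions

QC keeps cells with ≥500 detected genes (count > 0 — "gene count" means
detected genes, not total UMIs) and mitochondrial fraction ≤25%, both
computed on raw counts before any filtering, which makes the filter
idempotent. Mitochondrial genes are recognised by the `MT-` prefix.
Normalisation is log1p(10,000 × count / library size) with natural log; DEG
fold-changes elsewhere use log2. The two bases live in different containers
(`NormalizedMatrix` vs the `log2fc` column of stat tables) precisely so they
cannot be conflated. Pseudo-bulk aggregation always sums raw counts — the
test suite contains a guard documenting that aggregate-then-normalise and
normalise-then-aggregate do not commute.

The combined cell-cycle score is max(G1/S score, G2/M score): a cell is
cycling if it is high in either phase program; the source convention for the
combination is not fixed anywhere, and max is the choice here. Regression
against the cell-cycle score is OLS with intercept, returning residual +
intercept (slope contribution removed, location preserved); a constant
covariate returns the input unchanged with a warning.

## Stage-specific genes and DEG filtering

Stage assignment: per-gene stage means of normalised expression, plus a 0.01
pseudocount before ratios so zero-expression stages leave the fold defined;
the gene is assigned to its max-mean stage and called stage-specific iff the
max mean is ≥1.2× the largest other stage mean (inclusive boundary —
"attaining the fold" counts). The DEG filter is separate and strict on both
sides: padj < 0.05 and |log2FC| > 1.2 (a log2 threshold, not a linear one).
The bundled producer of DEG tables is a two-sided rank-sum test with
Benjamini–Hochberg adjustment and a 0.01 pseudocount on group means; any
table with `padj` and `log2fc` columns is accepted, so model-based producers
plug in unchanged.

## Trajectory reconstruction

The kNN graph (default k = 200, auto-capped at n_cells − 1 on small data)
uses Euclidean distances on whatever representation is supplied — normalised
expression or an embedding; inside the bundled pipeline a 20-component PCA is
used as plumbing. Edges are the union of neighbourhoods (symmetric); the
kernel is exp(−d²/(σ_i σ_j)) with the locally adaptive bandwidth σ_i =
distance to the ⌈k/2⌉-th neighbour — one concrete instance of the locally
adaptive ("local") sigma family, for which no single canonical rule exists;
σ has a
small floor against duplicate points. The diffusion map is the
eigendecomposition of the row-normalised transition operator via its
symmetric conjugate, with a deterministic Lanczos start vector, eigenvalues
sorted descending, the trivial constant eigenpair dropped, and a
largest-entry-positive sign convention.

Pseudotime is an iterative flood from the declared root cells: in each of 100
iterations, half of the edges are kept at random and cells are reached in
waves, each newly reached cell's time being the mean over its already-reached
kept neighbours of (neighbour time + edge distance); per-cell times are
averaged over iterations, roots sit at exactly 0, and the result is scaled to
[0, 1]. Cells never reached carry NaN and are flagged. Iteration count and
subsample fraction are configurable; the defaults trade smoothness against
runtime and are validated by the recovery tests.

Branch assignment sends biased random walks from each tip toward the root:
steps go to neighbours with probability proportional to edge weight,
restricted to neighbours whose pseudotime is at most current + window. Two
defaults here deliberately differ from a naive reading of the procedure and
were set by measurement on the canonical Y-shaped fixture: the window is the
25th percentile of per-edge pseudotime increments (a wide window barely
biases the walk, which then lingers near branch points and cross-visits the
other arm; a zero window stalls on noisy pseudotime), and the step cap is 50×
a double-BFS diameter estimate (hitting times of weakly biased walks exceed
the hop diameter by an order of magnitude). Only walks that actually reach
the root vote; more than 5% non-terminating walks is an error advising
parameter changes. A cell visited by ≥30% of one tip's walks and no other's
joins that tip's branch; by two or more tips', the shared segment; otherwise
it is unassigned. Tip cells always carry their own label.

Stage-correlation mapping computes, for each query cell, the mean Pearson r
against reference cells of each stage over a stage-specific gene panel
(≥10 shared genes required). The label is the top stage, or the hybrid
"X/Y-like" when the top two differ by <0.05 (the margin is a package choice;
hybrid labels are used in the field without a standard margin rule), and is
flagged low-confidence when the best mean r is below 0.1.

## Clonal quantifications

T7EI indel percentage: 100 × (1 − √(1 − (b+c)/(a+b+c))) from gel band
intensities, the square root inverting two-allele duplex formation. TMB is
non-silent mutations divided by the capture target size in Mb. The
inter-gRNA-site depth ratio is the mean per-base depth on [site1, site2)
divided by the mean over 200 bp flanks on each side (the comparison window is
a package choice formalising an otherwise qualitative observation), with a
seeded 1,000-resample position bootstrap for the 95% CI — positions, not
reads, because only per-base depth is available. The trend verdict is
"progressive reduction" iff the stage ratios are monotonically non-increasing
and the total decline exceeds the mean CI width.

## The synthetic-data generator

`SimulationDesign` encodes the study conditions: stages T0/T1/T2/End; eight
populations with stage frequency vectors summing to 1, including a cycling
NSC pool at 0.15 from T1 onward, an NB/Neuron burst at T1 (0.48), an AC burst
at T2 (0.45) and an OPC+OC burst at End (0.50 combined); 2,000 cells and
2,000 genes per stage across 3 samples per stage. Counts are negative
binomial with variance μ + μ²·d (d = 0.5) and baseline mean 2.0 per gene per
cell — about 4,000 UMIs per cell over the 2,000-gene panel, a typical droplet
depth; at substantially sparser baselines the stage means of unprogrammed
genes fluctuate past the 1.2-fold calling threshold, which is a property of
the threshold, not of the caller. Structure on top of baseline: each
population's own 40-gene module at 2-fold; G2/M at 2-fold in cycling NSCs;
the stage's fate module (NB_Neuron at T1, AC at T2, OPC at End) at 3-fold in
cycling NSCs — the programmed fate switch; 25 stage-marker genes per stage at
2-fold in all cells of that stage; 10 `MT-` genes tuned to a 5% mitochondrial
fraction (35% in optional programmed QC-failure cells, which also have 10%
depth). Depth profiles are Poisson with the inter-site mean reduced by the
stage's deletion fraction (defaults 0 / 0.1 / 0.4 / 0.7).

All randomness flows from the single design seed; every generator returns its
ground truth (cell labels, module library, marker lists) so downstream stages
are scored without re-deriving it. What the generator does **not** emulate:
ambient RNA, doublets, batch effects, library-size gradients within a
population, gene–gene correlation beyond module structure, or real biological
overlap between signatures. Recovery results on these data therefore
demonstrate correctness of the implementations under the assumed noise model,
not performance on real tissue.

Two smaller fixtures serve the trajectory stage: a 2-D branching time series
(trunk splitting into two arms, latent time mapped to four stages) and the
canonical Y-graph (three 50-point segments, 5-cell root and tip sets, jitter
0.03).

## Pipeline, seeds, determinism

`run_pipeline` executes simulate → preprocess → scoring → dynamics →
trajectory → clonetrack, each stage reading only files of earlier stages
(missing upstream artifacts raise an error naming the stage). The run seed is
fanned out to per-stage sub-seeds by spawning one `numpy` `SeedSequence`
child per stage in canonical order, so re-running a stage subset reproduces
the full run's outputs exactly. Every output table carries a header with
version, stage sub-seed and parameters; `manifest.json` records SHA-256
hashes of all outputs and omits wall-clock timestamps by default so that
manifests of identical runs are identical.

## Problem sizes

The test suite and acceptance script use: 200 random instances (N ≤ 50) for
the ssGSEA oracle; 500 replicates × 1,000-draw nulls for calibration; 3
subtypes × 20 samples × 10,000 draws for subtype recovery; 20 seeds of the
default 2,000-cells/stage design for fate-switch and frequency recovery; 20
seeds at 500 cells/stage for stage-marker recovery; a 600-cell branching
series and 20 seeds of the 150-cell Y-graph with 1,000 walks/tip for
trajectory recovery; 20 seeds of the Poisson depth series at mean depth 200;
and a 400-cells/stage, 20,000-draw full-pipeline double run for the
determinism check. These sizes were chosen so each check is statistically
decisive while the whole suite runs in a couple of minutes on one CPU.

## Known limitations

- The ssGSEA null interpretation (gene-set sampling vs expression
  permutation) is a documented package choice.
- The pseudotime flood and walk-bias parameters are validated on geometric
  fixtures; very noisy or disconnected graphs may need a wider window or
  higher step cap (both exposed).
- Branch assignment near a junction is intrinsically ambiguous; accuracy is
  measured over whole arms, and junction-adjacent cells may legitimately end
  up shared.
- The DEG producer is nonparametric; count-model inference (dispersion
  shrinkage etc.) is out of scope, and the threshold filter accepts any
  upstream producer's table.
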
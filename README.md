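# gliotraj

Reconstruction of gliomagenic lineage trajectories from time-series
transcriptomes, with clonal tracking of CRISPR-edited loci.

Genome-edited human neural stem cells (hNSCs) carrying glioblastoma driver
mutations generate malignant gliomas in vivo through a stereotyped sequence of
fate switches: a persistent cycling stem-like population first produces
neurons, then astrocytes, then oligodendrocytes, while clones carrying a
deletion between two CRISPR gRNA cut sites are progressively selected.
`gliotraj` reimplements the computational analyses behind that picture as a
tested, reusable Python pipeline for anyone working with staged bulk or
single-cell expression time courses:

- **ssGSEA subtype classification with an empirical null.** The enrichment
  score of signature S in one ranked profile (N genes, rank weights
  r_i = N − position_i + 1) is

  ES = Σ_i [P_hit(i) − P_miss(i)],  P_hit(i) = Σ_{j∈S, pos_j≤i} r_j^τ / Σ_{j∈S} r_j^τ,
  P_miss(i) = #{j∉S, pos_j≤i} / (N − |S|),

  with τ = 0.25. A null of ≥100,000 size-matched random gene sets gives an
  empirical upper-tail p; the sample's subtype is the signature with the
  highest −log10 p. Also exposed as a scikit-learn style
  `SubtypeClassifier` (fit/predict).
- **Meta-module cell-state scores**: per-cell mean normalised expression of a
  gene module, z-scaled group summaries, and a paired signed-rank test for the
  dominant module of a cell population.
- **Preprocessing** as in the droplet single-cell convention: QC at ≥500
  detected genes and ≤25% mitochondrial fraction, log library-size
  normalisation (scale 10,000), pseudo-bulk aggregation of raw counts,
  cell-cycle scoring and linear regression against the cell-cycle score.
- **Lineage dynamics**: per-sample population frequencies (mean ± SEM per
  stage), stage-specific gene calling (gene assigned to its max-mean stage and
  called at a ≥1.2 linear fold over every other stage), and the strict
  DEG filter padj < 0.05 and |log2FC| > 1.2.
- **Trajectory reconstruction**: kNN graph (k = 200, locally adaptive Gaussian
  kernel), diffusion-map embedding, pseudotime by an iterative flood from root
  cells over random edge subsamples, and tip-to-root biased random walks whose
  visitation frequencies assign cells to branches. Also exposed as
  `DiffusionTrajectory` (fit/transform). Stage-correlation mapping labels
  query cells "T1/T2-like", "T2-like", … by Pearson correlation with reference
  stages on a stage-specific gene panel.
- **Clonal quantification**: T7EI indel percentage
  100 × (1 − √(1 − (b+c)/(a+b+c))), tumor mutational burden per megabase, and
  the inter-gRNA-site depth ratio with a bootstrap CI plus a
  "progressive reduction" trend verdict across stages.

A bundled synthetic-data generator (`gliotraj.synthdata`) emulates the study
design — four stages (T0, T1, T2, End), eight neural subpopulations with
stage-dependent frequencies, module-structured negative-binomial counts,
mitochondrial genes, and depth profiles with programmed inter-site deletion —
so the whole pipeline is testable without any download.

## Worked example

Run the full pipeline on the default synthetic design (2,000 cells/stage,
2,000 genes, seed 1):

```bash
gliotraj run --seed 1 --outdir out/
```

`out/dominant_modules.tsv` then contains the per-stage dominant meta-module of
the cycling NSC population:

```
stage  top_module  second_module  p_value    significant
T0     NSC_cc      aNSC_adult     2.6e-182   True
T1     NB_Neuron   NSC_cc         2.7e-52    True
T2     AC          NSC_cc         1.7e-51    True
End    OPC         NSC_cc         4.6e-52    True
```

— the programmed neurogenic → astrocytic → oligodendrocytic fate switch, with
the stem module always second once differentiation begins.
`out/frequencies_per_stage.tsv` shows the persistent cycling-NSC pool
(mean ± SEM over 3 samples/stage): 0.156 ± 0.016 at T1, 0.156 ± 0.006 at T2,
0.156 ± 0.004 at End, against a programmed 0.15. `out/depth_ratios.tsv` tracks
clonal selection at the edited locus — the mean depth between the two cut
sites relative to the flanks falls from 1.00 (T0) to 0.91 (T1), 0.60 (T2) and
0.30 (End) under programmed deletion fractions 0 / 0.1 / 0.4 / 0.7, and the
verdict column reads `progressive reduction`.

Every output TSV carries a header with the package version, the stage
sub-seed, and the parameters used; `out/manifest.json` records a SHA-256 for
each output, and re-running with the same seed reproduces them bit for bit.

The same operations are importable directly — e.g.

```python
from gliotraj import synthdata, scoring
lib = synthdata.make_subtype_library()          # Proneural/Classical/Mesenchymal
expr, truth = synthdata.make_subtype_fixture(lib, 20, effect=2.0, seed=1)
calls = scoring.classify_subtypes(expr, lib, n_draws=10_000, seed=1)
sum(c.subtype == t for c, t in zip(calls, truth)) / len(truth)   # 1.0
```

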
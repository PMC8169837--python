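"""Synthetic inputs with the statistical structure the downstream analysis assumes.

The time-series generator emulates the study design the pipeline targets: four
stages (T0, T1, T2, End) sampled over eight neural subpopulations whose
frequencies shift across stages — a persistent cycling neural-stem-cell (NSC)
pool of about 15% from T1 on, a neuron/neuroblast burst at T1, an astrocyte
burst at T2 and an oligodendrocyte-lineage burst at the end stage.  Counts are
negative binomial (variance = mu + mu^2 * dispersion); each subpopulation
up-regulates its own marker module, cycling NSCs additionally up-regulate a
G2/M cell-cycle module and, from T1 on, the fate module of the lineage they
are currently generating (neuronal at T1, astrocytic at T2, oligodendrocytic
at End) — the programmed fate-switch the recovery tests score against.
Mitochondrial genes carry an ``MT-`` prefix so QC needs no extra annotation.

Every generator returns its ground truth (cell metadata, module library,
programmed marker lists) so downstream stages can be scored without
re-deriving it, and all randomness flows from the single design seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iokit import CountMatrix, DepthProfile, ModuleLibrary

DEFAULT_STAGES = ("T0", "T1", "T2", "End")

DEFAULT_POPULATIONS = (
    "NSC_cc", "NSC_ncc", "aNSC_adult", "qNSC_adult", "AC", "OPC", "OC", "NB_Neuron",
)

# stage x population frequency design: persistent cycling-NSC pool at 0.15
# from T1 on; NB/Neuron burst at T1, AC burst at T2, OPC/OC burst at End.
DEFAULT_FREQUENCIES: dict[str, dict[str, float]] = {
    "T0": {"NSC_cc": 0.55, "NSC_ncc": 0.25, "aNSC_adult": 0.05, "qNSC_adult": 0.05,
           "AC": 0.03, "OPC": 0.03, "OC": 0.02, "NB_Neuron": 0.02},
    "T1": {"NSC_cc": 0.15, "NSC_ncc": 0.07, "aNSC_adult": 0.12, "qNSC_adult": 0.04,
           "AC": 0.08, "OPC": 0.04, "OC": 0.02, "NB_Neuron": 0.48},
    "T2": {"NSC_cc": 0.15, "NSC_ncc": 0.06, "aNSC_adult": 0.05, "qNSC_adult": 0.10,
           "AC": 0.45, "OPC": 0.08, "OC": 0.04, "NB_Neuron": 0.07},
    "End": {"NSC_cc": 0.15, "NSC_ncc": 0.05, "aNSC_adult": 0.04, "qNSC_adult": 0.06,
            "AC": 0.12, "OPC": 0.22, "OC": 0.28, "NB_Neuron": 0.08},
}

# which module the cycling NSC pool transiently up-regulates at each stage:
# the programmed neurogenic -> astrocytic -> oligodendrocytic fate switch.
DEFAULT_FATE_MAP: dict[str, str] = {"T1": "NB_Neuron", "T2": "AC", "End": "OPC"}


@dataclass
class DepthDesign:
    """Geometry and per-stage deletion fraction of the doubly-cut edited locus."""

    locus_length: int = 1_200
    site1: int = 400
    site2: int = 800
    deletion_fraction: dict[str, float] = field(
        default_factory=lambda: {"T0": 0.0, "T1": 0.1, "T2": 0.4, "End": 0.7}
    )

    def __post_init__(self) -> None:
        if not 0 <= self.site1 < self.site2 < self.locus_length:
            raise ValueError("require 0 <= site1 < site2 < locus_length")
        for stage, frac in self.deletion_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"deletion fraction for {stage} outside [0, 1]")


@dataclass
class SimulationDesign:
    """Full design of the synthetic time series.

    Defaults are the desk-scale study conditions: 2,000 cells and 2,000 genes
    per stage, 3 samples per stage, baseline negative-binomial mean 2.0 with
    dispersion 0.5 (about 4,000 UMIs per cell over the 2,000-gene panel, a
    typical droplet depth), 2-fold module effects, 3-fold
    transient fate-module effects in cycling NSCs, 2-fold stage markers and a
    5% mitochondrial fraction in healthy cells.
    """

    stages: tuple[str, ...] = DEFAULT_STAGES
    populations: tuple[str, ...] = DEFAULT_POPULATIONS
    frequencies: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(p) for s, p in DEFAULT_FREQUENCIES.items()}
    )
    fate_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_FATE_MAP))
    n_cells_per_stage: int = 2_000
    n_samples_per_stage: int = 3
    n_genes: int = 2_000
    genes_per_module: int = 40
    n_stage_markers: int = 25
    n_mito_genes: int = 10
    baseline_mean: float = 2.0
    module_effect: float = 2.0
    fate_effect: float = 3.0
    cc_effect: float = 2.0
    stage_marker_fold: float = 2.0
    nb_dispersion: float = 0.5
    mito_fraction_by_qc_class: dict[str, float] = field(
        default_factory=lambda: {"pass": 0.05, "fail": 0.35}
    )
    qc_fail_fraction: float = 0.0
    depth_design: DepthDesign = field(default_factory=DepthDesign)
    seed: int = 0

    def __post_init__(self) -> None:
        for stage in self.stages:
            freqs = self.frequencies.get(stage)
            if freqs is None:
                raise ValueError(f"no population frequencies for stage {stage!r}")
            total = float(sum(freqs.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"frequencies at stage {stage!r} sum to {total!r}, not 1"
                )
            if set(freqs) != set(self.populations):
                raise ValueError(f"stage {stage!r} frequencies do not cover populations")
        if self.module_effect < 1 or self.fate_effect < 1 or self.cc_effect < 1:
            raise ValueError("effects are fold-changes and must be >= 1")
        if self.baseline_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("baseline_mean and nb_dispersion must be positive")
        if not 0.0 <= self.qc_fail_fraction < 1.0:
            raise ValueError("qc_fail_fraction must lie in [0, 1)")
        needed = (
            self.n_mito_genes
            + self.genes_per_module * (len(self.populations) + 2)
            + self.n_stage_markers * len(self.stages)
        )
        if self.n_genes < needed + 100:
            raise ValueError(
                f"n_genes={self.n_genes} too small for the module layout ({needed} structured genes)"
            )


def _gene_layout(design: SimulationDesign) -> tuple[list[str], ModuleLibrary, dict[str, list[str]], list[str]]:
    """Lay out gene names: population modules, cell-cycle sets, stage markers, mito, background."""
    genes: list[str] = []
    sets: dict[str, list[str]] = {}
    for pop in design.populations:
        members = [f"{pop}-g{i:03d}" for i in range(design.genes_per_module)]
        sets[pop] = members
        genes += members
    for cc in ("G1S", "G2M"):
        members = [f"{cc}-g{i:03d}" for i in range(design.genes_per_module)]
        sets[cc] = members
        genes += members
    markers = {
        stage: [f"MK-{stage}-g{i:03d}" for i in range(design.n_stage_markers)]
        for stage in design.stages
    }
    for stage in design.stages:
        genes += markers[stage]
    mito = [f"MT-{i + 1}" for i in range(design.n_mito_genes)]
    genes += mito
    n_background = design.n_genes - len(genes)
    genes += [f"BG-g{i:04d}" for i in range(n_background)]
    return genes, ModuleLibrary(sets=sets), markers, mito


def simulate_timeseries_counts(
    design: SimulationDesign | None = None,
) -> tuple[CountMatrix, pd.DataFrame, ModuleLibrary]:
    """Draw the synthetic time-series count matrix with its ground truth.

    Returns the genes x cells :class:`CountMatrix`, a per-cell metadata table
    (cell, sample, stage, population, qc_class) and the ground-truth
    :class:`ModuleLibrary` (population modules plus G1/S and G2/M cell-cycle
    sets).  Bit-reproducible from ``design.seed``.
    """
    design = design or SimulationDesign()
    rng = np.random.default_rng(design.seed)
    genes, library, markers, mito = _gene_layout(design)
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    # per-cell labels
    rows = []
    for stage in design.stages:
        pops = list(design.populations)
        probs = np.array([design.frequencies[stage][p] for p in pops])
        drawn = rng.choice(len(pops), size=design.n_cells_per_stage, p=probs)
        sample_ids = rng.integers(0, design.n_samples_per_stage, size=design.n_cells_per_stage)
        fails = rng.random(design.n_cells_per_stage) < design.qc_fail_fraction
        for i in range(design.n_cells_per_stage):
            rows.append(
                {
                    "stage": stage,
                    "population": pops[drawn[i]],
                    "sample": f"{stage}-s{sample_ids[i] + 1}",
                    "qc_class": "fail" if fails[i] else "pass",
                }
            )
    meta = pd.DataFrame(rows)
    meta.insert(0, "cell", [f"cell{i:05d}" for i in range(len(meta))])

    # mitochondrial mean per gene chosen so the expected mito count fraction
    # matches the design for each QC class
    base_total = design.baseline_mean * (n_genes - design.n_mito_genes)
    for cls, frac in design.mito_fraction_by_qc_class.items():
        if not 0.0 <= frac < 1.0:
            raise ValueError(f"mito fraction for class {cls!r} must lie in [0, 1)")
    mito_mean = {
        cls: frac / (1.0 - frac) * base_total / design.n_mito_genes
        for cls, frac in design.mito_fraction_by_qc_class.items()
    }

    counts = np.zeros((n_genes, len(meta)), dtype=np.int64)
    r = 1.0 / design.nb_dispersion  # NB shape: var = mu + mu^2 * dispersion

    # one NB draw per homogeneous (stage, population, qc_class) block
    for (stage, pop, qc_class), block in meta.groupby(
        ["stage", "population", "qc_class"], sort=True
    ):
        mu = np.full(n_genes, design.baseline_mean)
        for g in library[pop]:
            mu[gene_index[g]] *= design.module_effect
        if pop == "NSC_cc":
            for g in library["G2M"]:
                mu[gene_index[g]] *= design.cc_effect
            fate = design.fate_map.get(stage)
            if fate is not None:
                for g in library[fate]:
                    mu[gene_index[g]] *= design.fate_effect
        for g in markers[stage]:
            mu[gene_index[g]] *= design.stage_marker_fold
        for g in mito:
            mu[gene_index[g]] = mito_mean[qc_class]
        if qc_class == "fail":
            non_mito = np.ones(n_genes, dtype=bool)
            non_mito[[gene_index[g] for g in mito]] = False
            mu[non_mito] *= 0.1  # shallow cells: few detected genes
        idx = block.index.to_numpy()
        p = r / (r + mu)
        counts[:, idx] = rng.negative_binomial(
            r, p[:, None], size=(n_genes, len(idx))
        )

    matrix = CountMatrix(
        values=counts,
        gene_ids=genes,
        unit_ids=meta["cell"].tolist(),
        unit_meta=meta.set_index("cell", drop=False).reset_index(drop=True),
    )
    return matrix, meta, library


def stage_marker_genes(design: SimulationDesign) -> dict[str, list[str]]:
    """Ground-truth programmed stage markers, keyed by stage."""
    _, _, markers, _ = _gene_layout(design or SimulationDesign())
    return markers


def simulate_depth_profile(
    depth_design: DepthDesign,
    mean_depth: float,
    stage: str,
    seed: int = 0,
) -> DepthProfile:
    """Poisson per-base depth over the edited locus at one stage.

    Mean depth is ``mean_depth`` outside the two cut sites and
    ``mean_depth * (1 - deletion_fraction(stage))`` on [site1, site2) —
    the footprint of clones carrying the inter-site deletion.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    frac = depth_design.deletion_fraction.get(stage)
    if frac is None:
        raise ValueError(f"no deletion fraction for stage {stage!r}")
    if not 0.0 <= frac <= 1.0:
        raise ValueError("deletion fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    mu = np.full(depth_design.locus_length, float(mean_depth))
    mu[depth_design.site1:depth_design.site2] *= 1.0 - frac
    depth = rng.poisson(mu).astype(float)
    return DepthProfile(
        locus_id=f"locus-{stage}", depth=depth,
        site1=depth_design.site1, site2=depth_design.site2,
    )


def make_subtype_library(
    n_subtypes: int = 3,
    genes_per_signature: int = 50,
    subtype_names: tuple[str, ...] = ("Proneural", "Classical", "Mesenchymal"),
) -> ModuleLibrary:
    """Disjoint subtype signatures named after the bulk GBM transcriptional classes."""
    names = list(subtype_names)[:n_subtypes]
    while len(names) < n_subtypes:
        names.append(f"Subtype{len(names) + 1}")
    sets = {
        name: [f"SIG-{name}-g{i:03d}" for i in range(genes_per_signature)]
        for name in names
    }
    return ModuleLibrary(sets=sets)


def make_subtype_fixture(
    module_library: ModuleLibrary,
    n_samples_per_subtype: int = 20,
    effect: float = 2.0,
    seed: int = 0,
    n_background_genes: int = 850,
) -> tuple[pd.DataFrame, list[str]]:
    """Log-scale Gaussian expression with each truth subtype's signature shifted up.

    Returns a genes x samples expression table and the truth subtype labels.
    ``effect`` is in SD units of the unit-variance background noise.
    Partially overlapping signatures are tolerated with a warning.
    """
    names = module_library.names()
    if len(names) < 2:
        raise ValueError("need at least 2 subtype signatures")
    seen: set[str] = set()
    for name in names:
        overlap = seen.intersection(module_library[name])
        if overlap:
            warnings.warn(
                f"signature {name!r} overlaps earlier signatures on "
                f"{len(overlap)} genes; proceeding", stacklevel=2
            )
        seen.update(module_library[name])
    genes = list(dict.fromkeys(g for name in names for g in module_library[name]))
    genes += [f"BG-g{i:04d}" for i in range(n_background_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(seed)
    n_samples = n_samples_per_subtype * len(names)
    expr = rng.normal(0.0, 1.0, size=(len(genes), n_samples))
    labels: list[str] = []
    sample_ids: list[str] = []
    for k, name in enumerate(names):
        cols = slice(k * n_samples_per_subtype, (k + 1) * n_samples_per_subtype)
        sig_rows = [gene_index[g] for g in module_library[name]]
        expr[np.ix_(sig_rows, range(*cols.indices(n_samples)))] += effect
        labels += [name] * n_samples_per_subtype
        sample_ids += [f"{name}-s{i + 1}" for i in range(n_samples_per_subtype)]
    table = pd.DataFrame(expr, index=genes, columns=sample_ids)
    return table, labels


# ---------------------------------------------------------------------------
# geometric fixtures for the trajectory stage


def make_branching_series(
    n_cells: int = 600,
    noise: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A 2-D branching time series: a trunk that splits into two arms.

    Each cell has a latent progression time t ~ U(0, 4) mapped to the four
    stages by floor(t); cells with t < 2 lie on the trunk, later cells on one
    of two arms.  Returns (embedding (n, 2), stage_index (n,), branch labels
    (n,) with 'trunk'/'armA'/'armB').  Gaussian positional noise emulates
    transcriptomic scatter around the lineage manifold.
    """
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0.0, 4.0, size=n_cells))
    arm = rng.integers(0, 2, size=n_cells)
    xy = np.zeros((n_cells, 2))
    on_trunk = t < 2.0
    xy[on_trunk, 1] = t[on_trunk]
    s = t[~on_trunk] - 2.0
    sign = np.where(arm[~on_trunk] == 0, -1.0, 1.0)
    xy[~on_trunk, 0] = sign * s / np.sqrt(2.0)
    xy[~on_trunk, 1] = 2.0 + s / np.sqrt(2.0)
    xy += rng.normal(0.0, noise, size=xy.shape)
    stage_index = np.minimum(t.astype(int), 3)
    branch = np.where(on_trunk, "trunk", np.where(arm == 0, "armA", "armB"))
    return xy, stage_index, branch


def make_y_graph(
    n_per_segment: int = 50,
    jitter: float = 0.03,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[int], dict[str, list[int]]]:
    """The canonical Y-shaped fixture: one trunk, two arms, known memberships.

    Returns (points (3n, 2), segment labels 'trunk'/'armA'/'armB', root cell
    indices at the trunk base, {tip_name: tip cell indices} at the arm ends).
    """
    rng = np.random.default_rng(seed)
    s = np.linspace(0.0, 1.0, n_per_segment)
    trunk = np.column_stack([np.zeros_like(s), s])
    arm_a = np.column_stack([-s / np.sqrt(2.0), 1.0 + s / np.sqrt(2.0)])
    arm_b = np.column_stack([s / np.sqrt(2.0), 1.0 + s / np.sqrt(2.0)])
    pts = np.vstack([trunk, arm_a, arm_b]) + rng.normal(0.0, jitter, size=(3 * n_per_segment, 2))
    labels = np.array(
        ["trunk"] * n_per_segment + ["armA"] * n_per_segment + ["armB"] * n_per_segment
    )
    roots = list(range(5))  # trunk base
    tips = {
        "armA": list(range(2 * n_per_segment - 5, 2 * n_per_segment)),
        "armB": list(range(3 * n_per_segment - 5, 3 * n_per_segment)),
    }
    return pts, labels, roots, tips
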
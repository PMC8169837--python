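"""Lineage-frequency dynamics, stage-specific gene calling and the DEG
threshold filter.

Two fold thresholds with different units live here deliberately apart: stage
assignment uses a LINEAR ratio of stage means (default 1.2, inclusive) while
the differential-expression filter uses an absolute LOG2 fold-change (default
1.2, strict) together with a strict adjusted-p cutoff — conflating the two
scales is a classic reimplementation error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedMatrix

STAGE_MEAN_PSEUDOCOUNT = 0.01  # added to stage means before fold ratios
DEG_PSEUDOCOUNT = 0.01


def cell_frequencies(cell_meta: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample population frequencies plus per-stage mean +/- SEM summaries.

    ``cell_meta`` needs 'sample', 'stage' and 'population' columns, one row
    per cell.  Frequencies within each sample sum to 1 over the populations
    observed there.
    """
    required = {"sample", "stage", "population"}
    missing = required - set(cell_meta.columns)
    if missing:
        raise ValueError(f"cell metadata lacks columns {sorted(missing)}")
    if len(cell_meta) == 0:
        raise ValueError("empty cell metadata")

    populations = sorted(cell_meta["population"].unique())
    rows = []
    for (sample, stage), block in cell_meta.groupby(["sample", "stage"], sort=True):
        if len(block) == 0:
            raise ValueError(f"sample {sample!r} has no cells")
        counts = block["population"].value_counts()
        for pop in populations:
            n = int(counts.get(pop, 0))
            rows.append(
                {
                    "sample": sample,
                    "stage": stage,
                    "population": pop,
                    "n_cells": n,
                    "frequency": n / len(block),
                }
            )
    table = pd.DataFrame(rows)

    summaries = []
    for (stage, pop), block in table.groupby(["stage", "population"], sort=True):
        freqs = block["frequency"].to_numpy()
        sem = freqs.std(ddof=1) / np.sqrt(len(freqs)) if len(freqs) > 1 else 0.0
        summaries.append(
            {
                "stage": stage,
                "population": pop,
                "n_samples": len(freqs),
                "mean_frequency": freqs.mean(),
                "sem_frequency": sem,
            }
        )
    return table, pd.DataFrame(summaries)


def stage_specific_genes(
    norm: NormalizedMatrix,
    stage_labels,
    fold: float = 1.2,
    stage_order: list[str] | None = None,
) -> pd.DataFrame:
    """Assign each gene to its max-mean stage; call it stage-specific at a fold margin.

    Per gene: stage means of normalised expression (+ a 0.01 pseudocount so
    zero-mean stages leave the ratio defined); the assigned stage is the
    argmax; the gene is called stage-specific iff the max mean is at least
    ``fold`` times EVERY other stage's mean (inclusive boundary).
    Returns one row per gene with per-stage means, the assigned stage, the
    minimum fold over other stages and the call flag.
    """
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    labels = pd.Series(list(stage_labels))
    if len(labels) != norm.n_units:
        raise ValueError("one stage label per unit is required")
    stages = stage_order if stage_order is not None else sorted(labels.unique())
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    means = np.empty((norm.n_genes, len(stages)))
    for j, stage in enumerate(stages):
        mask = (labels == stage).to_numpy()
        if not mask.any():
            raise ValueError(f"stage {stage!r} has no cells")
        means[:, j] = norm.values[:, mask].mean(axis=1)
    padded = means + STAGE_MEAN_PSEUDOCOUNT
    best = np.argmax(padded, axis=1)
    best_mean = padded[np.arange(len(padded)), best]
    others = padded.copy()
    others[np.arange(len(padded)), best] = -np.inf
    # the binding constraint is the largest OTHER stage mean
    min_fold = best_mean / others.max(axis=1)
    out = pd.DataFrame(
        {
            "gene": norm.gene_ids,
            "assigned_stage": [stages[i] for i in best],
            "min_fold_over_other_stages": min_fold,
            "called": min_fold >= fold,
        }
    )
    for j, stage in enumerate(stages):
        out[f"mean_{stage}"] = means[:, j]
    return out


def deg_threshold_filter(
    stat_table: pd.DataFrame,
    max_padj: float = 0.05,
    min_abs_log2fc: float = 1.2,
) -> pd.DataFrame:
    """Keep rows with padj < max_padj AND |log2FC| > min_abs_log2fc (both strict)."""
    for col in ("padj", "log2fc"):
        if col not in stat_table.columns:
            raise ValueError(f"stat table lacks required column {col!r}")
    keep = (stat_table["padj"] < max_padj) & (stat_table["log2fc"].abs() > min_abs_log2fc)
    return stat_table.loc[keep].reset_index(drop=True)


def rank_sum_deg(
    norm: NormalizedMatrix,
    group_a,
    group_b,
) -> pd.DataFrame:
    """Per-gene two-sided rank-sum differential test between two cell groups.

    Returns gene, p-value, Benjamini-Hochberg adjusted p and the log2 fold
    change of group means (with a 0.01 pseudocount).  This is the bundled
    nonparametric producer for the downstream threshold filter; model-based
    alternatives plug in anywhere a (padj, log2fc) table is accepted.
    """
    a_idx = _as_indices(group_a, norm.n_units)
    b_idx = _as_indices(group_b, norm.n_units)
    if len(a_idx) < 3 or len(b_idx) < 3:
        raise ValueError("both groups need at least 3 cells")
    a = norm.values[:, a_idx]
    b = norm.values[:, b_idx]
    res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
    pvals = np.asarray(res.pvalue, dtype=float)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)  # degenerate all-tied genes
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_a + DEG_PSEUDOCOUNT) / (mean_b + DEG_PSEUDOCOUNT))
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": norm.gene_ids,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
        }
    )


def _as_indices(group, n_units: int) -> np.ndarray:
    group = np.asarray(group)
    if group.dtype == bool:
        if len(group) != n_units:
            raise ValueError("boolean group mask must cover all units")
        return np.flatnonzero(group)
    return group.astype(int)
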
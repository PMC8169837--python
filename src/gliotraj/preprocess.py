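"""Cell QC, library-size log-normalisation, pseudo-bulk aggregation and
cell-cycle scoring/regression.

QC keeps cells with at least ``min_genes`` detected genes (count > 0) and a
mitochondrial count fraction of at most ``max_mito_frac``, computed on the raw
counts; mitochondrial genes are recognised by the ``MT-`` identifier prefix.
Normalisation is the standard library-size transform
``log(1 + scale * count / libsize)`` with natural log and scale 10,000 by
default.  Fold-change statistics elsewhere in the package use log2; the two
bases are kept in distinct containers so they cannot be mixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iokit import CountMatrix, ModuleLibrary

MITO_PREFIX = "MT-"


@dataclass
class NormalizedMatrix:
    """Log-normalised expression (natural log1p of scale x count / library size)."""

    values: np.ndarray  # genes x units, floats >= 0
    gene_ids: list[str]
    unit_ids: list[str]
    scale: float
    unit_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("normalized values must be non-negative")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if len(self.gene_ids) != self.values.shape[0] or len(self.unit_ids) != self.values.shape[1]:
            raise ValueError("identifier lists inconsistent with matrix shape")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def gene_row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.unit_ids)


def qc_filter_cells(
    counts: CountMatrix,
    min_genes: int = 500,
    max_mito_frac: float = 0.25,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop low-quality cells; return the filtered matrix and a per-cell QC report.

    A cell is kept iff its detected-gene count (genes with count > 0) is at
    least ``min_genes`` AND its mitochondrial count fraction is at most
    ``max_mito_frac``.  Both statistics are computed on the raw counts of the
    input matrix, so the operation is idempotent.
    """
    mito_mask = np.array([g.startswith(MITO_PREFIX) for g in counts.gene_ids])
    detected = (counts.values > 0).sum(axis=0)
    totals = counts.values.sum(axis=0)
    mito_counts = counts.values[mito_mask].sum(axis=0) if mito_mask.any() else np.zeros(counts.n_units)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    keep = (detected >= min_genes) & (mito_frac <= max_mito_frac)
    reasons = np.where(
        keep, "pass",
        np.where(
            (detected < min_genes) & (mito_frac > max_mito_frac), "low_genes+high_mito",
            np.where(detected < min_genes, "low_genes", "high_mito"),
        ),
    )
    report = pd.DataFrame(
        {
            "cell": counts.unit_ids,
            "n_detected_genes": detected,
            "total_counts": totals,
            "mito_frac": mito_frac,
            "kept": keep,
            "reason": reasons,
        }
    )
    if not keep.any():
        raise ValueError(
            f"QC removed all {counts.n_units} cells "
            f"(min_genes={min_genes}, max_mito_frac={max_mito_frac})"
        )
    kept_idx = np.flatnonzero(keep)
    meta = None
    if counts.unit_meta is not None:
        meta = counts.unit_meta.iloc[kept_idx].reset_index(drop=True)
    filtered = CountMatrix(
        values=counts.values[:, kept_idx],
        gene_ids=list(counts.gene_ids),
        unit_ids=[counts.unit_ids[i] for i in kept_idx],
        unit_meta=meta,
    )
    return filtered, report


def normalize(counts: CountMatrix, scale: float = 10_000.0) -> NormalizedMatrix:
    """Library-size log-normalisation: value = log(1 + scale * count / libsize)."""
    libsize = counts.values.sum(axis=0)
    empty = np.flatnonzero(libsize == 0)
    if empty.size:
        raise ValueError(
            f"unit(s) with zero library size: {[counts.unit_ids[i] for i in empty[:5]]}"
        )
    values = np.log1p(scale * counts.values / libsize[None, :])
    return NormalizedMatrix(
        values=values,
        gene_ids=list(counts.gene_ids),
        unit_ids=list(counts.unit_ids),
        scale=float(scale),
        unit_meta=counts.unit_meta,
    )


def pseudobulk(counts: CountMatrix, sample_labels) -> CountMatrix:
    """Aggregate raw single-cell counts per gene into per-sample totals.

    Aggregation is always on raw counts — normalising first and then summing
    is a different (and wrong) operation for ssGSEA input.
    """
    labels = pd.Series(list(sample_labels), dtype="object")
    if len(labels) != counts.n_units:
        raise ValueError("one sample label per cell is required")
    if labels.isna().any() or (labels.astype(str).str.len() == 0).any():
        bad = labels.index[labels.isna() | (labels.astype(str).str.len() == 0)]
        raise ValueError(f"unlabeled cells at positions {list(bad[:5])}")
    sample_names = list(dict.fromkeys(labels))
    cols = [counts.values[:, (labels == s).to_numpy()].sum(axis=1) for s in sample_names]
    return CountMatrix(
        values=np.column_stack(cols),
        gene_ids=list(counts.gene_ids),
        unit_ids=[str(s) for s in sample_names],
    )


def cell_cycle_score(
    norm: NormalizedMatrix,
    g1s_set: list[str],
    g2m_set: list[str],
) -> pd.DataFrame:
    """Per-cell mean normalised expression of the G1/S and G2/M sets.

    The combined cell-cycle score is the max of the two phase scores: a cell
    is "cycling" if it is high in either phase program.
    """
    g1s = _set_mean(norm, g1s_set, "G1/S")
    g2m = _set_mean(norm, g2m_set, "G2/M")
    return pd.DataFrame(
        {
            "cell": norm.unit_ids,
            "g1s_score": g1s,
            "g2m_score": g2m,
            "cc_score": np.maximum(g1s, g2m),
        }
    )


def _set_mean(norm: NormalizedMatrix, gene_set: list[str], label: str) -> np.ndarray:
    idx = [i for i, g in enumerate(norm.gene_ids) if g in set(gene_set)]
    if not idx:
        raise ValueError(f"{label} set has no genes in the matrix")
    return norm.values[idx].mean(axis=0)


def regress_out_cell_cycle(score: np.ndarray, cc_score: np.ndarray) -> np.ndarray:
    """Remove the linear cell-cycle contribution from a per-cell score.

    Ordinary least squares of score on cc_score with intercept; returns
    residual + fitted intercept, so the slope contribution is removed while
    the location is preserved.  A constant covariate makes the regression
    undefined; the input is then returned unchanged with a warning.
    """
    score = np.asarray(score, dtype=float)
    cc = np.asarray(cc_score, dtype=float)
    if score.shape != cc.shape or score.ndim != 1:
        raise ValueError("score and cc_score must be equal-length 1-D vectors")
    if np.ptp(cc) == 0:
        warnings.warn("constant cell-cycle covariate; returning score unchanged", stacklevel=2)
        return score.copy()
    slope, intercept = np.polyfit(cc, score, deg=1)
    residual = score - (intercept + slope * cc)
    return residual + intercept


def subset_units(norm: NormalizedMatrix, mask: np.ndarray) -> NormalizedMatrix:
    """Column subset of a normalised matrix (helper for per-population analyses)."""
    mask = np.asarray(mask)
    if mask.dtype == bool:
        idx = np.flatnonzero(mask)
    else:
        idx = mask
    meta = None
    if norm.unit_meta is not None:
        meta = norm.unit_meta.iloc[idx].reset_index(drop=True)
    return NormalizedMatrix(
        values=norm.values[:, idx],
        gene_ids=list(norm.gene_ids),
        unit_ids=[norm.unit_ids[i] for i in idx],
        scale=norm.scale,
        unit_meta=meta,
    )
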
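"""Closed-form genome-editing and WES-side quantifications.

Three small statistics: the T7 endonuclease I indel percentage from gel band
intensities, tumor mutational burden per megabase of the exome capture
target, and the inter-gRNA-site depth ratio that tracks clonal selection of
cells carrying a deletion between two CRISPR cut sites — when such clones
expand, sequencing depth between the cut sites drops relative to the flanks,
stage after stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iokit import DepthProfile


@dataclass
class T7Bands:
    """Integrated gel band intensities: a = undigested product, b, c = cleaved products."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise ValueError("band intensities must be non-negative")
        if self.a + self.b + self.c <= 0:
            raise ValueError("total band intensity must be positive")


def t7ei_indel_percent(bands: T7Bands) -> float:
    """Indel percentage from T7EI band intensities.

    100 * (1 - sqrt(1 - (b + c) / (a + b + c))): the cleaved fraction measures
    the probability a re-annealed duplex is heteroduplex, and the square root
    inverts the two-allele pairing to a per-allele edit rate.
    """
    cleaved_fraction = (bands.b + bands.c) / (bands.a + bands.b + bands.c)
    return float(100.0 * (1.0 - np.sqrt(1.0 - cleaved_fraction)))


def tmb(n_nonsilent_mutations: int, target_size_bp: float) -> float:
    """Tumor mutational burden: non-silent mutations per megabase of capture target."""
    if target_size_bp <= 0:
        raise ValueError("target_size_bp must be positive")
    if n_nonsilent_mutations < 0:
        raise ValueError("mutation count must be non-negative")
    return float(n_nonsilent_mutations / (target_size_bp / 1e6))


@dataclass
class DepthRatio:
    locus_id: str
    ratio: float
    ci_low: float
    ci_high: float
    inter_mean: float
    flank_mean: float


def intertarget_depth_ratio(
    profile: DepthProfile,
    flank_bp: int = 200,
    n_bootstrap: int = 1_000,
    seed: int = 0,
) -> DepthRatio:
    """Mean depth between the two cut sites relative to the flanks, with a bootstrap CI.

    The inter-site window is [site1, site2); the comparison windows are
    ``flank_bp`` bases immediately outside each cut site.  The 95% CI comes
    from a seeded position bootstrap (resampling bases independently within
    the inter-site and flank windows).
    """
    if flank_bp < 1:
        raise ValueError("flank_bp must be positive")
    if profile.site1 - flank_bp < 0 or profile.site2 + flank_bp > profile.length:
        raise ValueError("flank windows do not fit inside the locus")
    inter = profile.depth[profile.site1:profile.site2]
    flank = np.concatenate(
        [
            profile.depth[profile.site1 - flank_bp:profile.site1],
            profile.depth[profile.site2:profile.site2 + flank_bp],
        ]
    )
    if flank.mean() == 0:
        raise ValueError("zero mean flank depth; ratio undefined")
    ratio = float(inter.mean() / flank.mean())

    rng = np.random.default_rng(seed)
    idx_i = rng.integers(0, len(inter), size=(n_bootstrap, len(inter)))
    idx_f = rng.integers(0, len(flank), size=(n_bootstrap, len(flank)))
    boot_f = flank[idx_f].mean(axis=1)
    boot_f[boot_f == 0] = np.nan
    boots = inter[idx_i].mean(axis=1) / boot_f
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return DepthRatio(
        locus_id=profile.locus_id, ratio=ratio,
        ci_low=float(lo), ci_high=float(hi),
        inter_mean=float(inter.mean()), flank_mean=float(flank.mean()),
    )


def clonal_selection_trend(stage_ratio_table: pd.DataFrame) -> str:
    """Verdict on inter-site depth ratios across ordered stages.

    "progressive reduction" iff the ratios are monotonically non-increasing
    AND the total decline exceeds the pooled CI width (so flat-but-noisy
    series do not qualify); otherwise "no trend".  Requires >= 3 stages, in
    temporal order, with columns ratio / ci_low / ci_high.
    """
    for col in ("ratio", "ci_low", "ci_high"):
        if col not in stage_ratio_table.columns:
            raise ValueError(f"stage ratio table lacks column {col!r}")
    if len(stage_ratio_table) < 3:
        raise ValueError("trend verdict needs ratios for at least 3 ordered stages")
    ratios = stage_ratio_table["ratio"].to_numpy(dtype=float)
    widths = (stage_ratio_table["ci_high"] - stage_ratio_table["ci_low"]).to_numpy(dtype=float)
    monotone = bool(np.all(np.diff(ratios) <= 0))
    decline = ratios[0] - ratios[-1]
    if monotone and decline > widths.mean():
        return "progressive reduction"
    return "no trend"
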
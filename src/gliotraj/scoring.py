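"""ssGSEA enrichment scoring, empirical permutation null, subtype
classification, and meta-module scoring.

The enrichment score of a gene set S in a single expression profile follows
the rank-weighted running-sum convention: genes are ranked by expression
(descending, ties broken by stable gene-identifier order); with N genes and
rank weights r_i = N - position_i + 1,

    ES = sum_i [ P_hit(i) - P_miss(i) ],
    P_hit(i)  = sum_{j in S, pos_j <= i} r_j^tau / sum_{j in S} r_j^tau,
    P_miss(i) = #{j not in S, pos_j <= i} / (N - |S|).

The null distribution for a profile is built from the ssGSEA scores of
uniformly sampled, size-matched random gene sets from the same profile, and
the empirical p-value is upper-tail with add-one smoothing; a sample's
subtype is the signature with the highest -log10 p.  Meta-module scores are
per-unit means of normalised expression over a module's genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .iokit import ModuleLibrary
from .preprocess import NormalizedMatrix


# ---------------------------------------------------------------------------
# profile preparation


def _as_series(expr_profile) -> pd.Series:
    if isinstance(expr_profile, pd.Series):
        s = expr_profile.astype(float)
    else:
        raise TypeError("expression profile must be a pandas Series indexed by gene")
    if s.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in profile")
    return s


def _ranked_profile(profile: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Sort descending by expression; ties broken by stable gene-id order."""
    ordered = profile.sort_index(kind="stable").sort_values(
        ascending=False, kind="stable"
    )
    return ordered.to_numpy(), list(ordered.index)


# ---------------------------------------------------------------------------
# core score


def ssgsea_score(expr_profile: pd.Series, gene_set, tau: float = 0.25) -> float:
    """Rank-weighted running-sum enrichment score of one gene set in one profile.

    Genes absent from the profile are dropped from the set before scoring.
    Raises if the set is empty after intersection or covers every gene
    (the miss term is then undefined).
    """
    profile = _as_series(expr_profile)
    _, genes = _ranked_profile(profile)
    in_set = np.isin(genes, list(set(map(str, gene_set)))) if len(gene_set) else np.zeros(len(genes), bool)
    n = len(genes)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set has no genes in the profile")
    if n_in == n:
        raise ValueError("gene set covers every profiled gene; miss term undefined")
    r = np.arange(n, 0, -1, dtype=float)  # N - position + 1
    w = np.where(in_set, r**tau, 0.0)
    p_hit = np.cumsum(w) / w.sum()
    p_miss = np.cumsum(~in_set) / (n - n_in)
    return float(np.sum(p_hit - p_miss))


# ---------------------------------------------------------------------------
# empirical null


def _sample_index_sets(n: int, m: int, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform without-replacement m-subsets of range(n), one per row.

    Rejection sampling of distinct m-tuples (fast for m << n) with an
    argpartition fallback for dense set sizes.
    """
    if m * 8 > n:
        out = np.empty((n_draws, m), dtype=np.int64)
        chunk = max(1, int(2e6 // max(n, 1)))
        for start in range(0, n_draws, chunk):
            stop = min(start + chunk, n_draws)
            keys = rng.random((stop - start, n))
            out[start:stop] = np.argpartition(keys, m - 1, axis=1)[:, :m]
        return out
    draws = rng.integers(0, n, size=(n_draws, m))
    while True:
        srt = np.sort(draws, axis=1)
        bad = np.flatnonzero((np.diff(srt, axis=1) == 0).any(axis=1))
        if bad.size == 0:
            return draws
        draws[bad] = rng.integers(0, n, size=(bad.size, m))


def build_empirical_null(
    expr_profile: pd.Series,
    set_size: int,
    n_draws: int = 100_000,
    tau: float = 0.25,
    seed: int = 0,
) -> np.ndarray:
    """ssGSEA scores of ``n_draws`` random size-matched gene sets from the profile.

    Uses the closed form of the running sum — for a set S at ranked positions
    with weights w_j = r_j^tau,

        ES = sum_{j in S} w_j r_j / sum_{j in S} w_j
             - sum_{j not in S} r_j / (N - |S|),

    which is algebraically identical to the cumulative-sum definition and
    makes 100,000-draw nulls cheap.  Reproducible from ``seed``.
    """
    profile = _as_series(expr_profile)
    n = len(profile)
    if not 0 < set_size < n:
        raise ValueError(f"set_size must lie in (0, {n}); got {set_size}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    _, _ = _ranked_profile(profile)  # validate orderable
    r = np.arange(n, 0, -1, dtype=float)
    w = r**tau
    a = w * r
    b_total = r.sum()
    idx = _sample_index_sets(n, set_size, n_draws, rng)
    sum_a = a[idx].sum(axis=1)
    sum_w = w[idx].sum(axis=1)
    sum_b = r[idx].sum(axis=1)
    return sum_a / sum_w - (b_total - sum_b) / (n - set_size)


def empirical_pvalue(es: float, null_scores: np.ndarray) -> float:
    """Upper-tail empirical p with add-one smoothing: (1 + #{null >= es}) / (1 + N)."""
    null_scores = np.asarray(null_scores, dtype=float)
    if null_scores.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.count_nonzero(null_scores >= es)) / (1 + null_scores.size))


# ---------------------------------------------------------------------------
# subtype classification


@dataclass
class EnrichmentResult:
    unit_id: str
    set_name: str
    es: float
    null_mean: float
    null_sd: float
    p_emp: float

    @property
    def neglog10p(self) -> float:
        return -np.log10(self.p_emp)


@dataclass
class SubtypeCall:
    """Per-unit subtype assignment with the full per-signature evidence."""

    unit_id: str
    subtype: str
    results: list[EnrichmentResult]
    margin: float  # difference of the top two -log10 p
    ambiguous: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit": self.unit_id,
                "set_name": [r.set_name for r in self.results],
                "es": [r.es for r in self.results],
                "null_mean": [r.null_mean for r in self.results],
                "null_sd": [r.null_sd for r in self.results],
                "p_emp": [r.p_emp for r in self.results],
                "neglog10p": [r.neglog10p for r in self.results],
                "subtype": self.subtype,
                "margin": self.margin,
                "ambiguous": self.ambiguous,
            }
        )


def classify_subtype(
    expr_profile: pd.Series,
    subtype_library: ModuleLibrary,
    tau: float = 0.25,
    n_draws: int = 100_000,
    seed: int = 0,
) -> SubtypeCall:
    """Call the subtype of one profile: highest -log10 empirical p across signatures.

    Each signature gets its own size-matched null.  Ties on p are broken by
    higher raw enrichment score, then lexicographic signature name; a call
    that falls through to library order is flagged ambiguous.
    """
    profile = _as_series(expr_profile)
    names = subtype_library.names()
    if len(names) < 2:
        raise ValueError("need at least 2 subtype signatures")
    seed_root = np.random.SeedSequence(seed)
    results: list[EnrichmentResult] = []
    unit = str(profile.name) if profile.name is not None else "sample"
    # one null per distinct set size: the null depends on the profile and the
    # size only, so equal-size signatures share it (and identical signatures
    # therefore tie exactly)
    null_cache: dict[int, np.ndarray] = {}
    for name in names:
        members = [g for g in subtype_library[name] if g in profile.index]
        if not members:
            raise ValueError(f"signature {name!r} does not intersect the profile")
        es = ssgsea_score(profile, members, tau=tau)
        m = len(members)
        if m not in null_cache:
            child = seed_root.spawn(1)[0]
            null_cache[m] = build_empirical_null(
                profile, set_size=m, n_draws=n_draws, tau=tau,
                seed=child.generate_state(1)[0] % (2**31),
            )
        null = null_cache[m]
        results.append(
            EnrichmentResult(
                unit_id=unit, set_name=name, es=es,
                null_mean=float(null.mean()), null_sd=float(null.std(ddof=1)),
                p_emp=empirical_pvalue(es, null),
            )
        )
    order = sorted(
        range(len(results)),
        key=lambda i: (-results[i].neglog10p, -results[i].es, results[i].set_name, i),
    )
    top, runner = results[order[0]], results[order[1]]
    # evidence tie on both p and ES: the call falls through to name/library
    # order and is flagged so downstream consumers can treat it with caution
    ambiguous = top.p_emp == runner.p_emp and top.es == runner.es
    return SubtypeCall(
        unit_id=unit,
        subtype=top.set_name,
        results=results,
        margin=float(top.neglog10p - runner.neglog10p),
        ambiguous=bool(ambiguous),
    )


def classify_subtypes(
    expr_table: pd.DataFrame,
    subtype_library: ModuleLibrary,
    tau: float = 0.25,
    n_draws: int = 100_000,
    seed: int = 0,
) -> list[SubtypeCall]:
    """Classify every column (sample) of a genes x samples expression table."""
    children = np.random.SeedSequence(seed).spawn(expr_table.shape[1])
    calls = []
    for col, child in zip(expr_table.columns, children):
        calls.append(
            classify_subtype(
                expr_table[col], subtype_library, tau=tau, n_draws=n_draws,
                seed=child.generate_state(1)[0] % (2**31),
            )
        )
    return calls


def subtype_calls_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    return pd.concat([c.to_frame() for c in calls], ignore_index=True)


class SubtypeClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based subtype classifier over ssGSEA empirical-null evidence.

    sklearn-compatible surface: ``fit`` freezes the signature library (no
    parameters are learned from data — the signatures ARE the model), and
    ``predict`` labels each sample (rows of X) by the signature with the
    highest -log10 empirical p.

    Parameters
    ----------
    signatures : ModuleLibrary
        Subtype signature gene sets.
    tau : float
        Rank-weight exponent of the running sum.
    n_draws : int
        Random gene sets per null distribution.
    random_state : int
        Seed for the null draws.
    """

    def __init__(
        self,
        signatures: ModuleLibrary | None = None,
        tau: float = 0.25,
        n_draws: int = 10_000,
        random_state: int = 0,
    ):
        self.signatures = signatures
        self.tau = tau
        self.n_draws = n_draws
        self.random_state = random_state

    def fit(self, X=None, y=None):
        if self.signatures is None or len(self.signatures) < 2:
            raise ValueError("signatures must hold at least 2 gene sets")
        self.classes_ = np.array(self.signatures.names())
        self.n_features_in_ = None if X is None else np.shape(X)[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "classes_"):
            raise ValueError("SubtypeClassifier is not fitted; call fit() first")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """X: samples x genes expression table (sklearn orientation)."""
        self._check_fitted()
        calls = self.decision_calls(X)
        return np.array([c.subtype for c in calls])

    def decision_calls(self, X: pd.DataFrame) -> list[SubtypeCall]:
        self._check_fitted()
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x genes DataFrame with gene columns")
        return classify_subtypes(
            X.T, self.signatures, tau=self.tau, n_draws=self.n_draws,
            seed=self.random_state,
        )


# ---------------------------------------------------------------------------
# meta-module scores


def meta_module_score(norm: NormalizedMatrix | pd.DataFrame, module) -> np.ndarray:
    """Per-unit mean normalised expression over the module genes present."""
    if isinstance(norm, NormalizedMatrix):
        frame = None
        gene_ids, values = norm.gene_ids, norm.values
    else:
        frame = norm
        gene_ids, values = list(frame.index), frame.to_numpy()
    members = set(map(str, module))
    idx = [i for i, g in enumerate(gene_ids) if g in members]
    if not idx:
        raise ValueError("module has no genes in the matrix")
    return values[idx].mean(axis=0)


def module_score_table(
    norm: NormalizedMatrix,
    library: ModuleLibrary,
    modules: list[str] | None = None,
) -> pd.DataFrame:
    """units x modules table of meta-module scores."""
    names = modules if modules is not None else library.names()
    data = {name: meta_module_score(norm, library[name]) for name in names}
    return pd.DataFrame(data, index=norm.unit_ids)


def scaled_module_heatmap_scores(
    score_table: pd.DataFrame,
    group_labels,
) -> pd.DataFrame:
    """Group-mean module scores z-scaled within each module across groups.

    Scaling uses the sample SD (ddof=1), the convention of R ``scale()`` that
    heatmap tooling applies; modules with identical group means scale to zero.
    """
    labels = pd.Series(list(group_labels), index=score_table.index)
    means = score_table.groupby(labels, sort=True).mean()
    if means.shape[0] < 2:
        raise ValueError("z-scaling needs at least 2 groups")
    sd = means.std(axis=0, ddof=1)
    centered = means - means.mean(axis=0)
    scaled = centered.divide(sd.replace(0.0, np.nan), axis=1).fillna(0.0)
    return scaled


@dataclass
class DominantModuleResult:
    top_module: str
    second_module: str
    p_value: float
    significant: bool


def dominant_module_test(
    score_table: pd.DataFrame,
    modules: list[str] | None = None,
    group=None,
    alpha: float = 0.01,
) -> DominantModuleResult:
    """Most highly expressed module in a cell group, with paired significance.

    The top module is the highest mean score; p comes from a two-sided
    Wilcoxon signed-rank test of top vs runner-up per cell.  Requires at
    least 6 cells for the test to be defined.
    """
    table = score_table if group is None else score_table.loc[group]
    cols = modules if modules is not None else list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 modules")
    table = table[cols]
    if len(table) < 6:
        raise ValueError(f"only {len(table)} cells; dominant-module test needs >= 6")
    means = table.mean(axis=0).sort_values(ascending=False, kind="stable")
    top, second = means.index[0], means.index[1]
    diff = table[top].to_numpy() - table[second].to_numpy()
    if np.all(diff == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diff, alternative="two-sided").pvalue)
    return DominantModuleResult(
        top_module=str(top), second_module=str(second),
        p_value=p, significant=bool(p < alpha),
    )
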
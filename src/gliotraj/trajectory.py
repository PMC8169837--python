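"""Simplified diffusion-map pseudotime with tip-to-root random-walk branch
assignment, and stage-correlation mapping of stem-like cells.

The reconstruction follows the lineage-tree logic of diffusion-based
trajectory tools: a k-nearest-neighbour graph with a locally adaptive
Gaussian kernel (sigma_i = distance to the ceil(k/2)-th neighbour, edge
weight exp(-d^2 / (sigma_i sigma_j))), the spectral embedding of the
row-normalised transition operator, an iterative "flood" from user-declared
root cells that averages graph distances over random edge subsamples to give
each cell a pseudotime, and biased random walks from each terminal tip back
toward the root whose per-cell visitation frequencies partition cells into
tip-specific branches and shared trunk segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import breadth_first_order, connected_components
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import NearestNeighbors


@dataclass
class NeighborGraph:
    """Symmetric weighted kNN graph: Gaussian weights plus raw distances."""

    weights: sp.csr_matrix  # symmetric, zero diagonal
    distances: sp.csr_matrix  # same sparsity pattern
    sigmas: np.ndarray
    k: int

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]


@dataclass
class TrajectoryResult:
    """Per-cell trajectory summary: embedding, pseudotime, branch, visitation."""

    cell_ids: list[str]
    components: np.ndarray
    eigenvalues: np.ndarray
    pseudotime: np.ndarray
    branch: np.ndarray
    visitation: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"cell": self.cell_ids, "pseudotime": self.pseudotime,
                            "branch": self.branch})
        for j in range(self.components.shape[1]):
            out[f"DC{j + 1}"] = self.components[:, j]
        for col in self.visitation.columns:
            out[f"visit_{col}"] = self.visitation[col].to_numpy()
        return out


def knn_graph(X: np.ndarray, k: int = 200) -> NeighborGraph:
    """Symmetric kNN graph with a local-bandwidth Gaussian kernel.

    An edge exists if either endpoint lists the other among its k nearest
    (Euclidean) neighbours; sigma_i is the distance from cell i to its
    ceil(k/2)-th neighbour and the edge weight is exp(-d_ij^2 / (sigma_i
    sigma_j)).  k is auto-capped at n_cells - 1 with a warning.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells")
    if k >= n:
        warnings.warn(f"k={k} >= n_cells={n}; capping at {n - 1}", stacklevel=2)
        k = n - 1
    if k < 1:
        raise ValueError("k must be a positive integer")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto").fit(X)
    dist, idx = nn.kneighbors(X)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self

    half = int(np.ceil(k / 2))
    sigmas = dist[:, half - 1].copy()
    # duplicate-point guard: a zero bandwidth would blow up the kernel
    floor = dist[dist > 0].min() if (dist > 0).any() else 1.0
    sigmas = np.maximum(sigmas, floor * 1e-6)

    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    d = sp.coo_matrix((dist.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    d = d.maximum(d.T)  # union of neighbourhoods, symmetric distances
    d.eliminate_zeros()
    coo = d.tocoo()
    w = np.exp(-(coo.data**2) / (sigmas[coo.row] * sigmas[coo.col]))
    weights = sp.coo_matrix((w, (coo.row, coo.col)), shape=(n, n)).tocsr()
    return NeighborGraph(weights=weights, distances=d, sigmas=sigmas, k=k)


def diffusion_map(graph: NeighborGraph, k_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Spectral embedding of the row-normalised transition operator.

    Computed through the symmetrised operator D^{-1/2} W D^{-1/2} (same
    spectrum as the row-stochastic D^{-1} W); eigenvalues are returned sorted
    descending AFTER dropping the trivial unit eigenvalue with its constant
    eigenvector.  On a disconnected graph the largest component is embedded
    (warning) and excluded cells carry NaN.
    """
    n = graph.n_cells
    if k_components >= n:
        raise ValueError("k_components must be smaller than n_cells")
    n_comp, labels = connected_components(graph.weights, directed=False)
    keep = np.arange(n)
    if n_comp > 1:
        warnings.warn(
            f"graph has {n_comp} connected components; embedding the largest",
            stacklevel=2,
        )
        largest = np.bincount(labels).argmax()
        keep = np.flatnonzero(labels == largest)
    W = graph.weights[np.ix_(keep, keep)].tocsr()
    deg = np.asarray(W.sum(axis=1)).ravel()
    inv_sqrt = 1.0 / np.sqrt(deg)
    A = sp.diags(inv_sqrt) @ W @ sp.diags(inv_sqrt)
    m = len(keep)
    want = min(k_components + 1, m - 1)
    if m <= k_components + 2:
        vals, vecs = np.linalg.eigh(A.toarray())
        order = np.argsort(vals)[::-1][: k_components + 1]
        vals, vecs = vals[order], vecs[:, order]
    else:
        v0 = np.full(m, 1.0 / np.sqrt(m))  # deterministic Lanczos start
        vals, vecs = sp.linalg.eigsh(A, k=want, which="LA", v0=v0)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    # right eigenvectors of the row-stochastic operator
    psi = vecs * inv_sqrt[:, None]
    # drop the trivial constant eigenvector (eigenvalue 1)
    vals_out = vals[1 : k_components + 1]
    psi_out = psi[:, 1 : k_components + 1]
    # deterministic sign: largest-magnitude entry positive
    for j in range(psi_out.shape[1]):
        pivot = np.argmax(np.abs(psi_out[:, j]))
        if psi_out[pivot, j] < 0:
            psi_out[:, j] = -psi_out[:, j]
    components = np.full((n, psi_out.shape[1]), np.nan)
    components[keep] = psi_out
    return components, vals_out


def pseudotime_from_root(
    graph: NeighborGraph,
    root_cells,
    n_iterations: int = 100,
    edge_subsample: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Iterative graph flood from the root cells, normalised to [0, 1].

    Each iteration keeps a random ``edge_subsample`` fraction of edges and
    propagates outward from the roots in waves: a newly reached cell's time is
    the mean over its already-reached included neighbours of (neighbour time +
    edge distance).  Per-cell times are averaged over iterations, shifted so
    roots sit at 0, and scaled to max 1.  Cells never reached carry NaN.
    """
    roots = np.asarray(list(root_cells), dtype=int)
    if roots.size == 0:
        raise ValueError("root set must be non-empty")
    n = graph.n_cells
    coo = sp.triu(graph.distances, k=1).tocoo()
    edges_i, edges_j, edges_d = coo.row, coo.col, coo.data
    rng = np.random.default_rng(seed)

    total = np.zeros(n)
    reached = np.zeros(n, dtype=int)
    root_mask = np.zeros(n, dtype=bool)
    root_mask[roots] = True

    for _ in range(n_iterations):
        inc = rng.random(len(edges_d)) < edge_subsample
        A = sp.coo_matrix(
            (np.ones(inc.sum()), (edges_i[inc], edges_j[inc])), shape=(n, n)
        )
        D = sp.coo_matrix((edges_d[inc], (edges_i[inc], edges_j[inc])), shape=(n, n))
        A = (A + A.T).tocsr()
        D = (D + D.T).tocsr()

        pt = np.zeros(n)
        assigned = root_mask.copy()
        while True:
            avec = assigned.astype(float)
            cnt = A @ avec
            frontier = (~assigned) & (cnt > 0)
            if not frontier.any():
                break
            sum_pt = A @ (pt * avec)
            sum_d = D @ avec
            pt[frontier] = (sum_pt[frontier] + sum_d[frontier]) / cnt[frontier]
            assigned |= frontier
        total[assigned] += pt[assigned]
        reached[assigned] += 1

    with np.errstate(invalid="ignore"):
        mean_pt = np.where(reached > 0, total / np.maximum(reached, 1), np.nan)
    if np.isnan(mean_pt[~root_mask]).any():
        warnings.warn(
            f"{int(np.isnan(mean_pt).sum())} cell(s) unreachable from the root; "
            "their pseudotime is NaN", stacklevel=2,
        )
    mean_pt = mean_pt - 0.0  # roots are exactly 0 by construction
    top = np.nanmax(mean_pt)
    if top > 0:
        mean_pt = mean_pt / top
    return mean_pt


def _diameter_estimate(graph: NeighborGraph, start: int = 0) -> int:
    """Double-BFS hop-count estimate of the graph diameter."""
    order1 = breadth_first_order(graph.weights, start, directed=False, return_predecessors=False)
    far = order1[-1]
    order2, preds = breadth_first_order(graph.weights, far, directed=False)
    hops = 0
    node = order2[-1]
    while preds[node] >= 0:
        node = preds[node]
        hops += 1
    return max(hops, 1)


def random_walk_branches(
    graph: NeighborGraph,
    pseudotime: np.ndarray,
    tips: dict[str, list[int]],
    root_cells,
    n_walks: int = 1_000,
    seed: int = 0,
    visit_threshold: float = 0.3,
    pt_window: float | None = None,
    max_steps: int | None = None,
    max_nonterminating_frac: float = 0.05,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Assign cells to branches by tip-to-root biased random walks.

    From each tip, ``n_walks`` walks step to neighbours with probability
    proportional to edge weight, restricted to neighbours whose pseudotime is
    at most (current + window) — the root-ward bias — and stop at any root
    cell or after ``max_steps``.  The window defaults to the 25th percentile of per-edge
    pseudotime increments (wide enough that noisy pseudotime does not stall
    the walk, tight enough that it descends quickly and does not linger at
    branch points); the step cap to 50x a
    double-BFS diameter estimate.  A cell visited above ``visit_threshold``
    by exactly
    one tip joins that tip's branch; by two or more, the shared segment;
    otherwise it is unassigned.  Tip cells always carry their own label.
    """
    pt = np.asarray(pseudotime, dtype=float)
    n = graph.n_cells
    roots = np.asarray(list(root_cells), dtype=int)
    root_mask = np.zeros(n, dtype=bool)
    root_mask[roots] = True
    for label, cells in tips.items():
        if root_mask[np.asarray(cells, dtype=int)].any():
            raise ValueError(f"tip {label!r} overlaps the root set")

    W = graph.weights.tocsr()
    if pt_window is None:
        coo = sp.triu(graph.distances, k=1).tocoo()
        incs = np.abs(pt[coo.row] - pt[coo.col])
        incs = incs[np.isfinite(incs)]
        pt_window = float(np.percentile(incs, 25)) if incs.size else 0.0
    if max_steps is None:
        max_steps = 50 * _diameter_estimate(graph)

    # static flat allowed-neighbour tables (the window is fixed), laid out so
    # one global searchsorted samples a weighted neighbour for every walk
    indptr, indices, data = W.indptr, W.indices, W.data
    flat_nbrs: list[np.ndarray] = []
    seg_cumw: list[np.ndarray] = []
    for i in range(n):
        nbrs = indices[indptr[i]:indptr[i + 1]]
        wts = data[indptr[i]:indptr[i + 1]]
        ok = pt[nbrs] <= pt[i] + pt_window
        flat_nbrs.append(nbrs[ok])
        seg_cumw.append(np.cumsum(wts[ok]))
    seg_len = np.array([len(s) for s in seg_cumw])
    seg_off = np.concatenate([[0], np.cumsum(seg_len)[:-1]])
    totals = np.array([s[-1] if len(s) else 0.0 for s in seg_cumw])
    big = (totals.max() if totals.size else 1.0) * 2 + 1.0
    flat_cumw = (
        np.concatenate([s + i * big for i, s in enumerate(seg_cumw) if len(s)])
        if seg_len.sum() else np.array([])
    )
    # flat_cumw is globally increasing: segment i occupies [i*big, i*big + total_i]
    flat_nbr_arr = np.concatenate([a for a in flat_nbrs if len(a)]) if seg_len.sum() else np.array([], int)
    # map flat_cumw position back to neighbour: positions align 1:1
    _ = seg_off  # retained for clarity of the layout

    rng = np.random.default_rng(seed)
    visits = {label: np.zeros(n) for label in tips}
    n_nonterm = 0
    n_total = 0
    for label in sorted(tips):
        tip_cells = np.asarray(tips[label], dtype=int)
        current = tip_cells[rng.integers(len(tip_cells), size=n_walks)]
        visited = np.zeros((n_walks, n), dtype=bool)
        visited[np.arange(n_walks), current] = True
        active = ~root_mask[current]
        stuck = np.zeros(n_walks, dtype=bool)
        for _ in range(max_steps):
            if not active.any():
                break
            idx = np.flatnonzero(active)
            cur = current[idx]
            dead = seg_len[cur] == 0
            if dead.any():
                stuck[idx[dead]] = True
                active[idx[dead]] = False
                idx, cur = idx[~dead], cur[~dead]
                if idx.size == 0:
                    continue
            u = rng.random(idx.size) * totals[cur]
            pos = np.searchsorted(flat_cumw, cur * big + u, side="right")
            nxt = flat_nbr_arr[pos]
            current[idx] = nxt
            visited[idx, nxt] = True
            arrived = root_mask[nxt]
            if arrived.any():
                active[idx[arrived]] = False
        failed = active | stuck
        n_nonterm += int(failed.sum())
        n_total += n_walks
        # only walks that actually reach the root vote: a wandering failed
        # walk says nothing about tip-to-root route membership
        visits[label] += visited[~failed].sum(axis=0) / max(1, int((~failed).sum())) * n_walks

    if n_total and n_nonterm / n_total > max_nonterminating_frac:
        raise RuntimeError(
            f"{n_nonterm}/{n_total} random walks failed to reach the root; "
            "widen pt_window, raise max_steps, or check the root/pseudotime setup"
        )
    if n_nonterm:
        warnings.warn(f"{n_nonterm}/{n_total} walks hit the step cap", stacklevel=2)

    visitation = pd.DataFrame({label: visits[label] / n_walks for label in sorted(tips)})
    above = visitation.to_numpy() >= visit_threshold
    n_above = above.sum(axis=1)
    tip_names = list(visitation.columns)
    branch = np.where(
        n_above == 0, "unassigned",
        np.where(n_above >= 2, "segment/shared",
                 np.array(tip_names, dtype=object)[np.argmax(above, axis=1)]),
    ).astype(object)
    for label, cells in tips.items():
        branch[np.asarray(cells, dtype=int)] = label
    return branch, visitation


def stage_correlation_map(
    query_profiles: pd.DataFrame,
    reference_matrix: pd.DataFrame,
    stage_labels,
    gene_panel,
    stage_order: list[str] | None = None,
    hybrid_margin: float = 0.05,
    low_confidence_r: float = 0.1,
) -> pd.DataFrame:
    """Correlate query cells with reference stages on a stage-specific gene panel.

    For each query unit (column of ``query_profiles``): the mean Pearson r
    against reference cells of each stage, computed over the panel genes
    shared by both matrices; the stage-like label is the top stage, or a
    hybrid "X/Y-like" when the top two stages' mean r differ by less than
    ``hybrid_margin``.  Labels with max mean r below ``low_confidence_r``
    are flagged low-confidence.
    """
    panel = [g for g in dict.fromkeys(map(str, gene_panel))
             if g in query_profiles.index and g in reference_matrix.index]
    if len(panel) < 10:
        raise ValueError(f"gene panel intersects both matrices on only {len(panel)} genes (<10)")
    labels = pd.Series(list(stage_labels))
    if len(labels) != reference_matrix.shape[1]:
        raise ValueError("one stage label per reference cell is required")
    stages = stage_order if stage_order is not None else sorted(labels.unique())

    Q = query_profiles.loc[panel].to_numpy(dtype=float)
    R = reference_matrix.loc[panel].to_numpy(dtype=float)
    Qc = Q - Q.mean(axis=0)
    Rc = R - R.mean(axis=0)
    qn = np.linalg.norm(Qc, axis=0)
    rn = np.linalg.norm(Rc, axis=0)
    qn[qn == 0] = np.nan
    rn[rn == 0] = np.nan
    corr = (Qc / qn).T @ (Rc / rn)  # queries x reference cells

    rows = []
    for qi, qname in enumerate(query_profiles.columns):
        means = {}
        for stage in stages:
            mask = (labels == stage).to_numpy()
            if not mask.any():
                raise ValueError(f"reference stage {stage!r} has no cells")
            means[stage] = float(np.nanmean(corr[qi, mask]))
        ranked = sorted(stages, key=lambda s: -means[s])
        top, second = ranked[0], ranked[1]
        if means[top] - means[second] < hybrid_margin:
            first, later = sorted([top, second], key=stages.index)
            label = f"{first}/{later}-like"
        else:
            label = f"{top}-like"
        row = {"query": qname, "stage_like": label,
               "low_confidence": bool(means[top] < low_confidence_r)}
        row.update({f"mean_r_{s}": means[s] for s in stages})
        rows.append(row)
    return pd.DataFrame(rows)


class DiffusionTrajectory(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper: kNN graph -> diffusion embedding -> pseudotime -> branches.

    ``fit(X)`` builds the graph and the spectral embedding; passing
    ``roots=...`` also infers pseudotime, and ``tips=...`` additionally runs
    the random-walk branch assignment.  ``transform`` returns the diffusion
    components.  Fitted attributes: ``graph_``, ``components_``,
    ``eigenvalues_``, ``pseudotime_``, ``branch_``, ``visitation_``.
    """

    def __init__(
        self,
        k: int = 200,
        n_components: int = 2,
        n_iterations: int = 100,
        edge_subsample: float = 0.5,
        n_walks: int = 1_000,
        visit_threshold: float = 0.3,
        random_state: int = 0,
    ):
        self.k = k
        self.n_components = n_components
        self.n_iterations = n_iterations
        self.edge_subsample = edge_subsample
        self.n_walks = n_walks
        self.visit_threshold = visit_threshold
        self.random_state = random_state

    def fit(self, X, y=None, roots=None, tips=None):
        X = np.asarray(X, dtype=float)
        self.graph_ = knn_graph(X, k=self.k)
        self.components_, self.eigenvalues_ = diffusion_map(
            self.graph_, k_components=self.n_components
        )
        self.pseudotime_ = None
        self.branch_ = None
        self.visitation_ = None
        if roots is not None:
            self.pseudotime_ = pseudotime_from_root(
                self.graph_, roots, n_iterations=self.n_iterations,
                edge_subsample=self.edge_subsample, seed=self.random_state,
            )
            if tips is not None:
                self.branch_, self.visitation_ = random_walk_branches(
                    self.graph_, self.pseudotime_, tips, roots,
                    n_walks=self.n_walks, seed=self.random_state,
                    visit_threshold=self.visit_threshold,
                )
        return self

    def transform(self, X=None):
        if not hasattr(self, "components_"):
            raise ValueError("DiffusionTrajectory is not fitted; call fit() first")
        return self.components_

    def result(self, cell_ids: list[str] | None = None) -> TrajectoryResult:
        if not hasattr(self, "components_"):
            raise ValueError("DiffusionTrajectory is not fitted; call fit() first")
        n = self.graph_.n_cells
        ids = cell_ids if cell_ids is not None else [f"cell{i}" for i in range(n)]
        return TrajectoryResult(
            cell_ids=list(ids),
            components=self.components_,
            eigenvalues=self.eigenvalues_,
            pseudotime=self.pseudotime_ if self.pseudotime_ is not None else np.full(n, np.nan),
            branch=self.branch_ if self.branch_ is not None else np.array(["unassigned"] * n, dtype=object),
            visitation=self.visitation_ if self.visitation_ is not None else pd.DataFrame(index=range(n)),
        )
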
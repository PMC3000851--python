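"""Multivariate analysis of the wavenumber panel.

Hierarchical cluster analysis uses correlation distance between samples
(d = 1 - Pearson r across the panel features) and unweighted pair-group
average linkage (UPGMA); principal components analysis retains every
component explaining at least 5% of the variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SpectrumCohort


@dataclass
class PanelMatrix:
    """Per-sample second-derivative values at the panel wavenumbers."""

    features: np.ndarray          # (n_samples, n_panel)
    wavenumbers: np.ndarray       # panel wavenumbers actually used (grid points)
    meta: pd.DataFrame            # sample_id, class, metadata (one row per sample)

    @property
    def sample_ids(self) -> list:
        return list(self.meta["sample_id"])

    @property
    def class_labels(self) -> np.ndarray:
        return self.meta["class"].to_numpy()


def build_panel_matrix(cohort: SpectrumCohort, panel: list[float]) -> PanelMatrix:
    """Extract features at the grid points nearest each panel wavenumber.

    ``cohort`` must hold one (aggregated) spectrum per sample.
    """
    if not panel:
        raise ValueError("panel is empty")
    if len(set(cohort.meta["sample_id"])) != cohort.n_spectra:
        raise ValueError("panel matrix needs one spectrum per sample; aggregate replicates first")
    idx = [cohort.grid.nearest_index(w) for w in sorted(panel)]
    return PanelMatrix(
        features=cohort.matrix[:, idx].copy(),
        wavenumbers=cohort.grid.values[idx].copy(),
        meta=cohort.meta.copy(),
    )


def correlation_distance_matrix(panel: PanelMatrix) -> np.ndarray:
    """d(i, j) = 1 - Pearson correlation between sample feature vectors."""
    x = panel.features
    if x.shape[1] < 2:
        raise ValueError("correlation distance needs >= 2 features")
    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        sid = panel.sample_ids[int(flat[0])]
        raise ValueError(f"sample {sid!r} has zero feature variance")
    centred = x - x.mean(axis=1, keepdims=True)
    centred /= np.linalg.norm(centred, axis=1, keepdims=True)
    d = 1.0 - centred @ centred.T
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


@dataclass
class DendrogramTree:
    """Agglomerative merge tree in scipy linkage layout.

    ``merges`` is (n-1, 4): the two merged node ids (leaves are 0..n-1,
    internal nodes n, n+1, ... in merge order), the merge height, and the
    leaf count of the new node. Heights are non-decreasing (UPGMA).
    """

    merges: np.ndarray
    labels: list

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def upgma_tree(distances: np.ndarray, labels) -> DendrogramTree:
    """Average-linkage (UPGMA) agglomeration of a symmetric distance matrix.

    Inter-cluster distance is the arithmetic mean over all cross-pair leaf
    distances. Ties are broken deterministically by the lexicographically
    smallest pair of smallest-member leaf indices.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    labels = list(labels)
    if d.ndim != 2 or d.shape != (n, n) or len(labels) != n or n < 2:
        raise ValueError("need a square distance matrix with matching labels, n >= 2")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if np.any(d < 0):
        raise ValueError("distance matrix has negative entries")

    # state per active cluster: node id, leaf members, first (smallest) leaf
    active = {i: {"id": i, "leaves": [i]} for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]
    merges = []
    next_id = n
    keys = sorted(active)
    while len(keys) > 1:
        best = None
        for a_pos, a in enumerate(keys):
            for b in keys[a_pos + 1:]:
                cand = (dist[(a, b)], a, b)
                if best is None or cand < best:
                    best = cand
        h, a, b = best
        ca, cb = active.pop(a), active.pop(b)
        sa, sb = len(ca["leaves"]), len(cb["leaves"])
        merged = {"id": next_id, "leaves": ca["leaves"] + cb["leaves"]}
        merges.append([ca["id"], cb["id"], h, sa + sb])
        keys = sorted(active)
        new_key = min(a, b)
        for other in keys:
            pa = (min(a, other), max(a, other))
            pb = (min(b, other), max(b, other))
            avg = (sa * dist.pop(pa) + sb * dist.pop(pb)) / (sa + sb)
            dist[(min(new_key, other), max(new_key, other))] = avg
        del dist[(a, b)]
        active[new_key] = merged
        keys = sorted(active)
        next_id += 1
    return DendrogramTree(np.array(merges, dtype=float), labels)


def cut_tree(tree: DendrogramTree, k: int) -> np.ndarray:
    """Cluster assignment per leaf after undoing the k-1 highest merges.

    Clusters are numbered 0..k-1 by increasing first-leaf position.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(n + len(tree.merges)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for t, (a, b, _, _) in enumerate(tree.merges[: n - k]):
        node = n + t
        parent[find(int(a))] = node
        parent[find(int(b))] = node
    roots = [find(i) for i in range(n)]
    relabel = {}
    out = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in relabel:
            relabel[r] = len(relabel)
        out[i] = relabel[r]
    return out


def to_newick(tree: DendrogramTree) -> str:
    """Newick serialisation; branch length = parent height - child height."""
    n = tree.n_leaves
    height = {i: 0.0 for i in range(n)}
    children = {}
    for t, (a, b, h, _) in enumerate(tree.merges):
        node = n + t
        children[node] = (int(a), int(b))
        height[node] = float(h)

    def render(node: int, parent_h: float) -> str:
        length = parent_h - height[node]
        if node < n:
            return f"{tree.labels[node]}:{length:.10g}"
        a, b = children[node]
        inner = ",".join(render(c, height[node]) for c in (a, b))
        return f"({inner}):{length:.10g}"

    root = n + len(tree.merges) - 1
    a, b = children[root]
    inner = ",".join(render(c, height[root]) for c in (a, b))
    return f"({inner});"


def cluster_purity(assignment, class_labels) -> dict:
    """Cluster composition and per-class capture percentages.

    For each class, capture = percentage of that class's samples falling in
    the cluster where the class is the majority (ties broken by lower cluster
    id). Also returns the full contingency table cluster x class.
    """
    assignment = np.asarray(assignment)
    class_labels = np.asarray(class_labels)
    if assignment.shape != class_labels.shape:
        raise ValueError("assignment and class_labels must have the same length")
    contingency = pd.crosstab(pd.Series(assignment, name="cluster"),
                              pd.Series(class_labels, name="class"))
    capture = {}
    majority = {}
    for cls in contingency.columns:
        col = contingency[cls]
        best = int(col.idxmax())
        majority[cls] = best
        capture[cls] = 100.0 * float(col.loc[best]) / float(col.sum())
    return {"contingency": contingency, "capture": capture,
            "majority_cluster": majority}


@dataclass
class PCAResult:
    scores: np.ndarray             # samples x components
    loadings: np.ndarray           # features x components, orthonormal columns
    variance_fraction: np.ndarray  # non-increasing, sums to 1
    retained: int                  # components with fraction >= threshold
    mean: np.ndarray = field(repr=False, default=None)
    scale: np.ndarray = field(repr=False, default=None)


def pca_panel(panel: PanelMatrix | np.ndarray, standardize: bool = True,
              retention_threshold: float = 0.05) -> PCAResult:
    """PCA by eigendecomposition of the (centred, optionally standardised)
    feature covariance; components with variance fraction >= threshold are
    retained. Loading signs are fixed so each column's largest-|entry| is
    positive."""
    x = panel.features if isinstance(panel, PanelMatrix) else np.asarray(panel, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-d matrix with >= 2 samples")
    mean = x.mean(axis=0)
    centred = x - mean
    scale = None
    if standardize:
        scale = centred.std(axis=0, ddof=1)
        flat = np.flatnonzero(scale == 0)
        if flat.size:
            raise ValueError(f"feature {int(flat[0])} has zero variance; "
                             "cannot standardise")
        centred = centred / scale
    cov = centred.T @ centred / (x.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    fractions = eigval / eigval.sum()
    retained = int(np.sum(fractions >= retention_threshold))
    return PCAResult(scores=centred @ eigvec, loadings=eigvec,
                     variance_fraction=fractions, retained=retained,
                     mean=mean, scale=scale)
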
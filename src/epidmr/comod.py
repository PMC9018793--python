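"""Coexpression-style module detection on methylation windows, and
module-trait correlation.

A WGCNA-style single-block workflow: windows are ranked by mean RPKM and
the top set retained; pairwise unsigned Pearson adjacency a_ij = |r_ij|^power
is transformed to topological overlap (TOM); 1 - TOM feeds average-linkage
hierarchical clustering with a static height cut (a simplified stand-in for
dynamic tree cut); small clusters are left unassigned ("grey"); modules
whose eigengenes are highly correlated are merged; and each module
eigengene (first principal component of the standardized member profiles)
is correlated with sample traits using Pearson r and the Student-t p value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

from .genome import InvalidParameterError

# WGCNA-style module label sequence, assigned by decreasing module size
MODULE_COLORS = ["turquoise", "blue", "brown", "yellow", "green", "red",
                 "black", "pink", "magenta", "purple", "greenyellow", "tan",
                 "salmon", "cyan", "midnightblue", "lightcyan", "grey60",
                 "lightgreen", "lightyellow", "royalblue"]
GREY = "grey"

# single-block ceiling; larger inputs should reduce n_top instead
MAX_BLOCK_SIZE = 15_000


@dataclass
class ModuleAssignment:
    """Window -> module label; ``grey`` marks unassigned windows."""

    labels: np.ndarray                  # per selected window, dtype object
    merge_heights: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def module_sizes(self) -> pd.Series:
        return pd.Series(self.labels).value_counts()

    def modules(self) -> list[str]:
        """Non-grey labels, largest first."""
        counts = pd.Series(self.labels).value_counts()
        return [m for m in counts.index if m != GREY]


def select_top_windows(rpkm_matrix: np.ndarray, n_top: int,
                       rank_by: str = "mean_rpkm") -> np.ndarray:
    """Indices of the top windows by mean RPKM (default) or total depth.

    Ties break toward the lower genome ordinal. Returned indices are in
    genome order.
    """
    if n_top <= 0:
        raise InvalidParameterError("n_top must be positive")
    n = rpkm_matrix.shape[0]
    if n_top > n:
        raise InvalidParameterError(f"n_top {n_top} exceeds {n} windows")
    score = rpkm_matrix.mean(axis=1) if rank_by == "mean_rpkm" else rpkm_matrix.sum(axis=1)
    order = np.lexsort((np.arange(n), -score))  # by -score, then ordinal
    return np.sort(order[:n_top])


def adjacency(profiles: np.ndarray, power: float = 4.0) -> np.ndarray:
    """Unsigned weighted adjacency |cor|^power between window profiles.

    ``profiles`` is windows x samples. Zero-variance windows correlate 0
    with everything by convention; the diagonal is 1.
    """
    if profiles.shape[1] < 3:
        raise InvalidParameterError("need at least 3 samples")
    if power <= 0:
        raise InvalidParameterError("power must be positive")
    x = np.asarray(profiles, dtype=float)
    sd = x.std(axis=1)
    ok = sd > 0
    z = np.zeros_like(x)
    z[ok] = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    r = z @ z.T / x.shape[1]
    np.clip(r, -1.0, 1.0, out=r)
    a = np.abs(r) ** power
    np.fill_diagonal(a, 1.0)
    return a


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k_i = sum_{u != i} a_iu; TOM_ii = 1.
    """
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InvalidParameterError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise InvalidParameterError("adjacency must be symmetric")
    n = a.shape[0]
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    k = off.sum(axis=1)
    shared = off @ off          # sum_u a_iu a_uj over all u != i (u=j term = a_ij*a_jj(0))
    shared -= 0.0               # diagonals of `off` are zero, so u=i, u=j excluded
    num = shared + off
    den = np.minimum.outer(k, k) + 1.0 - off
    tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(tom_dissim: np.ndarray, min_module_size: int = 30,
                   cut_height_frac: float = 0.99) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters are formed by cutting the dendrogram at ``cut_height_frac``
    times the maximum merge height; clusters smaller than
    ``min_module_size`` are left grey. Labels are assigned by decreasing
    cluster size.
    """
    d = np.asarray(tom_dissim, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InvalidParameterError("dissimilarity must be square")
    if min_module_size < 2:
        raise InvalidParameterError("min_module_size must be >= 2")
    n = d.shape[0]
    if n > MAX_BLOCK_SIZE:
        raise InvalidParameterError(
            f"{n} windows exceeds the single-block limit {MAX_BLOCK_SIZE}; "
            "reduce n_top in window selection")
    labels = np.full(n, GREY, dtype=object)
    if n < 2:
        return ModuleAssignment(labels)
    z = linkage(squareform(np.clip(d, 0, None), checks=False), method="average")
    heights = z[:, 2]
    max_h = heights[-1]
    if max_h <= 0:   # all-identical profiles: one module
        if n >= min_module_size:
            labels[:] = MODULE_COLORS[0]
        return ModuleAssignment(labels, heights)
    cl = fcluster(z, t=cut_height_frac * max_h, criterion="distance")
    sizes = pd.Series(cl).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= min_module_size]
    for rank, c in enumerate(keep):
        labels[cl == c] = MODULE_COLORS[rank % len(MODULE_COLORS)]
    return ModuleAssignment(labels, heights)


def module_eigengene(profiles: np.ndarray, member_idx: np.ndarray) -> np.ndarray:
    """First principal component of the standardized member profiles.

    Returned as a per-sample vector with unit variance, oriented so its
    correlation with the member-mean profile is non-negative.
    """
    if profiles.shape[1] < 2:
        raise InvalidParameterError("need at least 2 samples")
    x = np.asarray(profiles[member_idx], dtype=float)
    if x.shape[0] == 0:
        raise InvalidParameterError("empty module")
    sd = x.std(axis=1)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    # first right singular vector = first PC over samples
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    s = eig.std()
    return eig / s if s > 0 else eig


def eigengene_matrix(profiles: np.ndarray, assignment: ModuleAssignment
                     ) -> pd.DataFrame:
    """Samples x modules eigengene table (non-grey modules, largest first)."""
    cols = {}
    for m in assignment.modules():
        idx = np.flatnonzero(assignment.labels == m)
        cols[m] = module_eigengene(profiles, idx)
    return pd.DataFrame(cols)


def merge_close_modules(profiles: np.ndarray, assignment: ModuleAssignment,
                        merge_cut_height: float = 0.25) -> ModuleAssignment:
    """Merge modules whose eigengene correlation distance is below the cut.

    Single linkage over 1 - cor(eigengenes), iterated to a fixed point;
    eigengenes are recomputed after every merge round. The surviving label
    of a merged group is its largest module's.
    """
    if not 0 < merge_cut_height < 1:
        raise InvalidParameterError("merge_cut_height must be in (0, 1)")
    labels = assignment.labels.copy()
    while True:
        mods = [m for m in pd.Series(labels).value_counts().index if m != GREY]
        if len(mods) < 2:
            break
        eg = np.column_stack([module_eigengene(profiles, np.flatnonzero(labels == m))
                              for m in mods])
        r = np.corrcoef(eg.T)
        dist = 1.0 - r
        close = [(i, j) for i in range(len(mods)) for j in range(i + 1, len(mods))
                 if dist[i, j] < merge_cut_height]
        if not close:
            break
        # union-find over close pairs (single linkage at this height)
        parent = list(range(len(mods)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in close:
            parent[find(j)] = find(i)
        for j, m in enumerate(mods):
            root = mods[find(j)]   # mods sorted by size: root label is the largest member's
            if root != m:
                labels[labels == m] = root
    return ModuleAssignment(labels, assignment.merge_heights)


def module_trait_correlation(eigengenes: pd.DataFrame,
                             traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and Student-t p for every module x trait pair.

    p = 2 P(T_{n-2} >= |t|) with t = r sqrt(n-2) / sqrt(1-r^2); |r| = 1
    gives p = 0. Zero-variance traits yield missing r and p.
    """
    n = len(eigengenes)
    if n < 3:
        raise InvalidParameterError("need at least 3 samples")
    if len(traits) != n:
        raise InvalidParameterError("traits and eigengenes disagree on sample count")
    rows = []
    for m in eigengenes.columns:
        e = eigengenes[m].to_numpy(float)
        for tr in traits.columns:
            y = traits[tr].to_numpy(float)
            if np.std(y) == 0 or np.std(e) == 0:
                rows.append({"module": m, "trait": tr, "r": np.nan, "p": np.nan, "n": n})
                continue
            r = float(np.corrcoef(e, y)[0, 1])
            r = max(-1.0, min(1.0, r))
            rows.append({"module": m, "trait": tr, "r": r,
                         "p": corr_pvalue_student(r, n), "n": n})
    return pd.DataFrame(rows)


def corr_pvalue_student(r: float, n: int) -> float:
    """Two-sided Student-t p value for a Pearson correlation."""
    if abs(r) >= 1.0:
        return 0.0
    tval = abs(r) * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * t_dist.sf(tval, df=n - 2))
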
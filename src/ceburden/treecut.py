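"""Dynamic hybrid tree cut for co-expression dendrograms.

Module detection on the average-linkage tree of the topological-overlap
dissimilarity, in the spirit of the dynamic hybrid method: candidate
branches come from the dendrogram's nesting, and each candidate is judged
by the similarity structure it spans rather than by raw merge heights —
high soft-threshold powers compress heights into a sliver below one, where
absolute height criteria are uninformative.

The tree is walked top-down.  At each node the branch is first *purified*
(members much less connected than the branch's own connectivity scale are
set aside), then accepted as a module if the purified branch (i) retains
the majority of the node, (ii) meets the minimum module size, and (iii) is
internally more similar than to the rest of the network by the deep-split
dependent separation factor.  Rejected nodes are split into their children
and the walk continues.  A PAM-like stage then assigns leftover features to
the module they are closest to, but only if they are at least twice as
similar to it as to the feature population at large — so branch stragglers
are rescued while noise features and blocks smaller than the minimum
module size stay unassigned (label 0).
"""

from __future__ import annotations

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = ["cutree_hybrid"]

# deep_split (0..4) ladders; lower deep split demands stronger separation
# and hence yields fewer, coarser modules.  The soft power amplifies
# similarity contrasts multiplicatively: genuine module boundaries show
# within/cross ratios in the tens to hundreds, within-module heterogeneity
# stays within a small factor, and loosely self-similar noise subtrees
# reach modest ratios against the background — so splitting is permissive
# while module acceptance demands an order of magnitude of separation.
_SPLIT_LADDER = (8.0, 6.0, 4.0, 3.0, 2.0)
_ACCEPT_LADDER = (50.0, 30.0, 20.0, 12.0, 8.0)

#: members whose mean within-branch similarity falls below this fraction of
#: the branch's upper-tier (90th percentile) connectivity are set aside
#: during purification; topological overlaps span orders of magnitude under
#: high soft powers, so the tolerance is generous on the linear scale
_PURIFY_FRACTION = 0.05

#: purified branch must keep at least this share of the node
_COVERAGE = 0.5

#: PAM stage: required ratio of similarity-to-module over mean background
#: similarity for an unassigned feature to join a module
_PAM_SIM_RATIO = 2.0

#: a branch whose member connectivities split into two tiers differing by
#: at least this factor (geometric means) is purged to its upper tier
_BIMODAL_FACTOR = 10.0

#: minimum mean within-module topological overlap for the whole network to
#: count as one homogeneous module (fallback when no substructure exists)
_MIN_GLOBAL_TOM = 0.01


def _otsu_split(v: np.ndarray) -> tuple[float, float] | None:
    """Best two-class split of sorted values; returns (threshold, mean gap)."""
    n = len(v)
    if n < 3 or v[0] == v[-1]:
        return None
    csum = np.cumsum(v)
    total = csum[-1]
    best, thr, gap = -np.inf, v[-1], 0.0
    for i in range(1, n):
        m0 = csum[i - 1] / i
        m1 = (total - csum[i - 1]) / (n - i)
        bc = i * (n - i) * (m0 - m1) ** 2
        if bc > best:
            best, thr, gap = bc, (v[i - 1] + v[i]) / 2.0, m1 - m0
    return thr, gap


def cutree_hybrid(
    diss: np.ndarray,
    linkage: np.ndarray | None = None,
    deep_split: int = 2,
    min_cluster_size: int = 15,
    cut_height: float | None = None,
    pam: bool = True,
) -> np.ndarray:
    """Cut a dendrogram of ``diss`` into modules; returns labels (0 = none).

    Modules are numbered 1..k by decreasing size.  ``cut_height``, when
    given, excludes merges above it from forming branches (a static gate);
    by default the branch criteria decide alone.
    """
    diss = np.asarray(diss, dtype=float)
    n = diss.shape[0]
    if diss.ndim != 2 or diss.shape[0] != diss.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(diss, diss.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    if n < 2:
        return np.zeros(n, dtype=int)
    if linkage is None:
        linkage = hierarchy.linkage(squareform(diss, checks=False), method="average")
    split_required = _SPLIT_LADDER[deep_split]
    accept_required = _ACCEPT_LADDER[deep_split]
    sim = 1.0 - diss
    np.fill_diagonal(sim, 0.0)
    row_sum = sim.sum(axis=1)

    children = linkage[:, :2].astype(int)
    heights = linkage[:, 2]
    n_merge = len(heights)
    members: list[np.ndarray] = [np.array([i]) for i in range(n)]
    in_sum: list[float] = [0.0] * n  # sum of within-branch similarities
    cross_sum: list[float] = [0.0] * n_merge  # between the two children
    for i in range(n_merge):
        a, b = children[i]
        members.append(np.concatenate([members[a], members[b]]))
        cross = float(sim[np.ix_(members[a], members[b])].sum())
        cross_sum[i] = cross
        in_sum.append(in_sum[a] + in_sum[b] + 2.0 * cross)

    def mean_in(nid: int) -> float:
        m = len(members[nid])
        return in_sum[nid] / (m * (m - 1)) if m > 1 else np.inf

    def should_split(i: int) -> bool:
        """Split where both children are internally much more similar than
        they are to each other (decorrelated sub-branches)."""
        a, b = children[i]
        ma, mb = len(members[a]), len(members[b])
        if ma < 2 or mb < 2:
            return False
        cross = cross_sum[i] / (ma * mb)
        if cross <= 0:
            return True
        return min(mean_in(a), mean_in(b)) >= split_required * cross

    def purify(idx: np.ndarray) -> np.ndarray:
        """Drop members much less connected than the branch's own scale.

        First purges clearly bimodal branches (two connectivity tiers an
        order of magnitude apart) to their upper tier, then applies a mild
        relative floor.
        """
        cur = idx
        for _ in range(5):
            if len(cur) < 3:
                return cur
            sub = sim[np.ix_(cur, cur)]
            conn = sub.sum(axis=1) / (len(cur) - 1)
            logc = np.log10(np.clip(conn, 1e-15, None))
            split = _otsu_split(np.sort(logc))
            keep = None
            if split is not None:
                thr, gap = split
                if 10.0**gap >= _BIMODAL_FACTOR:
                    keep = logc > thr
            if keep is None or keep.all() or not keep.any():
                keep = conn >= _PURIFY_FRACTION * np.quantile(conn, 0.9)
            if keep.all():
                return cur
            cur = cur[keep]
        return cur

    def separation(idx: np.ndarray) -> float:
        """Within-branch similarity over similarity to the rest."""
        m = len(idx)
        if m < 2 or m == n:
            return 0.0
        sub = sim[np.ix_(idx, idx)]
        sim_in = sub.sum() / (m * (m - 1))
        sim_out = (row_sum[idx].sum() - sub.sum()) / (m * (n - m))
        if sim_out <= 0:
            return np.inf
        return sim_in / sim_out

    clusters: list[np.ndarray] = []
    root = n + n_merge - 1
    stack = [root]
    while stack:
        nid = stack.pop()
        mem = members[nid]
        if len(mem) < min_cluster_size:
            continue  # too small to be a module; PAM may rescue members
        if nid >= n:
            i = nid - n
            if (cut_height is not None and heights[i] > cut_height) or should_split(i):
                stack.extend(children[i])
                continue
        # cheap necessary condition before the full purify pass
        m = len(mem)
        raw_out = (row_sum[mem].sum() - in_sum[nid]) / max(m * (n - m), 1)
        raw_sep = mean_in(nid) / raw_out if raw_out > 0 else np.inf
        if raw_sep >= 0.2 * accept_required:
            core = purify(mem)
            if (
                len(core) >= min_cluster_size
                and len(core) >= _COVERAGE * len(mem)
                and separation(core) >= accept_required
            ):
                clusters.append(core)
                continue
        if nid >= n:
            stack.extend(children[nid - n])

    if not clusters and n >= min_cluster_size:
        # no separable substructure: the whole network is one module if it
        # shows genuine topological overlap throughout
        core = purify(np.arange(n))
        if len(core) >= max(min_cluster_size, _COVERAGE * n):
            sub = sim[np.ix_(core, core)]
            if sub.sum() / (len(core) * (len(core) - 1)) >= _MIN_GLOBAL_TOM:
                clusters.append(core)

    labels = np.zeros(n, dtype=int)
    for k, mem in enumerate(sorted(clusters, key=len, reverse=True), start=1):
        labels[mem] = k

    if pam and clusters and (labels == 0).any():
        labels = _pam_stage(sim, labels)

    ids, sizes = np.unique(labels[labels > 0], return_counts=True)
    order = ids[np.argsort(-sizes, kind="stable")]
    remap = {old: new for new, old in enumerate(order, start=1)}
    return np.array([remap.get(l, 0) for l in labels], dtype=int)


def _pam_stage(sim: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Assign unassigned features to the nearest module, conservatively.

    A feature joins the module with the highest mean similarity to its
    members, but only if that similarity reaches the module's own
    connectivity scale (the purification floor applied to the members'
    upper-tier connectivity) and clears the feature's mean background
    similarity by ``_PAM_SIM_RATIO`` — features no more similar to any
    module than to the background stay unassigned.
    """
    out = labels.copy()
    n = sim.shape[0]
    ids = np.unique(labels[labels > 0])
    sim_to = {}
    floor = {}
    for m in ids:
        mem = np.flatnonzero(labels == m)
        sim_to[m] = sim[:, mem].mean(axis=1)
        conn = sim[np.ix_(mem, mem)].sum(axis=1) / max(len(mem) - 1, 1)
        floor[m] = _PURIFY_FRACTION * float(np.quantile(conn, 0.9))
    bg = sim.sum(axis=1) / max(n - 1, 1)
    for i in np.flatnonzero(labels == 0):
        best, best_s = 0, -np.inf
        for m in ids:
            s = sim_to[m][i]
            if s > best_s:
                best, best_s = m, s
        if best and best_s >= floor[best] and best_s >= _PAM_SIM_RATIO * bg[i]:
            out[i] = best
    return out
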
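"""Numba kernels for per-genealogy bookkeeping.

All kernels operate on the raw edge/node arrays of a single-tree tree
sequence: ``child``/``parent`` are edge arrays sorted so that every edge
appears before any edge whose child is its parent (tskit's canonical
ordering for a single tree), and ``node_time`` is the node birth time in
generations.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def subtree_counts(child, parent, n_nodes, w0, w1, u):
    """Counts of two weighted leaf classes in the subtree rooted at node ``u``.

    ``w0``/``w1`` are int8 indicator vectors over sample nodes (length =
    number of samples; sample ids are 0..n_samples-1 in msprime output).
    """
    c0 = np.zeros(n_nodes, np.int32)
    c1 = np.zeros(n_nodes, np.int32)
    for s in range(w0.shape[0]):
        c0[s] = w0[s]
        c1[s] = w1[s]
    for i in range(child.shape[0]):
        c0[parent[i]] += c0[child[i]]
        c1[parent[i]] += c1[child[i]]
    return c0[u], c1[u]


@njit(cache=True)
def descendant_samples_mask(child, parent, n_nodes, n_samples, u):
    """Boolean mask over sample nodes lying below node ``u`` (inclusive)."""
    flag = np.zeros(n_nodes, np.uint8)
    flag[u] = 1
    # reversed edge order visits parents before their children
    for i in range(child.shape[0] - 1, -1, -1):
        if flag[parent[i]] == 1:
            flag[child[i]] = 1
    return flag[:n_samples] == 1


@njit(cache=True)
def lineage_counts_at_times(child, parent, node_time, n_nodes, n_samples,
                            is_focal, u, times):
    """Lineage counts of the focal sample set crossing each time in ``times``.

    For each grid time t the kernel returns (total, derived): the number of
    branches alive at t that subtend >=1 focal sample, and the subset of
    those lying inside the subtree of the mutated node ``u``.  A branch is
    alive at t when ``node_time[child] <= t < node_time[parent]``.
    """
    cnt = np.zeros(n_nodes, np.int32)
    for s in range(n_samples):
        cnt[s] = is_focal[s]
    below = np.zeros(n_nodes, np.uint8)
    below[u] = 1
    for i in range(child.shape[0] - 1, -1, -1):
        if below[parent[i]] == 1:
            below[child[i]] = 1
    nt = times.shape[0]
    total = np.zeros(nt, np.int32)
    derived = np.zeros(nt, np.int32)
    for i in range(child.shape[0]):
        c = child[i]
        p = parent[i]
        cnt[p] += cnt[c]
        if cnt[c] == 0:
            continue
        lo = node_time[c]
        hi = node_time[p]
        for k in range(nt):
            t = times[k]
            if lo <= t < hi:
                total[k] += 1
                if below[c] == 1:
                    derived[k] += 1
    return total, derived


def warm_up() -> None:
    """Trigger JIT compilation once with trivial inputs."""
    child = np.array([0, 1], dtype=np.int32)
    parent = np.array([2, 2], dtype=np.int32)
    t = np.array([0.0, 0.0, 1.0])
    w = np.array([1, 0], dtype=np.int8)
    subtree_counts(child, parent, 3, w, w, 2)
    descendant_samples_mask(child, parent, 3, 2, 2)
    lineage_counts_at_times(child, parent, t, 3, 2, w, 2, np.array([0.5]))
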
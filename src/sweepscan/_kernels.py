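"""Numba kernels for the EHH / iHH inner loops.

The statistics reduce to pairwise haplotype-identity extents: for two
haplotypes in an allele class, T is the number of consecutive markers,
walking outward from the core site, over which the pair is identical.
Every homozygosity quantity used by the scan is a function of these
extents:

* cluster EHH at marker i  =  #(member pairs with T >= i) / C(k, 2)
* cluster iHH              =  trapezoid sum of the EHH curve over genetic
                              distance, truncated at an EHH cutoff
* nSL class score          =  mean over pairs of (T_up + T_down + 1),
                              per-side extents capped

Pair extents are computed once per allele class per core site and reused
by every local cluster, which is what makes scoring a 1,000-haplotype
sample tractable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "pair_extents",
    "cluster_side_ihh",
    "class_mean_cluster_ihh",
    "class_mean_nsl",
]


@njit(cache=True)
def pair_extents(window: np.ndarray, max_t: int) -> np.ndarray:
    """Pairwise identity extents on one side of the core.

    ``window`` holds the class haplotypes over the side markers in outward
    order (column 0 = marker adjacent to the core).  Returns an (nc, nc)
    int32 matrix; entry (a, b) is the number of leading columns over which
    rows a and b agree, capped at min(window width, max_t).
    """
    nc, width = window.shape
    cap = width if width < max_t else max_t
    T = np.zeros((nc, nc), dtype=np.int32)
    for a in range(nc):
        for b in range(a + 1, nc):
            t = 0
            while t < cap and window[a, t] == window[b, t]:
                t += 1
            T[a, b] = t
            T[b, a] = t
    return T


@njit(cache=True)
def pair_extents_with_core(
    window: np.ndarray, core_allele: np.ndarray, max_t: int
) -> np.ndarray:
    """Pair extents over the stretch *including* the core site: -1 when the
    pair differs at the core, else the number of leading side markers over
    which it agrees.  Used when clusters may mix core alleles."""
    nc, width = window.shape
    cap = width if width < max_t else max_t
    T = np.empty((nc, nc), dtype=np.int32)
    for a in range(nc):
        T[a, a] = cap
        for b in range(a + 1, nc):
            if core_allele[a] != core_allele[b]:
                T[a, b] = -1
                T[b, a] = -1
                continue
            t = 0
            while t < cap and window[a, t] == window[b, t]:
                t += 1
            T[a, b] = t
            T[b, a] = t
    return T


@njit(cache=True)
def cluster_side_ihh(
    T: np.ndarray, members: np.ndarray, gaps: np.ndarray, cutoff: float
) -> float:
    """Integrate the within-cluster EHH curve along one side of the core.

    ``gaps[i-1]`` is the genetic distance between markers i-1 and i outward
    from the core (marker 0 = core, EHH = 1 there).  Trapezoidal quadrature;
    integration stops after the first trapezoid whose far edge drops below
    ``cutoff``, at the marker cap implied by len(gaps), or at the chromosome
    end, whichever comes first.
    """
    k = members.shape[0]
    n_pairs = k * (k - 1) // 2
    if n_pairs == 0:
        return 0.0
    n_markers = gaps.shape[0]
    # histogram of pair extents (bucket 0 = pairs differing at the core,
    # extent -1), clipped to the marker range of this side
    cnt = np.zeros(n_markers + 2, dtype=np.int64)
    for a in range(k):
        ia = members[a]
        for b in range(a + 1, k):
            t = T[ia, members[b]]
            if t > n_markers:
                t = n_markers
            cnt[t + 1] += 1
    # suffix sums: surv[i] = pairs identical through marker i (and at the
    # core); surv[0] < n_pairs when the cluster mixes core alleles
    surv = np.empty(n_markers + 1, dtype=np.int64)
    acc = 0
    for t in range(n_markers + 1, 0, -1):
        acc += cnt[t]
        surv[t - 1] = acc
    area = 0.0
    prev = surv[0] / n_pairs
    for i in range(1, n_markers + 1):
        ehh = surv[i] / n_pairs
        area += 0.5 * (prev + ehh) * gaps[i - 1]
        if cutoff > 0.0 and ehh < cutoff:
            break
        prev = ehh
    return area


@njit(cache=True)
def class_mean_cluster_ihh(
    T_up: np.ndarray,
    T_dn: np.ndarray,
    order: np.ndarray,
    n_neighbors: int,
    gaps_up: np.ndarray,
    gaps_dn: np.ndarray,
    cutoff: float,
) -> float:
    """Mean over focal haplotypes of the local-cluster iHH (the iHHL sum).

    ``order[j]`` lists the class members sorted by (Hamming distance to j,
    index); the focal plus its first ``n_neighbors`` entries (excluding the
    focal itself) form the local cluster.
    """
    nc = order.shape[0]
    members = np.empty(n_neighbors + 1, dtype=np.int64)
    total = 0.0
    for j in range(nc):
        members[0] = j
        c = 1
        for t in range(nc):
            if c > n_neighbors:
                break
            o = order[j, t]
            if o == j:
                continue
            members[c] = o
            c += 1
        m = members[:c]
        total += cluster_side_ihh(T_up, m, gaps_up, cutoff)
        total += cluster_side_ihh(T_dn, m, gaps_dn, cutoff)
    return total / nc


@njit(cache=True)
def all_focal_cluster_ihh(
    T_up: np.ndarray,
    T_dn: np.ndarray,
    order: np.ndarray,
    core_allele: np.ndarray,
    s_derived: int,
    s_ancestral: int,
    gaps_up: np.ndarray,
    gaps_dn: np.ndarray,
    cutoff: float,
) -> tuple[float, float]:
    """Sum of local-cluster iHH over every focal haplotype, split by the
    focal's core allele.  Neighbours come from the whole sample (clusters
    may mix core alleles; mixed pairs never count as identical, see
    ``pair_extents_with_core``); the cluster size is the focal's
    class-specific s."""
    n = order.shape[0]
    max_s = s_derived if s_derived > s_ancestral else s_ancestral
    if max_s > n - 1:
        max_s = n - 1
    members = np.empty(max_s + 1, dtype=np.int64)
    sum1 = 0.0
    sum0 = 0.0
    for j in range(n):
        s = s_derived if core_allele[j] == 1 else s_ancestral
        if s > n - 1:
            s = n - 1
        members[0] = j
        c = 1
        for t in range(n):
            if c > s:
                break
            o = order[j, t]
            if o == j:
                continue
            members[c] = o
            c += 1
        m = members[:c]
        v = cluster_side_ihh(T_up, m, gaps_up, cutoff)
        v += cluster_side_ihh(T_dn, m, gaps_dn, cutoff)
        if core_allele[j] == 1:
            sum1 += v
        else:
            sum0 += v
    return sum1, sum0


@njit(cache=True)
def class_mean_nsl(T_up: np.ndarray, T_dn: np.ndarray, cap: int) -> float:
    """Mean pairwise identity length in SNPs (core site included), capped
    at ``cap`` markers per side."""
    nc = T_up.shape[0]
    n_pairs = nc * (nc - 1) // 2
    total = 0.0
    for a in range(nc):
        for b in range(a + 1, nc):
            tu = T_up[a, b]
            if tu > cap:
                tu = cap
            td = T_dn[a, b]
            if td > cap:
                td = cap
            total += tu + td + 1
    return total / n_pairs
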
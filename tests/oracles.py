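"""Independent brute-force implementations used as test oracles.

Everything here is written for clarity, not speed, from the definitions:
explicit pairwise identity counting for EHH, explicit marker-by-marker
trapezoids for iHH, explicit pairwise shared-prefix walks for nSL.  These
functions never call the production kernels.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def naive_ehh(alleles: np.ndarray, members, core: int, marker: int) -> float:
    """Probability that two distinct members are identical over the
    core-to-marker stretch, by explicit pair enumeration."""
    members = list(members)
    lo, hi = min(core, marker), max(core, marker)
    same = 0
    for a, b in combinations(members, 2):
        if np.array_equal(alleles[a, lo : hi + 1], alleles[b, lo : hi + 1]):
            same += 1
    total = len(members) * (len(members) - 1) // 2
    return same / total


def naive_side_ihh(alleles, gen, members, core, n_markers, direction, cutoff):
    """One-sided trapezoid integral of the naive EHH curve.  The curve
    starts at the core's own homozygosity (< 1 when the cluster mixes core
    alleles)."""
    m = alleles.shape[1]
    area = 0.0
    prev = naive_ehh(alleles, members, core, core)
    prev_idx = core
    for i in range(1, n_markers + 1):
        marker = core - i if direction < 0 else core + i
        if marker < 0 or marker >= m:
            break
        ehh = naive_ehh(alleles, members, core, marker)
        area += 0.5 * (prev + ehh) * abs(gen[marker] - gen[prev_idx])
        if cutoff > 0 and ehh < cutoff:
            break
        prev, prev_idx = ehh, marker
    return area


def naive_ihh(alleles, gen, members, core, L=400, cutoff=0.0):
    if len(members) < 2:
        raise ValueError("cluster too small")
    return naive_side_ihh(alleles, gen, members, core, L, -1, cutoff) + naive_side_ihh(
        alleles, gen, members, core, L, +1, cutoff
    )


def naive_cluster_members(alleles, core, j, L=400, r=0.1, floor=8, pool="class"):
    """Focal j plus its s nearest neighbours by Hamming distance on the
    local window, ties broken by haplotype index; s is defined on the
    focal's class size, the neighbour pool by ``pool``."""
    n, m = alleles.shape
    c = alleles[j, core]
    klass = [h for h in range(n) if alleles[h, core] == c]
    cand = list(range(n)) if pool == "all" else klass
    lo, hi = max(0, core - L), min(m - 1, core + L)
    dist = {
        h: int(np.sum(alleles[h, lo : hi + 1] != alleles[j, lo : hi + 1]))
        for h in cand
        if h != j
    }
    s = int(min(max(math.ceil(r * len(klass)), floor), len(klass)))
    ranked = sorted(dist, key=lambda h: (dist[h], h))
    return [j] + ranked[: min(s, len(cand) - 1)]


def naive_site_scores(alleles, gen, core, L=400, r=0.1, floor=8, cutoff=0.0,
                      nsl_cap=500, pool="class"):
    """All unstandardized statistics at one core site, from first principles."""
    n, m = alleles.shape
    out = {}
    for c in (0, 1):
        klass = [h for h in range(n) if alleles[h, core] == c]
        ihh_c = naive_ihh(alleles, gen, klass, core, L, cutoff)
        vals = [
            naive_ihh(alleles, gen,
                      naive_cluster_members(alleles, core, j, L, r, floor, pool),
                      core, L, cutoff)
            for j in klass
        ]
        out[f"ihh{c}"] = ihh_c
        out[f"ihhl{c}"] = sum(vals) / len(vals)
        out[f"nsl{c}"] = naive_class_nsl(alleles, klass, core, nsl_cap)
    out["uihsl"] = math.log(out["ihhl1"] / out["ihhl0"])
    out["uihs"] = math.log(out["ihh1"] / out["ihh0"])
    out["urihs0"] = math.log(out["ihhl0"] / out["ihh0"])
    out["urihs1"] = math.log(out["ihhl1"] / out["ihh1"])
    out["unsl"] = math.log(out["nsl1"] / out["nsl0"])
    return out


def naive_shared_extent(alleles, a, b, core, direction, cap):
    """Consecutive markers outward from the core over which a and b agree."""
    m = alleles.shape[1]
    t = 0
    while t < cap:
        marker = core - (t + 1) if direction < 0 else core + (t + 1)
        if marker < 0 or marker >= m:
            break
        if alleles[a, marker] != alleles[b, marker]:
            break
        t += 1
    return t


def naive_class_nsl(alleles, klass, core, cap=500):
    """Mean pairwise identity length in SNPs around the core (inclusive)."""
    total, pairs = 0, 0
    for a, b in combinations(klass, 2):
        total += (
            naive_shared_extent(alleles, a, b, core, -1, cap)
            + naive_shared_extent(alleles, a, b, core, +1, cap)
            + 1
        )
        pairs += 1
    return total / pairs


def naive_knn_label(point, ref_points, ref_labels, k):
    """Exhaustive-distance kNN with the majority/nearest tie rule."""
    d = np.sqrt(((np.asarray(ref_points) - np.asarray(point)) ** 2).sum(axis=1))
    near = np.argsort(d, kind="stable")[:k]
    votes = {}
    for i in near:
        votes[ref_labels[i]] = votes.get(ref_labels[i], 0) + 1
    best = max(votes.values())
    winners = [lab for lab, v in votes.items() if v == best]
    if len(winners) == 1:
        return winners[0]
    return ref_labels[int(np.argmin(d))]
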
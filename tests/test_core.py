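"""Core statistic engine: cluster rules, EHH/iHH, log-ratios, standardization.

The heavy verification is oracle equivalence: the production kernels must
reproduce a naive pairwise-enumeration implementation exactly (1e-12) on
small fixtures, across both allele classes and every statistic.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan import core
from sweepscan.matrix import HaplotypeMatrix

import oracles
from conftest import random_matrix


# ---------------------------------------------------------------------- s rule


@pytest.mark.parametrize(
    "n_class,r,expected",
    [
        (100, 0.1, 10),
        (20, 0.1, 8),  # floor
        (5, 0.1, 5),  # capped at the class size
        (73, 0.1, 8),  # ceil(7.3) = 8 == floor
        (85, 0.1, 9),  # ceil(8.5)
        (100, 1.0, 100),  # r = 1: whole class
    ],
)
def test_cluster_size_rule(n_class, r, expected):
    assert core.cluster_size(n_class, r) == expected


def test_local_cluster_membership_and_determinism(small_hm):
    ctx = core.CoreSiteContext.from_matrix(small_hm, 30, 25)
    for j in (0, 5, 11):
        cl = core.local_cluster(small_hm, ctx, j, r=0.2, pool="class")
        assert j in cl.members
        assert cl.members[0] == j
        allele = small_hm.alleles[j, 30]
        assert np.all(small_hm.alleles[cl.members, 30] == allele)
        expected = oracles.naive_cluster_members(
            small_hm.alleles, 30, j, L=25, r=0.2, pool="class"
        )
        assert list(cl.members) == expected
        # unrestricted pool: same ordering rule over the whole sample
        cl_all = core.local_cluster(small_hm, ctx, j, r=0.2, pool="all")
        expected_all = oracles.naive_cluster_members(
            small_hm.alleles, 30, j, L=25, r=0.2, pool="all"
        )
        assert list(cl_all.members) == expected_all


def test_degenerate_class_unscorable():
    alleles = np.zeros((6, 9), dtype=np.uint8)
    alleles[0, 4] = 1  # singleton derived class at the core
    hm = HaplotypeMatrix(alleles | 0, np.arange(9.0) + 1, np.arange(9.0) * 0.01)
    ctx = core.CoreSiteContext.from_matrix(hm, 4, 4)
    with pytest.raises(core.UnscorableSiteError):
        core.ihhl_allele(hm, ctx, 1)
    rec = core.site_raw(hm, 4, core.ScanParams(min_freq=0.0))
    assert rec.reason == "class_too_small"


# ---------------------------------------------------------------------- EHH


def test_ehh_simple_partitions():
    # 4 members in two identical-within types of size 2 -> (1+1)/C(4,2) = 1/3
    alleles = np.array(
        [
            [1, 1, 0, 0],
            [1, 1, 0, 0],
            [1, 1, 1, 1],
            [1, 1, 1, 1],
        ],
        dtype=np.uint8,
    )
    hm = HaplotypeMatrix(alleles, np.arange(4.0) + 1, np.arange(4.0))
    ctx = core.CoreSiteContext.from_matrix(hm, 0, 3)
    cl = core.LocalCluster(0, np.arange(4), 3)
    assert core.ehh_cluster(hm, ctx, cl, 1) == pytest.approx(1.0)  # identical
    assert core.ehh_cluster(hm, ctx, cl, 2) == pytest.approx(1 / 3)
    # all members pairwise distinct
    alleles2 = np.array([[1, 0, 0], [1, 1, 0], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)
    hm2 = HaplotypeMatrix(alleles2, np.arange(3.0) + 1, np.arange(3.0))
    ctx2 = core.CoreSiteContext.from_matrix(hm2, 0, 2)
    assert core.ehh_cluster(hm2, ctx2, core.LocalCluster(0, np.arange(4), 3), 2) == 0.0


@given(seed=st.integers(0, 200), marker_steps=st.integers(1, 20))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_ehh_monotone_and_bounded(seed, marker_steps):
    """EHH never increases as the marker moves outward (partitions refine)."""
    hm = random_matrix(n=14, m=45, seed=seed)
    core_idx = 22
    ctx = core.CoreSiteContext.from_matrix(hm, core_idx, 22)
    cl = core.LocalCluster(0, np.arange(10), 9)
    prev = 1.0
    for i in range(1, marker_steps + 1):
        marker = core_idx + i
        if marker >= hm.n_sites:
            break
        e = core.ehh_cluster(hm, ctx, cl, marker)
        assert 0.0 <= e <= prev + 1e-15
        prev = e


# ---------------------------------------------------------------------- iHH


def test_ihh_rectangle_and_triangle():
    # EHH == 1 over both sides: area = total genetic span
    alleles = np.tile(np.array([[1], [1], [1], [0]], dtype=np.uint8), (1, 7))
    alleles[:, 3] = [1, 1, 1, 0]
    gen = np.arange(7.0) * 0.5
    hm = HaplotypeMatrix(alleles, np.arange(7.0) + 1, gen)
    ctx = core.CoreSiteContext.from_matrix(hm, 3, 3)
    cl = core.LocalCluster(0, np.array([0, 1, 2]), 2)
    assert core.ihh_cluster(hm, ctx, cl) == pytest.approx(3.0)  # 1.5 per side
    # single marker per side, EHH drops 1 -> 0: one half-trapezoid per side
    alleles2 = np.array([[0, 1, 0], [1, 1, 1]], dtype=np.uint8)
    hm2 = HaplotypeMatrix(alleles2, np.arange(3.0) + 1, np.array([0.0, 0.2, 0.4]))
    ctx2 = core.CoreSiteContext.from_matrix(hm2, 1, 1)
    cl2 = core.LocalCluster(0, np.array([0, 1]), 1)
    assert core.ihh_cluster(hm2, ctx2, cl2) == pytest.approx(0.5 * 0.2 * 2)
    # zero genetic distance everywhere -> zero area
    hm3 = HaplotypeMatrix(alleles2, np.arange(3.0) + 1, np.zeros(3))
    ctx3 = core.CoreSiteContext.from_matrix(hm3, 1, 1)
    assert core.ihh_cluster(hm3, ctx3, cl2) == 0.0


def test_ihhl_equals_ihh_at_r1(small_hm):
    """Under the class-restricted pool, r = 1 makes every cluster the whole
    allele class, so iHHL coincides with iHH (the iHS special case)."""
    ctx = core.CoreSiteContext.from_matrix(small_hm, 30, 25)
    params = core.ScanParams(r=1.0, max_extend=25, neighbor_pool="class")
    for c in (0, 1):
        ihhl, ihh = core.ihhl_allele(small_hm, ctx, c, params)
        assert ihhl == pytest.approx(ihh, abs=1e-14)


def test_two_subfamily_class_has_ihhl_above_ihh():
    """Two identical-within, distinct-between subfamilies: within-cluster
    homozygosity decays slower than whole-class homozygosity."""
    left = np.array([1, 0, 0, 1, 0])
    right = np.array([0, 1, 1, 0, 1])
    rows = [np.r_[left, 1, left] for _ in range(3)] + [np.r_[right, 1, right] for _ in range(3)]
    rows += [np.r_[left, 0, right], np.r_[right, 0, left]]  # ancestral class
    alleles = np.array(rows, dtype=np.uint8)
    m = alleles.shape[1]
    hm = HaplotypeMatrix(alleles, np.arange(m) + 1.0, np.arange(m) * 0.1)
    ctx = core.CoreSiteContext.from_matrix(hm, 5, 5)
    ihhl, ihh = core.ihhl_allele(hm, ctx, 1, core.ScanParams(r=0.34, min_neighbors=2, max_extend=5))
    assert ihhl > ihh
    # oracle cross-check by direct pair counting
    expected_ihh = oracles.naive_ihh(alleles, hm.gen_pos, list(range(6)), 5, L=5)
    assert ihh == pytest.approx(expected_ihh, abs=1e-12)


# ------------------------------------------------------------------ log-ratios


def test_uihsl_and_urihs_identities():
    assert core.uihsl(2.0, 2.0) == 0.0
    assert core.uihsl(2.0 * math.e, 2.0) == pytest.approx(1.0)
    assert core.uihsl(3.0, 5.0) == -core.uihsl(5.0, 3.0)
    assert core.urihs(4.0, 4.0) == 0.0
    with pytest.raises(core.UnscorableSiteError):
        core.uihsl(0.0, 1.0)


def test_core_allele_relabel_flips_uihsl_sign(small_hm):
    params = core.ScanParams(min_freq=0.0, max_extend=20, compute_nsl=False)
    x0 = 30
    rec = core.site_raw(small_hm, x0, params)
    flipped = small_hm.alleles.copy()
    flipped[:, x0] = 1 - flipped[:, x0]
    hm2 = HaplotypeMatrix(flipped, small_hm.phys_pos, small_hm.gen_pos)
    rec2 = core.site_raw(hm2, x0, params)
    assert rec.uihsl == pytest.approx(-rec2.uihsl, abs=1e-12)
    assert rec.urihs1 == pytest.approx(rec2.urihs0, abs=1e-12)


# ------------------------------------------------------- oracle equivalence


@pytest.mark.parametrize("seed", [2, 7, 19, 31])
@pytest.mark.parametrize("pool", ["all", "class"])
def test_production_matches_bruteforce_oracle(seed, pool):
    """EHH/iHH/iHSL/RiHS/iHS/nSL from the kernels equal naive
    pair-enumeration values to 1e-12 on small fixtures, for both
    neighbour-pool conventions."""
    hm = random_matrix(n=18, m=70, seed=seed)
    params = core.ScanParams(
        r=0.25, max_extend=12, min_neighbors=3, min_freq=0.0, nsl_max_extend=9,
        neighbor_pool=pool,
    )
    for x0 in (20, 35, 52):
        rec = core.site_raw(hm, x0, params)
        if rec.reason:
            continue
        exp = oracles.naive_site_scores(
            hm.alleles, hm.gen_pos, x0, L=12, r=0.25, floor=3, nsl_cap=9, pool=pool
        )
        assert rec.uihsl == pytest.approx(exp["uihsl"], abs=1e-12)
        assert rec.uihs == pytest.approx(exp["uihs"], abs=1e-12)
        assert rec.urihs0 == pytest.approx(exp["urihs0"], abs=1e-12)
        assert rec.urihs1 == pytest.approx(exp["urihs1"], abs=1e-12)
        assert rec.unsl == pytest.approx(exp["unsl"], abs=1e-12)
        assert rec.ihhl1 == pytest.approx(exp["ihhl1"], abs=1e-12)
        assert rec.ihh0 == pytest.approx(exp["ihh0"], abs=1e-12)


def test_urihs_essentially_nonnegative_under_class_pool(neutral_equilibrium_hm):
    """With neighbours restricted to the focal's allele class, within-cluster
    homozygosity dominates whole-class homozygosity, so uRiHS is
    non-negative up to rare, tiny boundary effects (neighbours are picked on
    the whole window, so cluster EHH can dip marginally below class EHH
    right next to the core).  Under the default whole-sample pool the sign
    is unconstrained — clusters mixing core alleles start below EHH = 1 —
    so there we only require finiteness."""
    hm = neutral_equilibrium_hm
    class_vals, all_vals = [], []
    for x0 in range(100, hm.n_sites - 100, 7):
        rec = core.site_raw(hm, x0, core.ScanParams(max_extend=150, neighbor_pool="class"))
        if not rec.reason:
            class_vals += [rec.urihs0, rec.urihs1]
        rec2 = core.site_raw(hm, x0, core.ScanParams(max_extend=150))
        if not rec2.reason:
            all_vals += [rec2.urihs0, rec2.urihs1]
    class_vals = np.array(class_vals)
    assert (class_vals >= -0.05).all()
    assert (class_vals >= 0).mean() > 0.95
    assert np.isfinite(np.array(all_vals)).all()


# --------------------------------------------------------------- normalization


def test_standardization_bins_have_zero_mean_unit_sd():
    rng = np.random.default_rng(5)
    n = 4000
    freq = rng.uniform(0.05, 0.95, n)
    vals = rng.normal(freq * 2, 1.0)  # frequency-confounded raw scores
    raw = pd.DataFrame({"freq": freq, "uihsl": vals})
    model = core.NormalizationModel()
    model.fit_column(raw["uihsl"].to_numpy(), freq, "uihsl", n_bins=20, min_count=20)
    z = model.transform(raw["uihsl"].to_numpy(), freq, "uihsl")
    edges = model.bins["uihsl"][0]
    for b in range(edges.size - 1):
        sel = (freq >= edges[b]) & (freq < edges[b + 1])
        assert abs(z[sel].mean()) < 1e-12
        assert z[sel].std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_two_value_bin_standardizes_to_plus_minus_one():
    model = core.NormalizationModel()
    model.fit_column(np.array([3.0, 7.0]), np.array([0.4, 0.45]), "x", n_bins=1, min_count=2)
    z = model.transform(np.array([3.0, 7.0]), np.array([0.4, 0.45]), "x")
    # sample SD (n-1): SD = sqrt(8), mean 5 -> z = ±0.7071...
    assert z == pytest.approx([-math.sqrt(0.5), math.sqrt(0.5)], abs=1e-12)


def test_constant_bin_rejected():
    model = core.NormalizationModel()
    with pytest.raises(ValueError):
        model.fit_column(np.full(30, 2.0), np.full(30, 0.5), "x", n_bins=1, min_count=2)


def test_underfilled_bins_merge():
    rng = np.random.default_rng(0)
    freq = np.r_[rng.uniform(0.05, 0.30, 200), rng.uniform(0.8, 0.82, 5)]
    vals = rng.normal(size=freq.size)
    model = core.NormalizationModel()
    model.fit_column(vals, freq, "x", n_bins=25, min_count=20)
    edges, mean, sd = model.bins["x"]
    counts, _ = np.histogram(freq, bins=edges)
    assert (counts >= 20).all()
    assert np.all(sd > 0)


# ------------------------------------------------------------------ score_sites


def test_score_sites_pipeline_and_pvalues(neutral_equilibrium_hm):
    params = core.ScanParams(max_extend=150, n_bins=12, min_bin_count=15)
    table = core.score_sites(neutral_equilibrium_hm, params)
    scored = table.dropna(subset=["ihsl"])
    assert len(scored) > 200
    # composite identity and p-value conventions
    np.testing.assert_allclose(
        scored["rihsl"], scored["ihsl"] ** 2 + scored["rihs"] ** 2, rtol=0, atol=1e-12
    )
    assert ((scored["p_ihsl"] > 0) & (scored["p_ihsl"] <= 1)).all()
    assert ((scored["p_rihsl"] > 0) & (scored["p_rihsl"] <= 1)).all()
    low_freq = table[table["freq"] < params.min_freq]
    assert (low_freq["reason"] == "freq_out_of_range").all()
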
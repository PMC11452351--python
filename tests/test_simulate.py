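"""Simulators: neutral coalescent, selection trajectories, rescaled forward
sweeps and founder-lineage bookkeeping."""

import numpy as np
import pytest
from scipy import stats

from sweepscan import core, simulate
from sweepscan.simulate import SweepParams


def test_neutral_diversity_matches_theta():
    """Mean pairwise diversity per bp ~= 4*Ne*mu = 0.001 at equilibrium
    (closed-form neutral expectation as the oracle)."""
    dem = simulate.equilibrium()
    pis = []
    for seed in range(40):
        hm = simulate.simulate_neutral(dem, 30, length=5e4, seed=seed)
        f = hm.derived_freq()
        n = hm.n_haplotypes
        pis.append((2 * f * (1 - f) * n / (n - 1)).sum() / 5e4)
    assert np.mean(pis) == pytest.approx(0.001, rel=0.15)


def test_neutral_zero_mutation_and_determinism():
    dem = simulate.equilibrium()
    hm0 = simulate.simulate_neutral(dem, 10, length=1e4, mu=0.0, seed=1)
    assert hm0.n_sites == 0
    a = simulate.simulate_neutral(dem, 10, length=1e4, seed=5)
    b = simulate.simulate_neutral(dem, 10, length=1e4, seed=5)
    np.testing.assert_array_equal(a.alleles, b.alleles)
    np.testing.assert_array_equal(a.phys_pos, b.phys_pos)
    with pytest.raises(ValueError):
        simulate.simulate_neutral(dem, 10, mu=-1.0)


def test_neutral_sfs_close_to_one_over_i():
    """Folded-free SFS at equilibrium follows E[count at i] ∝ 1/i
    (chi-square goodness of fit, loose)."""
    dem = simulate.equilibrium()
    n = 12
    counts = np.zeros(n - 1)
    for seed in range(200):
        hm = simulate.simulate_neutral(dem, n, length=1e4, seed=1000 + seed)
        if hm.n_sites:
            k = hm.alleles.sum(axis=0)
            counts += np.bincount(k, minlength=n)[1:n]
    expected = (1.0 / np.arange(1, n)) / (1.0 / np.arange(1, n)).sum() * counts.sum()
    chi2 = ((counts - expected) ** 2 / expected).sum()
    # sites within a replicate are linked, which inflates the chi-square
    # statistic well beyond its iid null; a loose factor-of-12 bound on
    # chi2/dof still catches any systematic SFS distortion
    assert chi2 / (n - 2) < 12.0
    assert np.abs(counts / counts.sum() - expected / expected.sum()).max() < 0.05


def test_demography_presets_size_histories():
    growth = simulate.exponential_growth()
    assert growth.size_at(0) == pytest.approx(20_000)
    assert growth.size_at(1_000) == pytest.approx(1_000)
    assert growth.size_at(500) == pytest.approx(np.sqrt(20_000 * 1_000), rel=0.01)
    mild = simulate.bottleneck(0.5)
    assert (mild.size_at(100), mild.size_at(320), mild.size_at(400)) == (10_000, 5_000, 10_000)
    severe = simulate.bottleneck(0.1)
    assert severe.size_at(330) == 1_000
    ooa = simulate.out_of_africa("CHB")
    assert ooa.size_at(0) > ooa.size_at(848) and ooa.size_at(900) == 2_100


def test_trajectory_neutral_drift_is_martingale():
    """With s = 0 the allele frequency is a martingale: the mean final
    frequency over replicates stays at f0 (drift over 50 generations at
    Ne = 10,000 makes absorption negligible)."""
    dem = simulate.equilibrium()
    rng = np.random.default_rng(0)
    p = SweepParams(mode="sgv", s=0.0, f0=0.5, onset=50, freq_window=(0.01, 0.99))
    finals = [simulate.simulate_trajectory(p, dem, rng).freqs[-1] for _ in range(300)]
    assert np.mean(finals) == pytest.approx(0.5, abs=0.01)
    assert np.std(finals) > 0.005  # drift is actually happening


def test_trajectory_strong_selection_sweeps_to_high_frequency():
    dem = simulate.equilibrium()
    rng = np.random.default_rng(1)
    p = SweepParams(mode="sgv", s=0.1, f0=0.5, onset=400, freq_window=(0.9, 1.0))
    traj = simulate.simulate_trajectory(p, dem, rng)
    assert traj.tries == 1  # 2Ns >> 1 from f0 = 0.5: fixation is near-certain
    assert traj.freqs[-1] >= 0.9
    assert np.mean(np.diff(traj.freqs[:50])) > 0  # rising in expectation


def test_trajectory_reproducible_and_budget_error():
    dem = simulate.equilibrium()
    p = SweepParams(mode="sgv", s=0.02, f0=0.1, onset_range=(100, 1500))
    t1 = simulate.simulate_trajectory(p, dem, np.random.default_rng(7))
    t2 = simulate.simulate_trajectory(p, dem, np.random.default_rng(7))
    np.testing.assert_array_equal(t1.freqs, t2.freqs)
    assert t1.onset == t2.onset
    impossible = SweepParams(mode="sgv", s=5.0, f0=0.5, onset=2000, freq_window=(0.45, 0.5))
    with pytest.raises(simulate.TrajectoryBudgetError):
        simulate.simulate_trajectory(impossible, dem, np.random.default_rng(1), max_tries=500)


# ------------------------------------------------------------------- sweeps


FAST = dict(length=1e5, Q=10)


def test_hard_sweep_single_founder_and_window():
    dem = simulate.equilibrium()
    p = SweepParams(mode="hard", s=0.05, onset_range=(100, 1200))
    for seed in (1, 2, 3):
        res = simulate.simulate_sweep(p, dem, n_hap=100, seed=seed, **FAST)
        assert res.founder_count == 1
        assert 0.25 <= res.sample_freq <= 0.85
        assert res.hm.alleles[:, res.selected_site].mean() == res.sample_freq


def test_srm_sweep_multiple_founders():
    dem = simulate.equilibrium()
    p = SweepParams(mode="srm", s=0.02, theta_b=50, onset_range=(100, 2000))
    for seed in (1, 2):
        res = simulate.simulate_sweep(p, dem, n_hap=100, seed=seed, **FAST)
        assert res.founder_count >= 2
        assert 0.25 <= res.sample_freq <= 0.85


def test_sweep_reproducible_with_seed():
    dem = simulate.equilibrium()
    p = SweepParams(mode="sgv", s=0.05, f0=0.2, onset_range=(100, 800))
    a = simulate.simulate_sweep(p, dem, n_hap=60, seed=11, **FAST)
    b = simulate.simulate_sweep(p, dem, n_hap=60, seed=11, **FAST)
    np.testing.assert_array_equal(a.hm.alleles, b.hm.alleles)
    assert a.selected_site == b.selected_site
    assert a.founder_count == b.founder_count


def test_founder_lineages_increase_with_theta_and_f0():
    """Stochastically monotone founder counts: more recurrent mutation or
    more standing copies at onset -> more founder lineages in the sample."""
    dem = simulate.equilibrium()
    small = dict(length=2e4, Q=10)

    def mean_founders(p, n=25, base=0):
        out = []
        for seed in range(n):
            try:
                res = simulate.simulate_sweep(p, dem, n_hap=60, seed=base + seed,
                                              max_tries=8, **small)
                out.append(res.founder_count)
            except (simulate.TrajectoryBudgetError, simulate.SweepFilterError):
                continue
        return np.mean(out)

    theta_lo = mean_founders(SweepParams(mode="srm", s=0.02, theta_b=5,
                                         onset_range=(100, 1000)))
    theta_hi = mean_founders(SweepParams(mode="srm", s=0.02, theta_b=50,
                                         onset_range=(100, 1000)), base=100)
    assert theta_hi > theta_lo
    f0_lo = mean_founders(SweepParams(mode="sgv", s=0.02, f0=0.05,
                                      onset_range=(100, 1000)), base=200)
    f0_hi = mean_founders(SweepParams(mode="sgv", s=0.02, f0=0.2,
                                      onset_range=(100, 1000)), base=300)
    assert f0_hi > f0_lo


def test_rescaling_insensitivity_q10_vs_q5():
    """Mean raw iHSL at the sweep site is statistically indistinguishable
    between Q = 10 and Q = 5 rescaling (two-sample Welch test, alpha=0.01)."""
    dem = simulate.equilibrium()
    p = SweepParams(mode="sgv", s=0.05, f0=0.1, onset_range=(100, 600))
    scores = {}
    for Q in (10, 5):
        vals = []
        for seed in range(18):
            res = simulate.simulate_sweep(p, dem, n_hap=200, seed=1000 * Q + seed,
                                          length=1.5e5, Q=Q, max_tries=10)
            rec = core.site_raw(res.hm, res.selected_site,
                                core.ScanParams(compute_nsl=False, compute_ihs=False))
            if rec.uihsl is not None:
                vals.append(rec.uihsl)
        scores[Q] = np.array(vals)
    t, pval = stats.ttest_ind(scores[10], scores[5], equal_var=False)
    assert pval > 0.01


def test_build_reference_smoke():
    ref, model = simulate.build_reference("YRI", n_per_class=8, seed=2,
                                          length=1.2e5, Q=20)
    assert len(ref) == 24
    counts = ref.class_counts()
    assert counts == {"hard": 8, "neutral": 8, "soft": 8}
    assert np.isfinite(ref.points).all()
    assert "uihsl" in model.bins
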
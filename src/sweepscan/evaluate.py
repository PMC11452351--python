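"""Power, false-positive-rate, localization and classification accuracy.

Power conventions follow the simulation-study design the statistics were
built for: standardized scores are compared against analytic 1% thresholds
(one-tailed normal 2.3263 for iHSL/iHS/nSL on the derived allele; upper
chi-square(2) 9.2103 for RiHSL, additionally requiring iHSL > 0), while
H12 uses the empirical 99th percentile of matched neutral simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import IHSL_1PCT, RIHSL_1PCT

__all__ = [
    "PowerResult",
    "ConfusionMatrix",
    "power_at_1pct",
    "rihsl_power_at_1pct",
    "fpr",
    "empirical_threshold",
    "best_h12_window",
    "peak_and_rank",
    "classification_accuracy",
    "neutral_score_pool",
    "neutral_fpr_study",
    "sweep_power_study",
    "FREQ_BINS",
]

#: present-day adaptive-allele frequency bins used to condition power
FREQ_BINS = tuple((0.25 + 0.1 * i, 0.35 + 0.1 * i) for i in range(6))


@dataclass
class PowerResult:
    method: str
    condition: dict
    power: float
    n_replicates: int
    threshold: float


def power_at_1pct(
    scores: np.ndarray,
    threshold: float = IHSL_1PCT,
    method: str = "ihsl",
    condition: dict | None = None,
) -> PowerResult:
    """Proportion of replicate focal scores exceeding the threshold
    (one-tailed: the adaptive allele is the derived allele)."""
    scores = np.asarray(scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    if scores.size == 0:
        raise ValueError("no finite scores supplied")
    return PowerResult(
        method=method,
        condition=condition or {},
        power=float((scores > threshold).mean()),
        n_replicates=int(scores.size),
        threshold=float(threshold),
    )


def rihsl_power_at_1pct(
    rihsl: np.ndarray, ihsl: np.ndarray, condition: dict | None = None
) -> PowerResult:
    """RiHSL power: scores above the 1% chi-square(2) point with a positive
    standardized iHSL."""
    rihsl, ihsl = np.asarray(rihsl, float), np.asarray(ihsl, float)
    ok = np.isfinite(rihsl) & np.isfinite(ihsl)
    if not ok.any():
        raise ValueError("no finite scores supplied")
    hit = (rihsl[ok] > RIHSL_1PCT) & (ihsl[ok] > 0)
    return PowerResult("rihsl", condition or {}, float(hit.mean()), int(ok.sum()), RIHSL_1PCT)


def fpr(neutral_scores: np.ndarray, threshold: float = IHSL_1PCT) -> float:
    """False-positive rate: rejection proportion among neutral replicates."""
    return power_at_1pct(neutral_scores, threshold, method="fpr").power


def empirical_threshold(neutral_scores: np.ndarray, quantile: float = 0.99) -> float:
    """Empirical null threshold (e.g. the neutral 99th percentile for H12)."""
    scores = np.asarray(neutral_scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    if scores.size == 0:
        raise ValueError("no finite scores supplied")
    return float(np.quantile(scores, quantile))


def best_h12_window(
    sweep_by_size: dict[int, np.ndarray], neutral_by_size: dict[int, np.ndarray]
) -> tuple[int, dict[int, PowerResult]]:
    """Window size maximizing H12 power at the empirical 1% FPR threshold
    from matched neutral simulations (ties -> smaller window)."""
    results: dict[int, PowerResult] = {}
    for size in sorted(sweep_by_size):
        thr = empirical_threshold(neutral_by_size[size])
        results[size] = power_at_1pct(
            sweep_by_size[size], thr, method="h12", condition={"window": size}
        )
    best = max(sorted(results), key=lambda s: results[s].power)
    return best, results


def peak_and_rank(
    scores: pd.DataFrame,
    true_site: int,
    significance: str = "abs_ihsl",
) -> tuple[float, int]:
    """Localization metrics for a scan around a known adaptive site.

    peak distance: |bp(most significant site) - bp(true site)|, the nearest
    site winning ties; rank: 1-based position of the true site when sites
    are ordered by decreasing significance (unscored sites excluded; if the
    true site itself is unscored, rank is over scored sites only and
    reported relative to its significance of 0).
    """
    if significance == "abs_ihsl":
        sig = np.abs(scores["ihsl"].to_numpy(dtype=float))
    else:
        sig = -np.log10(scores[significance].to_numpy(dtype=float))
    pos = scores["pos_bp"].to_numpy(dtype=float)
    sites = scores["site"].to_numpy()
    finite = np.isfinite(sig)
    true_pos = float(pos[sites == true_site][0])
    smax = np.nanmax(sig[finite])
    peaks = np.flatnonzero(finite & (sig == smax))
    peak = peaks[np.argmin(np.abs(pos[peaks] - true_pos))]
    peak_distance = float(abs(pos[peak] - true_pos))
    where_true = np.flatnonzero(sites == true_site)[0]
    true_sig = sig[where_true] if finite[where_true] else 0.0
    rank = int((sig[finite] > true_sig).sum()) + 1
    return peak_distance, rank


@dataclass
class ConfusionMatrix:
    """3x3 counts over {neutral, hard, soft}, true class x called class."""

    labels: tuple[str, ...] = ("neutral", "hard", "soft")
    counts: np.ndarray = field(default_factory=lambda: np.zeros((3, 3), dtype=int))

    def accuracy(self) -> float:
        """Mean of the per-class diagonal proportions (classes with no
        calls are excluded from the mean)."""
        totals = self.counts.sum(axis=1)
        used = totals > 0
        if not used.any():
            raise ValueError("empty confusion matrix")
        diag = np.diag(self.counts)[used] / totals[used]
        return float(diag.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f"true_{l}" for l in self.labels],
            columns=[f"called_{l}" for l in self.labels],
        )


def _spread_scorable_sites(hm, params, k: int, margin: int) -> np.ndarray:
    """k well-separated scorable site indices away from the segment edges."""
    f = hm.derived_freq()
    ok = np.zeros(hm.n_sites, dtype=bool)
    ok[margin : hm.n_sites - margin] = True
    ok &= (f >= params.min_freq) & (f <= 1 - params.min_freq)
    cand = np.flatnonzero(ok)
    if cand.size == 0:
        return cand
    targets = np.linspace(0, cand.size - 1, num=min(k, cand.size)).round().astype(int)
    return np.unique(cand[targets])


def neutral_score_pool(
    dem,
    n_hap: int,
    length: float,
    n_reps: int,
    sites_per_rep: int,
    seed: int,
    params=None,
    mu: float | None = None,
    rec: float | None = None,
    h12_window: int | None = None,
    progress: bool = False,
):
    """Raw focal-site scores from independent neutral segments.

    Returns a DataFrame of unstandardized scores (one row per scored site,
    ``sites_per_rep`` spread sites per replicate) plus, optionally, the H12
    value at each segment's central site.
    """
    from . import comparators, core, simulate

    params = params or core.ScanParams()
    mu = simulate.MU if mu is None else mu
    rec = simulate.REC if rec is None else rec
    rng = np.random.default_rng(seed)
    rows, h12_vals = [], []
    margin = params.max_extend
    if h12_window is not None:
        margin = max(margin, h12_window // 2)
    for _ in range(n_reps):
        hm = simulate.simulate_neutral(
            dem, n_hap, length=length, mu=mu, rec=rec,
            seed=int(rng.integers(1, 2**31 - 1)),
        )
        sites = _spread_scorable_sites(hm, params, sites_per_rep, margin)
        if sites.size == 0:
            continue
        rows.append(core.raw_score_table(hm, params, sites))
        if h12_window is not None:
            h12_vals += [
                comparators.h_stats(hm, int(s), h12_window)[0] for s in sites
            ]
    pool = pd.concat(rows, ignore_index=True)
    if h12_window is not None:
        return pool, np.array(h12_vals)
    return pool


def neutral_fpr_study(
    rec_multipliers=(0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    mut_multipliers=(1.2, 1.4, 1.6, 1.8, 2.0, 2.2, 2.4, 2.6, 2.8, 3.0),
    n_hap: int = 1000,
    length: float = 2e6,
    reps_per_condition: int = 10,
    sites_per_rep: int = 4,
    baseline_reps: int = 30,
    seed: int = 1,
    params=None,
) -> dict:
    """iHSL false-positive rate under perturbed recombination / mutation
    rates.

    Frequency-bin standardization is fitted once from baseline-rate neutral
    segments (the genome-wide normalization of a scan) and applied to every
    perturbed condition; the FPR per condition is the proportion of
    standardized scores exceeding the one-tailed 1% normal threshold.
    """
    from . import core, simulate

    params = params or core.ScanParams(compute_ihs=False, compute_nsl=False)
    dem = simulate.equilibrium()
    base = neutral_score_pool(
        dem, n_hap, length, baseline_reps, sites_per_rep, seed, params
    )
    model = core.NormalizationModel()
    model.fit_column(
        base["uihsl"].to_numpy(), base["freq"].to_numpy(), "uihsl",
        params.n_bins, params.min_bin_count,
    )
    conditions = [(m, 1.0) for m in rec_multipliers] + [(1.0, m) for m in mut_multipliers]
    out = {"conditions": [], "fpr": [], "n_scores": []}
    for i, (rmult, mmult) in enumerate(conditions):
        pool = neutral_score_pool(
            dem, n_hap, length, reps_per_condition, sites_per_rep,
            seed + 1000 + i, params,
            mu=simulate.MU * mmult, rec=simulate.REC * rmult,
        )
        z = model.transform(pool["uihsl"].to_numpy(), pool["freq"].to_numpy(), "uihsl")
        z = z[np.isfinite(z)]
        out["conditions"].append({"rec_mult": rmult, "mut_mult": mmult})
        out["fpr"].append(float((z > IHSL_1PCT).mean()))
        out["n_scores"].append(int(z.size))
    out["mean_fpr"] = float(np.mean(out["fpr"]))
    out["total_scores"] = int(np.sum(out["n_scores"]))
    return out


def sweep_power_study(
    mode: str,
    s_values=(0.01, 0.02, 0.05),
    f0: float | None = None,
    theta_b: float = 0.0,
    reps_per_s: int = 34,
    n_hap: int = 1000,
    length: float = 5e5,
    neutral_reps: int = 50,
    sites_per_neutral: int = 5,
    h12_window: int = 1001,
    onset_range=(100, 2000),
    Q: int = 10,
    seed: int = 1,
    params=None,
    neutral: tuple | None = None,
) -> dict:
    """Detection power of iHSL, iHS, nSL and H12 on one softness grid.

    Replicates are simulated with onsets drawn from ``onset_range``
    conditioned on a present-day adaptive frequency in (0.25, 0.85), then
    grouped into the six standard frequency bins; power per (s, bin) cell
    is the rejection proportion at each statistic's 1% threshold (analytic
    for the log-ratio statistics on standardized scores, the neutral 99th
    percentile for H12).  ``mean_power`` averages over the full s x bin
    grid (cells left empty after conditioning are skipped).
    """
    from . import comparators, core, simulate

    params = params or core.ScanParams()
    dem = simulate.equilibrium()
    if neutral is None:
        neutral = neutral_score_pool(
            dem, n_hap, length, neutral_reps, sites_per_neutral, seed, params,
            h12_window=h12_window,
        )
    neutral, h12_null = neutral
    model = core.fit_normalization(neutral, params)
    h12_thr = empirical_threshold(h12_null)
    rng = np.random.default_rng(seed + 99)
    records = []
    for s in s_values:
        p = simulate.SweepParams(
            mode=mode, s=s, f0=f0, theta_b=theta_b,
            onset_range=tuple(onset_range), freq_window=(0.25, 0.85),
        )
        got = 0
        while got < reps_per_s:
            try:
                res = simulate.simulate_sweep(
                    p, dem, n_hap, seed=int(rng.integers(1, 2**31 - 1)),
                    length=length, Q=Q, max_tries=6,
                )
            except (simulate.TrajectoryBudgetError, simulate.SweepFilterError):
                continue
            rec = core.site_raw(res.hm, res.selected_site, params)
            if rec.reason:
                continue
            freq = rec.freq
            z = model.transform(np.array([rec.uihsl]), np.array([freq]), "uihsl")[0]
            z_ihs = model.transform(np.array([rec.uihs]), np.array([freq]), "uihs")[0]
            z_nsl = model.transform(np.array([rec.unsl]), np.array([freq]), "unsl")[0]
            ur = rec.urihs1 if z >= 0 else rec.urihs0
            rs = model.transform(
                np.array([ur]), np.array([freq]), "urihs1" if z >= 0 else "urihs0"
            )[0]
            h12 = comparators.h_stats(res.hm, res.selected_site, h12_window)[0]
            records.append({"s": s, "freq": freq, "ihsl": z, "ihs": z_ihs,
                            "nsl": z_nsl, "rihsl": z**2 + rs**2, "h12": h12})
            got += 1
    df = pd.DataFrame(records)
    powers: dict[str, list[float]] = {
        m: [] for m in ("ihsl", "ihs", "nsl", "h12", "rihsl")
    }
    cells = []
    for s in s_values:
        for lo, hi in FREQ_BINS:
            cell = df[(df["s"] == s) & (df["freq"] >= lo) & (df["freq"] < hi)]
            if len(cell) == 0:
                continue
            cells.append({"s": s, "bin": (lo, hi), "n": len(cell)})
            for m in ("ihsl", "ihs", "nsl"):
                powers[m].append(float((cell[m] > IHSL_1PCT).mean()))
            powers["h12"].append(float((cell["h12"] > h12_thr).mean()))
            powers["rihsl"].append(
                float(((cell["rihsl"] > RIHSL_1PCT) & (cell["ihsl"] > 0)).mean())
            )
    return {
        "mode": mode,
        "mean_power": {m: float(np.mean(v)) for m, v in powers.items()},
        "cell_power": powers,
        "cells": cells,
        "n_replicates": len(df),
        "h12_threshold": float(h12_thr),
        "scores": df,
    }


def classification_accuracy(
    true_labels: np.ndarray,
    called_labels: np.ndarray,
    p_values: np.ndarray | None = None,
    p_cut: float = 0.01,
) -> ConfusionMatrix:
    """Confusion matrix over significant calls (p < p_cut when p-values are
    given)."""
    true_labels = np.asarray(true_labels, dtype=object)
    called_labels = np.asarray(called_labels, dtype=object)
    keep = np.ones(true_labels.size, dtype=bool)
    if p_values is not None:
        keep = np.asarray(p_values, dtype=float) < p_cut
    if not keep.any():
        raise ValueError(f"no calls significant at p < {p_cut}")
    cm = ConfusionMatrix()
    index = {lab: i for i, lab in enumerate(cm.labels)}
    for t, c in zip(true_labels[keep], called_labels[keep]):
        cm.counts[index[str(t)], index[str(c)]] += 1
    return cm
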
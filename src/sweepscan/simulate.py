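"""Simulation of neutral and sweep haplotype data.

Neutral data come from the coalescent (msprime).  Sweep data are generated
in three steps, mirroring trajectory-conditioned sweep simulators:

1. a beneficial-allele frequency trajectory is simulated forward in time at
   the full population size under Wright-Fisher sampling with additive
   (genic) selection, rejection-sampled until the present-day frequency
   lands in the requested window;
2. the trajectory is mapped onto a population rescaled by a factor Q
   (sizes / Q, per-generation rates * Q, duration / Q);
3. an explicit forward Wright-Fisher haplotype population, initialized from
   a coalescent sample at onset time, is driven by the rescaled trajectory
   (see :mod:`sweepscan._forward`), and n haplotypes are sampled at present.

Sweep modes: ``hard`` (single origin at onset), ``sgv`` (standing genetic
variation: an existing neutral allele at frequency ~f0 turns beneficial at
onset) and ``srm`` (recurrent beneficial mutation at scaled rate
theta_b = 4*Ne*mu_b).  Founder lineages — distinct chromosome backgrounds
carrying the beneficial allele at onset (or at origin, for srm) with
descendants in the sample — are tracked explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable

import msprime
import numpy as np

from numba import njit

from ._forward import forward_sweep
from .matrix import HaplotypeMatrix

__all__ = [
    "Demography",
    "SweepParams",
    "SweepSimResult",
    "equilibrium",
    "exponential_growth",
    "bottleneck",
    "out_of_africa",
    "simulate_neutral",
    "simulate_trajectory",
    "simulate_sweep",
    "build_reference",
]

MU = 2.5e-8  #: default per-bp per-generation mutation rate
REC = 1.25e-8  #: default per-bp per-generation recombination rate
NE_REF = 10_000  #: reference diploid effective size for scaled parameters


@dataclass
class Demography:
    """A named demographic model: an msprime demography for coalescent
    initialization plus the focal population's diploid size through time
    (needed by the trajectory and forward engines).  ``pop_at`` maps a
    sampling time to the deme the focal lineage belongs to then (ancestral
    demes after merge events)."""

    name: str
    msp: msprime.Demography
    focal: str
    size_at: Callable[[float], float]  # t generations ago -> diploid Ne
    pop_at: Callable[[float], str] | None = None

    def sample_population(self, t: float) -> str:
        return self.focal if self.pop_at is None else self.pop_at(t)


def equilibrium(ne: int = NE_REF) -> Demography:
    d = msprime.Demography()
    d.add_population(name="pop0", initial_size=ne)
    return Demography("equilibrium", d, "pop0", lambda t: float(ne))


def exponential_growth(
    n_start: int = 1_000, n_end: int = 20_000, duration: int = 1_000
) -> Demography:
    """Growth from ``n_start`` to ``n_end`` over ``duration`` generations
    (0.3%/generation at the defaults), constant before."""
    rate = np.log(n_end / n_start) / duration
    d = msprime.Demography()
    d.add_population(name="pop0", initial_size=n_end, growth_rate=rate)
    d.add_population_parameters_change(
        time=duration, initial_size=n_start, growth_rate=0.0, population="pop0"
    )

    def size_at(t: float) -> float:
        return float(n_end * np.exp(-rate * t)) if t < duration else float(n_start)

    return Demography("growth", d, "pop0", size_at)


def bottleneck(
    strength: float = 0.5,
    start: int = 300,
    duration: int = 50,
    ne: int = NE_REF,
    name: str | None = None,
) -> Demography:
    """Ne reduced to ``strength * ne`` between ``start`` and
    ``start + duration`` generations ago.  strength=0.5 is the mild preset,
    0.1 the severe one; a 400-generation variant is available by passing
    ``duration=400``."""
    d = msprime.Demography()
    d.add_population(name="pop0", initial_size=ne)
    d.add_population_parameters_change(time=start, initial_size=strength * ne, population="pop0")
    d.add_population_parameters_change(time=start + duration, initial_size=ne, population="pop0")

    def size_at(t: float) -> float:
        return float(strength * ne) if start <= t < start + duration else float(ne)

    label = name or ("mild_bottleneck" if strength >= 0.5 else "severe_bottleneck")
    return Demography(label, d, "pop0", size_at)


def _ooa_params() -> dict:
    with resources.files("sweepscan.data").joinpath("ooa_model.json").open() as fh:
        return json.load(fh)


def out_of_africa(focal: str = "YRI") -> Demography:
    """Three-population out-of-Africa model; ``focal`` is the sampled
    population (YRI, CEU or CHB).  Parameters live in data/ooa_model.json."""
    p = _ooa_params()
    if focal not in ("YRI", "CEU", "CHB"):
        raise ValueError("focal population must be one of YRI, CEU, CHB")
    T_EU_AS, T_B, T_AF = p["T_EU_AS_gen"], p["T_B_gen"], p["T_AF_gen"]
    n_eu = p["N_EU0"] * np.exp(p["r_EU"] * T_EU_AS)
    n_as = p["N_AS0"] * np.exp(p["r_AS"] * T_EU_AS)
    d = msprime.Demography()
    d.add_population(name="YRI", initial_size=p["N_AF"])
    d.add_population(name="CEU", initial_size=n_eu, growth_rate=p["r_EU"])
    d.add_population(name="CHB", initial_size=n_as, growth_rate=p["r_AS"])
    d.add_population(name="B", initial_size=p["N_B"])
    d.add_population(name="ANC", initial_size=p["N_A"])
    d.set_symmetric_migration_rate(["YRI", "CEU"], p["m_AF_EU"])
    d.set_symmetric_migration_rate(["YRI", "CHB"], p["m_AF_AS"])
    d.set_symmetric_migration_rate(["CEU", "CHB"], p["m_EU_AS"])
    d.add_population_split(time=T_EU_AS, derived=["CEU", "CHB"], ancestral="B")
    d.add_symmetric_migration_rate_change(time=T_EU_AS, populations=["YRI", "B"], rate=p["m_AF_B"])
    d.add_population_split(time=T_B, derived=["YRI", "B"], ancestral="ANC")
    d.add_population_parameters_change(time=T_AF, initial_size=p["N_A"], population="ANC")
    d.sort_events()

    def size_at(t: float) -> float:
        if focal == "YRI":
            return float(p["N_AF"]) if t < T_AF else float(p["N_A"])
        n0, r = (n_eu, p["r_EU"]) if focal == "CEU" else (n_as, p["r_AS"])
        if t < T_EU_AS:
            return float(n0 * np.exp(-r * t))
        if t < T_B:
            return float(p["N_B"])
        return float(p["N_AF"]) if t < T_AF else float(p["N_A"])

    def pop_at(t: float) -> str:
        if focal != "YRI" and t >= T_EU_AS:
            return "B" if t < T_B else "ANC"
        if focal == "YRI" and t >= T_B:
            return "ANC"
        return focal

    return Demography(f"ooa_{focal}", d, focal, size_at, pop_at)


OOA_SAMPLE_HAPLOTYPES = {"YRI": 216, "CEU": 198, "CHB": 206}


# ---------------------------------------------------------------------------


def _matrix_from_ts(ts, rec: float) -> HaplotypeMatrix:
    G = ts.genotype_matrix().T.astype(np.uint8)
    pos = ts.sites_position.copy()
    keep = np.flatnonzero((G.sum(axis=0) > 0) & (G.sum(axis=0) < G.shape[0]))
    return HaplotypeMatrix(G[:, keep], pos[keep], pos[keep] * rec * 100.0)


def simulate_neutral(
    dem: Demography,
    n_hap: int,
    length: float = 2e6,
    mu: float = MU,
    rec: float = REC,
    seed: int | None = None,
    sample_time: float = 0.0,
) -> HaplotypeMatrix:
    """Neutral coalescent sample; ancestral allele is 0 by construction and
    genetic positions follow the constant recombination rate (cM)."""
    if mu < 0 or rec < 0:
        raise ValueError("rates must be non-negative")
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31 - 1) + 1
    ts = msprime.sim_ancestry(
        samples=[
            msprime.SampleSet(
                n_hap, population=dem.sample_population(sample_time), ploidy=1,
                time=sample_time,
            )
        ],
        demography=dem.msp,
        sequence_length=length,
        recombination_rate=rec,
        discrete_genome=False,
        random_seed=int(seeds[0]),
    )
    ts = msprime.sim_mutations(
        ts,
        rate=mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=int(seeds[1]),
    )
    return _matrix_from_ts(ts, rec)


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepParams:
    """Selection scenario for a single simulated segment.

    mode : 'hard' | 'sgv' | 'srm'
    s : per-copy selection coefficient (fitness 1, 1+s/2, 1+s).
    f0 : standing frequency at onset (sgv mode).
    theta_b : scaled beneficial mutation rate 4*Ne_ref*mu_b (srm mode).
    onset : selection onset, generations ago; when ``onset_range`` is set,
        each trajectory attempt draws the onset uniformly from it, which is
        how a grid over onset times conditioned on the present-day
        frequency is realized.
    freq_window : acceptance window for the present-day beneficial
        frequency (population level; the sampled frequency is checked by
        the caller's filters).
    """

    mode: str = "hard"
    s: float = 0.02
    f0: float | None = None
    theta_b: float = 0.0
    onset: int = 1_000
    onset_range: tuple[int, int] | None = None
    freq_window: tuple[float, float] = (0.25, 0.85)


@dataclass
class Trajectory:
    freqs: np.ndarray  # length onset+1, index 0 = onset, last = present
    origins: np.ndarray  # new beneficial origins per generation
    onset: int
    tries: int


class TrajectoryBudgetError(RuntimeError):
    pass


_MODE_CODE = {"hard": 0, "sgv": 1, "srm": 2}


@njit(cache=True)
def _trajectory_attempts(
    sizes_rev: np.ndarray,
    t_min: int,
    t_max: int,
    mode: int,
    s: float,
    f0: float,
    mu_b: float,
    lo: float,
    hi: float,
    max_tries: int,
    seed: int,
):
    """Run rejection-sampled Wright-Fisher trajectories with additive
    selection.  ``sizes_rev[t]`` is the haploid population size (2N) at t
    generations before present.  Returns (tries, onset, freqs, origins);
    tries == 0 signals budget exhaustion."""
    np.random.seed(seed)
    empty = np.zeros(1, dtype=np.float64)
    empty_o = np.zeros(1, dtype=np.int64)
    for attempt in range(1, max_tries + 1):
        T = t_min if t_max <= t_min else t_min + np.random.randint(0, t_max - t_min + 1)
        freqs = np.zeros(T + 1, dtype=np.float64)
        origins = np.zeros(T + 1, dtype=np.int64)
        n2 = sizes_rev[T]
        if mode == 1:
            x = int(round(f0 * n2))
            if x < 1:
                x = 1
        elif mode == 0:
            x = 1
            origins[0] = 1
        else:
            x = 0
        freqs[0] = x / n2
        dead = False
        for g in range(1, T + 1):
            n_prev = sizes_rev[T - g + 1]
            n2 = sizes_rev[T - g]
            f = x / n_prev
            if x > 0:
                fsel = f * (1.0 + 0.5 * s * (1.0 + f)) / (1.0 + s * f)
                if fsel > 1.0:
                    fsel = 1.0
                x = np.random.binomial(int(n2), fsel)
            else:
                x = 0
            if mu_b > 0.0 and x < n2:
                o = np.random.binomial(int(n2 - x), mu_b)
                if o > 0:
                    origins[g] = o
                    x += o
            freqs[g] = x / n2
            if mu_b == 0.0:
                if x == 0:
                    dead = True
                    break
                if x == int(n2) and hi < 1.0:
                    dead = True
                    break
        if dead:
            continue
        if lo <= freqs[T] <= hi:
            return attempt, T, freqs, origins
    return 0, -1, empty, empty_o


def simulate_trajectory(
    p: SweepParams,
    dem: Demography,
    rng: np.random.Generator,
    max_tries: int = 1_000_000,
) -> Trajectory:
    """Forward Wright-Fisher trajectory with additive selection at full
    population size, conditioned on the present-day frequency window."""
    if p.mode not in _MODE_CODE:
        raise ValueError(f"unknown sweep mode {p.mode!r}")
    if p.mode == "sgv" and (p.f0 is None or not (0 < p.f0 < 1)):
        raise ValueError("sgv mode requires 0 < f0 < 1")
    t_min, t_max = (p.onset_range if p.onset_range else (int(p.onset), int(p.onset)))
    sizes_rev = np.array([2.0 * dem.size_at(t) for t in range(t_max + 1)])
    mu_b = p.theta_b / (4.0 * NE_REF) if p.mode == "srm" else 0.0
    tries, onset, freqs, origins = _trajectory_attempts(
        sizes_rev,
        int(t_min),
        int(t_max),
        _MODE_CODE[p.mode],
        p.s,
        p.f0 or 0.0,
        mu_b,
        p.freq_window[0],
        p.freq_window[1],
        max_tries,
        int(rng.integers(1, 2**31 - 1)),
    )
    if tries == 0:
        raise TrajectoryBudgetError(
            f"no trajectory hit the window {p.freq_window} in {max_tries} tries "
            f"(mode={p.mode}, s={p.s}, onset={p.onset}, range={p.onset_range})"
        )
    return Trajectory(freqs, origins, int(onset), int(tries))


@dataclass
class SweepSimResult:
    hm: HaplotypeMatrix
    selected_site: int
    sample_freq: float
    founder_count: int
    trajectory: Trajectory
    params: SweepParams
    seed: int | None = None
    tries: int = 1


class SweepFilterError(RuntimeError):
    pass


#: cap on the scaled forward population, in haplotypes.  Drift in epochs
#: whose scaled size exceeds the cap is negligible on sweep time scales, so
#: clipping bounds the engine's cost under recent explosive growth.
MAX_SCALED_POP = 3000


def _scaled_schedule(
    traj: Trajectory, dem: Demography, onset: int, Q: int, rng: np.random.Generator
):
    """Downsample the real-scale trajectory to scaled generations.

    Carrier counts follow the real trajectory's frequencies (minimum one
    copy while the allele segregates).  Recurrent-origin events are thinned
    binomially by 1/Q: a scaled generation spans Q real generations but the
    scaled population is Q-fold smaller, so the expected number of origin
    *events* per scaled generation equals the real per-generation rate.
    """
    n_gen = int(np.ceil(onset / Q)) if onset > 0 else 0
    real_idx = np.minimum(np.arange(n_gen + 1) * Q, onset)
    sizes = np.maximum(
        np.round([2.0 * dem.size_at(onset - g) / Q for g in real_idx]).astype(np.int64), 4
    )
    sizes = np.minimum(sizes, MAX_SCALED_POP)
    counts = np.minimum(np.round(traj.freqs[real_idx] * sizes).astype(np.int64), sizes)
    counts = np.where((traj.freqs[real_idx] > 0) & (counts == 0), 1, counts)
    origins = np.zeros(n_gen + 1, dtype=np.int64)
    for tau in range(1, n_gen + 1):
        block = int(traj.origins[real_idx[tau - 1] + 1 : real_idx[tau] + 1].sum())
        if block:
            origins[tau] = rng.binomial(block, 1.0 / Q)
    return sizes, counts, origins


def _single_sweep(
    p: SweepParams,
    dem: Demography,
    n_hap: int,
    length: float,
    mu: float,
    rec: float,
    Q: int,
    rng: np.random.Generator,
) -> SweepSimResult:
    traj = simulate_trajectory(p, dem, rng)
    n0_nominal = max(
        int(min(round(2.0 * dem.size_at(traj.onset) / Q), MAX_SCALED_POP)), 4
    )
    init = simulate_neutral(
        dem,
        n0_nominal,
        length=length,
        mu=mu,
        rec=rec,
        seed=int(rng.integers(1, 2**31 - 1)),
        sample_time=float(traj.onset),
    )
    H0, pos0 = init.alleles, init.phys_pos.copy()
    n0 = H0.shape[0]
    fid = np.zeros(n0, dtype=np.int64)
    center = length / 2.0
    if p.mode == "sgv":
        # promote the standing neutral variant nearest the centre whose
        # count best matches the prescribed onset count ...
        k0 = max(int(round((p.f0 or 0.0) * n0)), 1)
        cnt = H0.sum(axis=0)
        cost = np.abs(cnt - k0) * (length / 10.0) + np.abs(pos0 - center)
        ok = (cnt >= 2) & (cnt < n0)
        if not ok.any():
            raise SweepFilterError("no usable standing variant for sgv initialization")
        cost[~ok] = np.inf
        sel_col = int(np.argmin(cost))
        carriers = np.flatnonzero(H0[:, sel_col] == 1)
        fid[carriers] = np.arange(1, carriers.size + 1)
        # ... then re-condition the trajectory on the variant's realized
        # frequency, so the forward schedule never jumps the carrier count
        # (and founder lineages) discontinuously at onset
        realized_f0 = carriers.size / n0
        if abs(realized_f0 - (p.f0 or 0.0)) / max(p.f0 or 1.0, 1e-9) > 1e-6:
            traj = simulate_trajectory(
                replace(p, f0=realized_f0, onset=traj.onset, onset_range=None),
                dem, rng,
            )
        sizes, counts, origins = _scaled_schedule(traj, dem, traj.onset, Q, rng)
        counts[0] = carriers.size
    else:
        # fresh beneficial column at the exact centre
        sizes, counts, origins = _scaled_schedule(traj, dem, traj.onset, Q, rng)
        sel_col = H0.shape[1]
        col = np.zeros((n0, 1), dtype=np.uint8)
        k0 = int(counts[0])
        if k0 > 0:
            chosen = rng.choice(n0, size=k0, replace=False)
            col[chosen, 0] = 1
            fid[chosen] = np.arange(1, k0 + 1)
        H0 = np.hstack([H0, col])
        pos0 = np.append(pos0, center)
    H, pos, sel_col, fid = forward_sweep(
        H0, pos0, length, sel_col, fid, sizes, counts, origins,
        rec * Q, mu * Q, rng,
    )
    take = rng.choice(H.shape[0], size=n_hap, replace=False)
    Hs, fid_s = H[take], fid[take]
    sel_count = int(Hs[:, sel_col].sum())
    keep = np.flatnonzero((Hs.sum(axis=0) > 0) & (Hs.sum(axis=0) < n_hap))
    if sel_col not in keep:
        keep = np.sort(np.append(keep, sel_col))
    order = keep[np.argsort(pos[keep], kind="stable")]
    hm = HaplotypeMatrix(Hs[:, order], pos[order], pos[order] * rec * 100.0)
    sel_index = int(np.flatnonzero(order == sel_col)[0])
    founders = np.unique(fid_s[Hs[:, sel_col] == 1])
    return SweepSimResult(
        hm=hm,
        selected_site=sel_index,
        sample_freq=sel_count / n_hap,
        founder_count=int(founders.size),
        trajectory=traj,
        params=p,
    )


def simulate_sweep(
    p: SweepParams,
    dem: Demography,
    n_hap: int,
    seed: int | None = None,
    length: float = 2e6,
    mu: float = MU,
    rec: float = REC,
    Q: int = 10,
    max_tries: int = 50,
    require_founders: tuple[int, int] | None = None,
) -> SweepSimResult:
    """Simulate one sweep segment, retrying until the sampled beneficial
    frequency lies in the requested window and the founder-lineage filter
    holds (hard sweeps: exactly 1 founder; soft sweeps: >= 2).

    ``require_founders`` overrides the mode's default (min, max) filter.
    """
    rng = np.random.default_rng(seed)
    if require_founders is None:
        require_founders = (1, 1) if p.mode == "hard" else (2, 10**9)
    lo, hi = p.freq_window
    fmin, fmax = require_founders
    for attempt in range(1, max_tries + 1):
        res = _single_sweep(p, dem, n_hap, length, mu, rec, Q, rng)
        if lo <= res.sample_freq <= hi and fmin <= res.founder_count <= fmax:
            res.seed = seed
            res.tries = attempt
            return res
    raise SweepFilterError(
        f"no replicate passed the frequency/founder filters in {max_tries} tries "
        f"(mode={p.mode}, s={p.s}, onset={p.onset})"
    )


# ---------------------------------------------------------------------------
# simulated reference distribution for sweep-type classification


def _neutral_point_raws(dem, n, n_hap, length, rng, params):
    """Raw focal scores of n independent neutral segments."""
    import pandas as pd

    from . import core

    rows = []
    while len(rows) < n:
        hm = simulate_neutral(dem, n_hap, length=length,
                              seed=int(rng.integers(1, 2**31 - 1)))
        x0 = _scorable_site_near_center(hm, params)
        if x0 is None:
            continue
        rec = core.site_raw(hm, x0, params)
        if not rec.reason:
            rows.append((rec.freq, rec.uihsl, rec.urihs0, rec.urihs1))
    return pd.DataFrame(rows, columns=["freq", "uihsl", "urihs0", "urihs1"])


def _sweep_point_raws(dem, label, n, n_hap, length, Q, rng, params):
    """Raw selected-site scores of n sweep segments with parameters drawn
    from the reference-distribution priors: 2*Ne_ref*s ~ U(50, 1000), onset
    ~ U(0, 2000), soft f0 ~ U(0.01, 0.2); retained when the sampled
    adaptive frequency lies in (0.05, 0.95) and the founder filter holds."""
    import pandas as pd

    from . import core

    rows = []
    while len(rows) < n:
        s = rng.uniform(50, 1000) / (2.0 * NE_REF)
        if label == "hard":
            p = SweepParams(mode="hard", s=s, onset_range=(1, 2000),
                            freq_window=(0.05, 0.95))
        else:
            p = SweepParams(mode="sgv", s=s, f0=float(rng.uniform(0.01, 0.2)),
                            onset_range=(1, 2000), freq_window=(0.05, 0.95))
        try:
            res = simulate_sweep(p, dem, n_hap, seed=int(rng.integers(1, 2**31 - 1)),
                                 length=length, Q=Q, max_tries=4)
        except (TrajectoryBudgetError, SweepFilterError):
            continue
        rec = core.site_raw(res.hm, res.selected_site, params)
        if not rec.reason:
            rows.append((rec.freq, rec.uihsl, rec.urihs0, rec.urihs1,
                         res.founder_count, res.trajectory.onset, p.s, p.f0 or 0.0))
    return pd.DataFrame(rows, columns=["freq", "uihsl", "urihs0", "urihs1",
                                       "founders", "onset", "s", "f0"])


def _default_ref_params():
    from . import core

    return core.ScanParams(compute_ihs=False, compute_nsl=False)


def build_reference(
    pop: str = "YRI",
    n_per_class: int = 2_000,
    seed: int | None = None,
    length: float = 3e5,
    Q: int = 10,
    n_hap: int | None = None,
    scan_params=None,
):
    """Labelled (iHSL, RiHS) reference points under an out-of-Africa
    demographic model: neutral segments plus hard and soft (standing
    variation) sweeps.  Standardization is fitted on the neutral class and
    applied to all points.

    Returns a :class:`sweepscan.classify.ReferenceDistribution` together
    with the neutral-fit :class:`sweepscan.core.NormalizationModel`.
    """
    from . import core
    from .classify import ReferenceDistribution

    params = scan_params or _default_ref_params()
    dem = out_of_africa(pop)
    if n_hap is None:
        n_hap = OOA_SAMPLE_HAPLOTYPES[pop]
    rng = np.random.default_rng(seed)
    neutral = _neutral_point_raws(dem, n_per_class, n_hap, length, rng, params)
    model = core.fit_normalization(neutral, params, columns=("uihsl", "urihs0", "urihs1"))
    pts, labels = [], []
    for _, row in neutral.iterrows():
        pts.append(_standardize_point(model, row["freq"], row["uihsl"],
                                      row["urihs0"], row["urihs1"]))
        labels.append("neutral")
    for label in ("hard", "soft"):
        raws = _sweep_point_raws(dem, label, n_per_class, n_hap, length, Q, rng, params)
        for _, row in raws.iterrows():
            pts.append(_standardize_point(model, row["freq"], row["uihsl"],
                                          row["urihs0"], row["urihs1"]))
            labels.append(label)
    ref = ReferenceDistribution(
        points=np.array(pts),
        labels=np.array(labels),
        provenance={
            "model": dem.name,
            "n_per_class": n_per_class,
            "length": length,
            "Q": Q,
            "n_hap": n_hap,
            "seed": seed,
        },
    )
    return ref, model


def labeled_sweep_points(
    pop: str,
    n_per_class: int,
    model,
    seed: int | None = None,
    length: float = 3e5,
    Q: int = 10,
    n_hap: int | None = None,
    scan_params=None,
):
    """Held-out labelled sweep points (hard + soft) standardized with a
    supplied (typically the data population's own) normalization model;
    includes the composite RiHSL p-value used to restrict to significant
    calls."""
    import pandas as pd

    params = scan_params or _default_ref_params()
    dem = out_of_africa(pop)
    if n_hap is None:
        n_hap = OOA_SAMPLE_HAPLOTYPES[pop]
    rng = np.random.default_rng(seed)
    rows = []
    for label in ("hard", "soft"):
        raws = _sweep_point_raws(dem, label, n_per_class, n_hap, length, Q, rng, params)
        for _, row in raws.iterrows():
            z, rs = _standardize_point(model, row["freq"], row["uihsl"],
                                       row["urihs0"], row["urihs1"])
            rows.append({"ihsl": z, "rihs": rs,
                         "p_rihsl": float(np.exp(-0.5 * (z**2 + rs**2))),
                         "true_label": label, "founders": int(row["founders"]),
                         "onset": int(row["onset"]), "s": row["s"], "f0": row["f0"],
                         "freq": row["freq"]})
    return pd.DataFrame(rows)


def _scorable_site_near_center(hm: HaplotypeMatrix, params) -> int | None:
    """Site closest to the segment centre with in-range derived frequency."""
    f = hm.derived_freq()
    ok = (f >= params.min_freq) & (f <= 1 - params.min_freq)
    if not ok.any():
        return None
    center = (hm.phys_pos[0] + hm.phys_pos[-1]) / 2.0
    cand = np.flatnonzero(ok)
    return int(cand[np.argmin(np.abs(hm.phys_pos[cand] - center))])


def _standardize_point(model, freq, uihsl, urihs0, urihs1):
    z = float(model.transform(np.array([uihsl]), np.array([freq]), "uihsl")[0])
    name = "urihs1" if z >= 0 else "urihs0"
    val = urihs1 if z >= 0 else urihs0
    rs = float(model.transform(np.array([val]), np.array([freq]), name)[0])
    return z, rs
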
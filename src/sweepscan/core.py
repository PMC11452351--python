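"""Local-cluster EHH sweep statistics: iHSL, RiHS and the RiHSL composite.

The scan statistic family generalizes the classic integrated-haplotype-score
(iHS) idea.  At a core SNP the sample splits into a derived (1) and an
ancestral (0) allele class.  Instead of measuring extended haplotype
homozygosity (EHH) over a whole allele class — which collapses quickly when
a sweep rises on several founder haplotypes — homozygosity is measured
inside *local clusters*: for each focal haplotype, the focal plus its s
nearest neighbours by Hamming distance on the local window.  Averaging the
integrated within-cluster homozygosity (iHH) over focal haplotypes gives
iHHL per allele class, and

* ``uiHSL  = ln(iHHL_1 / iHHL_0)``      — sweep signal on either allele,
* ``uRiHS_c = ln(iHHL_c / iHH_c) >= 0`` — excess of cluster-level over
  class-level homozygosity, elevated when the sweeping class is a mixture
  of founder lineages (a soft sweep).

Raw scores are z-standardized within derived-allele-frequency bins fitted
genome-wide (low-frequency alleles are younger and carry longer haplotypes,
so the raw statistics are frequency-confounded).  The composite
``RiHSL = iHSL^2 + RiHS^2`` behaves approximately as a chi-square with 2 df
under neutrality; the allele class entering RiHS is chosen by the sign of
the standardized iHSL.

Setting the cluster fraction r = 1 makes every cluster the whole allele
class, and iHSL reduces exactly to iHS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from .matrix import HaplotypeMatrix

__all__ = [
    "ScanParams",
    "CoreSiteContext",
    "LocalCluster",
    "NormalizationModel",
    "cluster_size",
    "local_cluster",
    "ehh_cluster",
    "ihh_cluster",
    "ihhl_allele",
    "uihsl",
    "urihs",
    "site_raw",
    "raw_score_table",
    "fit_normalization",
    "score_sites",
]

#: 1% one-tailed standard-normal critical value used throughout power work
IHSL_1PCT = float(stats.norm.isf(0.01))
#: 1% upper-tail chi-square(2 df) critical value for RiHSL
RIHSL_1PCT = float(stats.chi2.isf(0.01, df=2))


@dataclass(frozen=True)
class ScanParams:
    """Tunable knobs of the scan.

    r
        Local-cluster fraction; cluster diameter s = min(max(ceil(r*|Hc|),
        min_neighbors), |Hc|).  r = 1 recovers iHS.
    max_extend
        L: markers per side defining both the local-haplotype window used
        for Hamming distances and the EHH integration cap.
    ehh_cutoff
        Optional early stop: end a side's integration once within-cluster
        EHH falls below this.  The default 0 integrates the full L-marker
        window on both the cluster and the class, which keeps the
        cluster/class ratio (uRiHS) a pure homozygosity contrast; an
        iHS-style cutoff (e.g. 0.05) truncates the class integral earlier
        than the cluster integral and distorts that ratio.
    min_freq
        Sites with derived frequency outside [min_freq, 1 - min_freq] are
        left unscored.
    n_bins / min_bin_count
        Frequency-bin standardization: equal-width bins on (0, 1),
        underfilled bins merged with a neighbour.
    nsl_max_extend
        Per-side cap, in SNPs, of the pairwise identity length used by nSL.
    neighbor_pool
        Where a focal haplotype's nearest neighbours come from.  The
        default ``"class"`` restricts them to the focal's own allele class,
        under which r = 1 reduces iHSL to iHS exactly.  ``"all"`` draws
        them from the whole sample, so clusters may mix core alleles and
        cluster EHH starts below 1 at the core; this variant calibrates
        identically under neutrality but dilutes the cluster signal of
        very soft (recurrent-mutation) sweeps.
    """

    r: float = 0.1
    max_extend: int = 400
    min_neighbors: int = 8
    ehh_cutoff: float = 0.0
    min_freq: float = 0.05
    n_bins: int = 50
    min_bin_count: int = 20
    nsl_max_extend: int = 500
    neighbor_pool: str = "class"
    compute_nsl: bool = True
    compute_ihs: bool = True

    def __post_init__(self) -> None:
        if self.neighbor_pool not in ("all", "class"):
            raise ValueError("neighbor_pool must be 'all' or 'class'")

    def with_r(self, r: float) -> "ScanParams":
        return replace(self, r=r)


def cluster_size(n_class: int, r: float, floor: int = 8) -> int:
    """Cluster diameter s = min(max(ceil(r*|Hc|), floor), |Hc|)."""
    return int(min(max(math.ceil(r * n_class), floor), n_class))


@dataclass
class CoreSiteContext:
    """Allele classes and window bounds at one core site."""

    core_index: int
    window_half_length: int
    derived_class: np.ndarray
    ancestral_class: np.ndarray
    derived_freq: float
    lo: int  # first window column (inclusive)
    hi: int  # last window column (inclusive)
    edge_truncated: bool

    @classmethod
    def from_matrix(
        cls, hm: HaplotypeMatrix, core_index: int, window_half_length: int = 400
    ) -> "CoreSiteContext":
        d = hm.alleles[:, core_index]
        lo = max(0, core_index - window_half_length)
        hi = min(hm.n_sites - 1, core_index + window_half_length)
        return cls(
            core_index=core_index,
            window_half_length=window_half_length,
            derived_class=np.flatnonzero(d == 1),
            ancestral_class=np.flatnonzero(d == 0),
            derived_freq=float(d.mean()),
            lo=lo,
            hi=hi,
            edge_truncated=(lo > core_index - window_half_length)
            or (hi < core_index + window_half_length),
        )

    def allele_class(self, c: int) -> np.ndarray:
        return self.derived_class if c == 1 else self.ancestral_class


@dataclass
class LocalCluster:
    """A focal haplotype together with its nearest same-allele neighbours."""

    focal: int
    members: np.ndarray  # haplotype indices into the full matrix, focal first
    diameter: int  # s


class UnscorableSiteError(ValueError):
    """Raised when a core site cannot be scored (degenerate allele class)."""


def _hamming_order(alleles_window: np.ndarray) -> np.ndarray:
    """Row-wise neighbour order by (Hamming distance on the window,
    haplotype index); stable argsort breaks ties by ascending index."""
    x = alleles_window.astype(np.float32)
    sums = x.sum(axis=1)
    d = sums[:, None] + sums[None, :] - 2.0 * (x @ x.T)
    dist = np.rint(d).astype(np.int32)
    return np.argsort(dist, axis=1, kind="stable")


def local_cluster(
    hm: HaplotypeMatrix,
    ctx: CoreSiteContext,
    j: int,
    r: float = 0.1,
    min_neighbors: int = 8,
    pool: str = "class",
) -> LocalCluster:
    """Local cluster of haplotype ``j``: focal plus its s nearest neighbours
    by Hamming distance on the local window.  ``pool`` selects whether the
    neighbours come from the whole sample or only the focal's allele class;
    the diameter s is defined on the class size either way."""
    c = int(hm.alleles[j, ctx.core_index])
    idx = ctx.allele_class(c)
    if idx.size < 2:
        raise UnscorableSiteError(
            f"allele class {c} at site {ctx.core_index} has < 2 haplotypes"
        )
    window_cols = np.arange(ctx.lo, ctx.hi + 1)
    cand = np.arange(hm.n_haplotypes) if pool == "all" else idx
    order = _hamming_order(hm.alleles[np.ix_(cand, window_cols)])
    jj = int(np.searchsorted(cand, j))
    if jj >= cand.size or cand[jj] != j:
        raise ValueError(f"haplotype {j} does not carry allele {c} at the core")
    s = cluster_size(idx.size, r, min_neighbors)
    picked = [jj]
    for o in order[jj]:
        if len(picked) > min(s, cand.size - 1):
            break
        if o == jj:
            continue
        picked.append(int(o))
    return LocalCluster(focal=j, members=cand[np.array(picked)], diameter=s)


def _side_columns(ctx: CoreSiteContext, side: str) -> np.ndarray:
    """Site indices walking outward from the core on one side."""
    x0 = ctx.core_index
    if side == "up":
        return np.arange(x0 - 1, ctx.lo - 1, -1)
    return np.arange(x0 + 1, ctx.hi + 1)


def ehh_cluster(
    hm: HaplotypeMatrix, ctx: CoreSiteContext, cluster: LocalCluster, marker_index: int
) -> float:
    """EHH of the cluster at a marker: probability two members drawn without
    replacement are identical over the core-to-marker stretch (inclusive)."""
    if cluster.members.size < 2:
        raise UnscorableSiteError("EHH undefined for a cluster of size < 2")
    x0 = ctx.core_index
    a, b = (marker_index, x0) if marker_index <= x0 else (x0, marker_index)
    stretch = hm.alleles[np.ix_(cluster.members, np.arange(a, b + 1))]
    _, counts = np.unique(stretch, axis=0, return_counts=True)
    k = cluster.members.size
    return float((counts * (counts - 1)).sum() / (k * (k - 1)))


def _cluster_ihh_kernel_inputs(hm: HaplotypeMatrix, ctx: CoreSiteContext, members: np.ndarray):
    out = []
    core_allele = hm.alleles[members, ctx.core_index]
    x0 = ctx.core_index
    for side in ("up", "dn"):
        cols = _side_columns(ctx, side)
        window = np.ascontiguousarray(hm.alleles[np.ix_(members, cols)])
        T = _kernels.pair_extents_with_core(window, core_allele, cols.size)
        gaps = np.abs(np.diff(hm.gen_pos[np.concatenate(([x0], cols))]))
        out.append((T, gaps))
    return out


def ihh_cluster(
    hm: HaplotypeMatrix,
    ctx: CoreSiteContext,
    cluster: LocalCluster,
    ehh_cutoff: float = 0.0,
) -> float:
    """Integrated within-cluster haplotype homozygosity, both sides of the
    core, in genetic-distance units (trapezoidal quadrature)."""
    sides = _cluster_ihh_kernel_inputs(hm, ctx, cluster.members)
    local = np.arange(cluster.members.size, dtype=np.int64)
    total = 0.0
    for T, gaps in sides:
        total += _kernels.cluster_side_ihh(T, local, gaps, ehh_cutoff)
    return total


def ihhl_allele(
    hm: HaplotypeMatrix,
    ctx: CoreSiteContext,
    c: int,
    params: ScanParams = ScanParams(),
) -> tuple[float, float]:
    """(iHHL_c, iHH_c): mean local-cluster iHH over class members, and the
    whole-class iHH (the r = 1 special case under the class pool)."""
    idx = ctx.allele_class(c)
    if idx.size < 2:
        raise UnscorableSiteError(
            f"allele class {c} at site {ctx.core_index} has < 2 haplotypes"
        )
    rec = site_raw(
        hm, ctx.core_index,
        replace(params, max_extend=ctx.window_half_length, min_freq=0.0,
                compute_nsl=False, compute_ihs=False),
    )
    if rec.reason:
        raise UnscorableSiteError(rec.reason)
    return (rec.ihhl1, rec.ihh1) if c == 1 else (rec.ihhl0, rec.ihh0)


def uihsl(ihhl_1: float, ihhl_0: float) -> float:
    """ln(iHHL_1 / iHHL_0); requires both positive."""
    if ihhl_1 <= 0 or ihhl_0 <= 0:
        raise UnscorableSiteError("uiHSL undefined: non-positive iHHL")
    return math.log(ihhl_1 / ihhl_0)


def urihs(ihhl_c: float, ihh_c: float) -> float:
    """ln(iHHL_c / iHH_c); non-negative by construction of the clusters."""
    if ihhl_c <= 0 or ihh_c <= 0:
        raise UnscorableSiteError("uRiHS undefined: non-positive iHH")
    return math.log(ihhl_c / ihh_c)


# ---------------------------------------------------------------------------
# batch per-site engine


@dataclass
class SiteRaw:
    """Unstandardized per-site scores (None where undefined)."""

    site: int
    freq: float
    uihsl: float | None = None
    urihs0: float | None = None
    urihs1: float | None = None
    uihs: float | None = None
    unsl: float | None = None
    ihhl1: float | None = None
    ihhl0: float | None = None
    ihh1: float | None = None
    ihh0: float | None = None
    edge_truncated: bool = False
    reason: str = ""


def site_raw(hm: HaplotypeMatrix, x0: int, params: ScanParams = ScanParams()) -> SiteRaw:
    """Compute every unstandardized statistic at one core site.

    Pair extents are computed once and shared between iHSL, iHS (the
    whole-class special case) and nSL, so requesting the comparators is
    nearly free.
    """
    freq = hm.derived_freq(x0)
    rec = SiteRaw(site=x0, freq=freq)
    if not (params.min_freq <= freq <= 1 - params.min_freq):
        rec.reason = "freq_out_of_range"
        return rec
    max_side = params.max_extend
    if params.compute_nsl:
        max_side = max(max_side, params.nsl_max_extend)
    ctx = CoreSiteContext.from_matrix(hm, x0, max_side)
    rec.edge_truncated = (x0 - params.max_extend < 0) or (
        x0 + params.max_extend > hm.n_sites - 1
    )
    d = hm.alleles[:, x0]
    classes = {1: ctx.derived_class, 0: ctx.ancestral_class}
    if min(classes[1].size, classes[0].size) < 2:
        rec.reason = "class_too_small"
        return rec
    gen = hm.gen_pos
    ham_cols = np.arange(
        max(0, x0 - params.max_extend), min(hm.n_sites - 1, x0 + params.max_extend) + 1
    )
    per_class: dict[int, dict] = {1: {}, 0: {}}

    if params.neighbor_pool == "all":
        Ts, gapss = [], []
        for side in ("up", "dn"):
            cols = _side_columns(ctx, side)
            window = np.ascontiguousarray(hm.alleles[:, cols])
            Ts.append(_kernels.pair_extents_with_core(window, d, max_side))
            gaps = np.abs(np.diff(gen[np.concatenate(([x0], cols))]))
            gapss.append(gaps[: params.max_extend])
        (T_up, T_dn), (g_up, g_dn) = Ts, gapss
        order = _hamming_order(hm.alleles[:, ham_cols])
        s1 = cluster_size(classes[1].size, params.r, params.min_neighbors)
        s0 = cluster_size(classes[0].size, params.r, params.min_neighbors)
        sum1, sum0 = _kernels.all_focal_cluster_ihh(
            T_up, T_dn, order, d.astype(np.int64), s1, s0, g_up, g_dn,
            params.ehh_cutoff,
        )
        per_class[1]["ihhl"] = sum1 / classes[1].size
        per_class[0]["ihhl"] = sum0 / classes[0].size
        for c in (1, 0):
            idx = classes[c]
            Tc_up = np.ascontiguousarray(T_up[np.ix_(idx, idx)])
            Tc_dn = np.ascontiguousarray(T_dn[np.ix_(idx, idx)])
            whole = np.arange(idx.size, dtype=np.int64)
            per_class[c]["ihh"] = _kernels.cluster_side_ihh(
                Tc_up, whole, g_up, params.ehh_cutoff
            ) + _kernels.cluster_side_ihh(Tc_dn, whole, g_dn, params.ehh_cutoff)
            if params.compute_nsl:
                per_class[c]["nsl"] = _kernels.class_mean_nsl(
                    Tc_up, Tc_dn, params.nsl_max_extend
                )
    else:
        for c in (1, 0):
            idx = classes[c]
            res = per_class[c]
            Ts, gapss = [], []
            for side in ("up", "dn"):
                cols = _side_columns(ctx, side)
                window = np.ascontiguousarray(hm.alleles[np.ix_(idx, cols)])
                Ts.append(_kernels.pair_extents(window, max_side))
                gaps = np.abs(np.diff(gen[np.concatenate(([x0], cols))]))
                gapss.append(gaps[: params.max_extend])
            (T_up, T_dn), (g_up, g_dn) = Ts, gapss
            whole = np.arange(idx.size, dtype=np.int64)
            res["ihh"] = _kernels.cluster_side_ihh(
                T_up, whole, g_up, params.ehh_cutoff
            ) + _kernels.cluster_side_ihh(T_dn, whole, g_dn, params.ehh_cutoff)
            order = _hamming_order(hm.alleles[np.ix_(idx, ham_cols)])
            s = cluster_size(idx.size, params.r, params.min_neighbors)
            res["ihhl"] = _kernels.class_mean_cluster_ihh(
                T_up, T_dn, order, min(s, idx.size - 1), g_up, g_dn,
                params.ehh_cutoff,
            )
            if params.compute_nsl:
                res["nsl"] = _kernels.class_mean_nsl(T_up, T_dn, params.nsl_max_extend)

    rec.ihhl1, rec.ihhl0 = per_class[1]["ihhl"], per_class[0]["ihhl"]
    rec.ihh1, rec.ihh0 = per_class[1]["ihh"], per_class[0]["ihh"]
    if min(rec.ihhl1, rec.ihhl0, rec.ihh1, rec.ihh0) <= 0:
        rec.reason = "zero_ihh"
        return rec
    rec.uihsl = math.log(rec.ihhl1 / rec.ihhl0)
    rec.urihs1 = math.log(rec.ihhl1 / rec.ihh1)
    rec.urihs0 = math.log(rec.ihhl0 / rec.ihh0)
    if params.compute_ihs:
        rec.uihs = math.log(rec.ihh1 / rec.ihh0)
    if params.compute_nsl:
        rec.unsl = math.log(per_class[1]["nsl"] / per_class[0]["nsl"])
    return rec


_RAW_COLUMNS = [
    "site",
    "pos_bp",
    "pos_cm",
    "freq",
    "uihsl",
    "urihs0",
    "urihs1",
    "uihs",
    "unsl",
    "edge_truncated",
    "reason",
]


def raw_score_table(
    hm: HaplotypeMatrix,
    params: ScanParams = ScanParams(),
    sites: np.ndarray | None = None,
) -> pd.DataFrame:
    """Unstandardized score table for the requested sites (default: all)."""
    if sites is None:
        sites = np.arange(hm.n_sites)
    rows = []
    for x0 in np.asarray(sites):
        rec = site_raw(hm, int(x0), params)
        rows.append(
            (
                rec.site,
                hm.phys_pos[rec.site],
                hm.gen_pos[rec.site],
                rec.freq,
                np.nan if rec.uihsl is None else rec.uihsl,
                np.nan if rec.urihs0 is None else rec.urihs0,
                np.nan if rec.urihs1 is None else rec.urihs1,
                np.nan if rec.uihs is None else rec.uihs,
                np.nan if rec.unsl is None else rec.unsl,
                rec.edge_truncated,
                rec.reason,
            )
        )
    return pd.DataFrame(rows, columns=_RAW_COLUMNS)


# ---------------------------------------------------------------------------
# frequency-bin standardization


class NormalizationModel:
    """Per-statistic frequency-bin z-standardization.

    Each statistic column gets its own set of equal-width derived-frequency
    bins on (0, 1); bins holding fewer than ``min_bin_count`` finite values
    are merged with their smaller adjacent neighbour until all bins are
    usable.  Standardization is (x - mean_bin) / sd_bin with the n-1 sample
    SD convention.
    """

    def __init__(self) -> None:
        self.bins: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @staticmethod
    def _merge_edges(
        freqs: np.ndarray, n_bins: int, min_count: int
    ) -> np.ndarray:
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        while edges.size > 2:
            counts, _ = np.histogram(freqs, bins=edges)
            bad = np.flatnonzero(counts < min_count)
            if bad.size == 0:
                break
            i = int(bad[0])
            if i == 0:
                drop = 1
            elif i == counts.size - 1:
                drop = i
            else:
                drop = i if counts[i - 1] <= counts[i + 1] else i + 1
            edges = np.delete(edges, drop)
        return edges

    def fit_column(
        self,
        values: np.ndarray,
        freqs: np.ndarray,
        name: str,
        n_bins: int = 50,
        min_count: int = 20,
    ) -> None:
        ok = np.isfinite(values) & np.isfinite(freqs)
        v, f = np.asarray(values)[ok], np.asarray(freqs)[ok]
        if v.size < 2:
            raise ValueError(f"not enough finite values to standardize {name!r}")
        edges = self._merge_edges(f, n_bins, min_count)
        which = np.clip(np.digitize(f, edges) - 1, 0, edges.size - 2)
        mean = np.empty(edges.size - 1)
        sd = np.empty(edges.size - 1)
        for b in range(edges.size - 1):
            sel = v[which == b]
            if sel.size < 2:
                raise ValueError(f"degenerate frequency bin for {name!r}")
            mean[b] = sel.mean()
            sd[b] = sel.std(ddof=1)
            if sd[b] <= 0:
                raise ValueError(f"zero-variance frequency bin for {name!r}")
        self.bins[name] = (edges, mean, sd)

    def transform(self, values: np.ndarray, freqs: np.ndarray, name: str) -> np.ndarray:
        edges, mean, sd = self.bins[name]
        values = np.asarray(values, dtype=float)
        which = np.clip(np.digitize(freqs, edges) - 1, 0, edges.size - 2)
        out = (values - mean[which]) / sd[which]
        out[~np.isfinite(values)] = np.nan
        return out


def fit_normalization(
    raw: pd.DataFrame,
    params: ScanParams = ScanParams(),
    columns: tuple[str, ...] = ("uihsl", "urihs0", "urihs1", "uihs", "unsl"),
) -> NormalizationModel:
    """Fit frequency-bin standardization from an unstandardized score table."""
    model = NormalizationModel()
    for col in columns:
        if col in raw.columns and raw[col].notna().any():
            model.fit_column(
                raw[col].to_numpy(),
                raw["freq"].to_numpy(),
                col,
                params.n_bins,
                params.min_bin_count,
            )
    return model


def standardize_scores(raw: pd.DataFrame, model: NormalizationModel) -> pd.DataFrame:
    """Apply a fitted model: adds iHSL, RiHS, RiHSL, iHS, nSL and p-values."""
    out = raw.copy()
    freq = out["freq"].to_numpy()
    out["ihsl"] = model.transform(out["uihsl"].to_numpy(), freq, "uihsl")
    r0 = model.transform(out["urihs0"].to_numpy(), freq, "urihs0")
    r1 = model.transform(out["urihs1"].to_numpy(), freq, "urihs1")
    # allele class entering RiHS follows the sign of the standardized iHSL
    out["rihs"] = np.where(out["ihsl"].to_numpy() >= 0, r1, r0)
    out["rihsl"] = out["ihsl"] ** 2 + out["rihs"] ** 2
    if "uihs" in model.bins:
        out["ihs"] = model.transform(out["uihs"].to_numpy(), freq, "uihs")
    if "unsl" in model.bins:
        out["nsl"] = model.transform(out["unsl"].to_numpy(), freq, "unsl")
    out["p_ihsl"] = 2.0 * stats.norm.sf(np.abs(out["ihsl"]))
    out["p_rihsl"] = np.exp(-0.5 * out["rihsl"])
    out["sweep_label"] = np.where(out["ihsl"].isna(), "unscored", "neutral")
    return out


def score_sites(
    hm: HaplotypeMatrix,
    params: ScanParams = ScanParams(),
    sites: np.ndarray | None = None,
    model: NormalizationModel | None = None,
) -> pd.DataFrame:
    """Full pipeline: raw scores, frequency-bin standardization (fitted on
    this table when no model is given), composites and p-values."""
    raw = raw_score_table(hm, params, sites)
    if model is None:
        model = fit_normalization(raw, params)
    return standardize_scores(raw, model)
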
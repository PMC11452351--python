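"""Baseline sweep statistics: iHS, nSL and Garud's H-statistics.

iHS is the r = 1 special case of the local-cluster statistic (every
"cluster" is the whole allele class), so it falls out of the core engine.
nSL replaces the genetic-distance integral with pairwise identity lengths
counted in SNPs (no genetic map needed), capped at 500 SNPs per side.
H12 / H2/H1 are window-haplotype frequency statistics: with p1 >= p2 >= ...
the distinct-haplotype frequencies in an SNP window,

    H1 = sum p_i^2,   H12 = (p1 + p2)^2 + sum_{i>=3} p_i^2,
    H2/H1 = (H1 - p1^2) / H1.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from . import core
from .matrix import HaplotypeMatrix

__all__ = ["ihs", "nsl", "h_stats", "h12_window_sweep", "H12_WINDOW_SIZES"]

#: SNP window sizes screened when tuning H12
H12_WINDOW_SIZES = (21, 51, 101, 201, 401, 1001, 2001)


def ihs(
    hm: HaplotypeMatrix,
    params: core.ScanParams = core.ScanParams(),
    sites: np.ndarray | None = None,
    model: core.NormalizationModel | None = None,
) -> pd.DataFrame:
    """iHS scan: identical to the local-cluster scan with r = 1 under the
    class-restricted neighbour pool (every cluster is the whole class)."""
    table = core.score_sites(
        hm, replace(params, r=1.0, neighbor_pool="class"), sites, model
    )
    table["statistic"] = "ihs"
    return table


def nsl(
    hm: HaplotypeMatrix,
    params: core.ScanParams = core.ScanParams(),
    sites: np.ndarray | None = None,
    model: core.NormalizationModel | None = None,
) -> pd.DataFrame:
    """nSL scan (already computed by the core engine; genetic positions in
    the matrix are ignored by the statistic itself)."""
    raw = core.raw_score_table(hm, params, sites)
    if model is None:
        model = core.NormalizationModel()
        model.fit_column(
            raw["unsl"].to_numpy(), raw["freq"].to_numpy(), "unsl",
            params.n_bins, params.min_bin_count,
        )
    out = raw.copy()
    out["nsl"] = model.transform(out["unsl"].to_numpy(), out["freq"].to_numpy(), "unsl")
    out["statistic"] = "nsl"
    return out


def h_stats(
    hm: HaplotypeMatrix, site: int, window_size: int
) -> tuple[float, float, float]:
    """(H12, H2/H1, H1) in an SNP window of odd size centred on ``site``
    (edge-truncated with a warning)."""
    if window_size < 1 or window_size % 2 == 0:
        raise ValueError("window size must be odd and positive")
    half = window_size // 2
    lo, hi = site - half, site + half + 1
    if lo < 0 or hi > hm.n_sites:
        warnings.warn(
            f"H-statistic window of {window_size} SNPs truncated at the "
            f"chromosome edge around site {site}",
            stacklevel=2,
        )
        lo, hi = max(0, lo), min(hm.n_sites, hi)
    block = hm.alleles[:, lo:hi]
    _, counts = np.unique(block, axis=0, return_counts=True)
    p = np.sort(counts / block.shape[0])[::-1]
    h1 = float((p**2).sum())
    h12 = h1 if p.size < 2 else float((p[0] + p[1]) ** 2 + (p[2:] ** 2).sum())
    h2_h1 = (h1 - p[0] ** 2) / h1
    return h12, float(h2_h1), h1


def h12_window_sweep(
    hm: HaplotypeMatrix, site: int, sizes: tuple[int, ...] = H12_WINDOW_SIZES
) -> dict[int, float]:
    """H12 at each candidate window size (sizes wider than the data are
    skipped with a warning); pick the winner by power with
    :func:`sweepscan.evaluate.best_h12_window`."""
    out: dict[int, float] = {}
    for size in sizes:
        if size > hm.n_sites:
            warnings.warn(f"window size {size} exceeds {hm.n_sites} sites; skipped",
                          stacklevel=2)
            continue
        out[size] = h_stats(hm, site, size)[0]
    return out
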
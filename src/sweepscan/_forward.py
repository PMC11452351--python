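"""Rescaled forward Wright-Fisher engine driven by a beneficial-allele
frequency trajectory.

The engine evolves an explicit haplotype population (one row per
chromosome) forward from selection onset to the present.  The number of
beneficial copies in each generation is prescribed by a trajectory
simulated at full population size; conditioning on the trajectory is what
msms-style machinery does, here realized forward in time.  Each generation:

* children destined to carry the beneficial allele copy their selected-site
  segment from a uniformly drawn carrier parent chromosome; non-carrier
  children from a non-carrier parent;
* the partner chromosome of every child is drawn uniformly from the whole
  parent generation, and crossovers (Poisson along the segment) exchange
  material between the two, with the segment containing the selected site
  pinned to the first parent;
* new neutral mutations arise as fresh biallelic columns at
  Poisson(mu * length) per child;
* recurrent beneficial origins (soft sweeps from recurrent mutation)
  convert non-carrier children into carriers with a fresh founder id.

Founder ids ride along with the selected-site copy, so the number of
distinct founder lineages surviving in the present-day sample falls out of
the bookkeeping directly.

All rates passed in are already rescaled (population sizes divided by the
rescaling factor Q, per-generation rates multiplied by Q).
"""

from __future__ import annotations

import numpy as np

__all__ = ["forward_sweep"]


class _ColumnStore:
    """Growable set of biallelic columns over a fixed-capacity population."""

    def __init__(self, init: np.ndarray, positions: np.ndarray, max_rows: int):
        n0, m0 = init.shape
        cap = max(2 * m0 + 1024, 4096)
        self.H = np.zeros((2, max_rows, cap), dtype=np.uint8)
        self.H[0, :n0, :m0] = init
        self.pos = np.empty(cap, dtype=np.float64)
        self.pos[:m0] = positions
        self.n_cols = m0
        self.base_cols = m0
        self.cur = 0
        self.n_rows = n0

    def grow(self, need: int) -> None:
        cap = self.H.shape[2]
        if self.n_cols + need <= cap:
            return
        new_cap = max(2 * cap, self.n_cols + need)
        H = np.zeros((2, self.H.shape[1], new_cap), dtype=np.uint8)
        H[:, :, : self.n_cols] = self.H[:, :, : self.n_cols]
        pos = np.empty(new_cap, dtype=np.float64)
        pos[: self.n_cols] = self.pos[: self.n_cols]
        self.H, self.pos = H, pos

    def active(self) -> np.ndarray:
        return self.H[self.cur, : self.n_rows, : self.n_cols]

    def prune(self, keep_col: int) -> int:
        """Drop columns lost or fixed in the current population; returns the
        new index of ``keep_col``."""
        a = self.active()
        sums = a.sum(axis=0, dtype=np.int64)
        keep = (sums > 0) & (sums < self.n_rows)
        keep[keep_col] = True
        idx = np.flatnonzero(keep)
        new_keep = int(np.searchsorted(idx, keep_col))
        nc = idx.size
        self.H[self.cur, : self.n_rows, :nc] = a[:, idx]
        self.pos[:nc] = self.pos[idx]
        self.n_cols = nc
        self.base_cols = nc
        return new_keep


def forward_sweep(
    init_haplotypes: np.ndarray,
    init_positions: np.ndarray,
    length: float,
    sel_col: int,
    founder_ids: np.ndarray,
    pop_sizes: np.ndarray,
    carrier_counts: np.ndarray,
    origin_counts: np.ndarray,
    rec_rate: float,
    mut_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Run the conditioned forward simulation.

    Parameters
    ----------
    init_haplotypes : (2N_0, m) 0/1 matrix of the population at onset.
    init_positions : column positions in bp (floats, unsorted OK).
    length : segment length in bp.
    sel_col : column index of the selected site in ``init_haplotypes``.
    founder_ids : per-chromosome founder label at onset (0 = non-carrier).
    pop_sizes : haplotype count per generation, ``pop_sizes[0]`` = onset.
    carrier_counts : prescribed beneficial copies per generation.
    origin_counts : new beneficial origins per generation (recurrent mode).
    rec_rate, mut_rate : per-bp per-(scaled)-generation rates.
    rng : numpy Generator.

    Returns
    -------
    (haplotypes, positions, sel_col, founder_ids) for the final generation;
    columns are in the engine's internal order (sort by position afterwards).
    """
    n_gen = pop_sizes.shape[0] - 1
    store = _ColumnStore(init_haplotypes, init_positions, int(pop_sizes.max()))
    fid = np.zeros(store.H.shape[1], dtype=np.int64)
    fid[: founder_ids.shape[0]] = founder_ids
    next_fid = int(founder_ids.max()) + 1
    sel_pos = float(init_positions[sel_col])

    for g in range(1, n_gen + 1):
        n_prev = int(pop_sizes[g - 1])
        n_next = int(pop_sizes[g])
        k_next = int(carrier_counts[g])
        o = min(int(origin_counts[g]), k_next)
        cur = store.cur
        nxt = 1 - cur
        ncols = store.n_cols
        Hc = store.H[cur, :n_prev, :ncols]
        sel = Hc[:, sel_col]
        carriers = np.flatnonzero(sel == 1)
        non_carriers = np.flatnonzero(sel == 0)
        c_t = k_next - o
        if carriers.size == 0:
            # trajectory says the allele (re)appears purely via new origins
            o, c_t = k_next, 0
        if non_carriers.size == 0:
            c_t, o = k_next, 0

        parent_a = np.empty(n_next, dtype=np.int64)
        if c_t > 0:
            parent_a[:c_t] = rng.choice(carriers, size=c_t, replace=True)
        n_non = n_next - c_t
        if n_non > 0:
            pool = non_carriers if non_carriers.size else carriers
            parent_a[c_t:] = rng.choice(pool, size=n_non, replace=True)
        parent_b = rng.integers(0, n_prev, size=n_next)

        store.grow(0)
        Hn = store.H[nxt, :n_next, :ncols]
        Hn[:] = Hc[parent_a]
        new_fid = fid[parent_a].copy()
        new_fid[c_t:] = 0

        # crossovers: swap the columns whose segment parity differs from the
        # selected site's segment, so the selected copy stays with parent A
        n_cross = rng.poisson(rec_rate * length, size=n_next)
        for child in np.flatnonzero(n_cross > 0):
            bp = np.sort(rng.uniform(0.0, length, size=n_cross[child]))
            par = np.searchsorted(bp, store.pos[:ncols]) & 1
            par_sel = np.searchsorted(bp, sel_pos) & 1
            mask = par != par_sel
            Hn[child, mask] = Hc[parent_b[child], mask]

        # recurrent beneficial origins among the non-carrier children
        if o > 0:
            chosen = c_t + rng.choice(n_non, size=o, replace=False)
            Hn[chosen, sel_col] = 1
            new_fid[chosen] = np.arange(next_fid, next_fid + o)
            next_fid += o

        # new neutral mutations: fresh singleton columns
        n_mut = rng.poisson(mut_rate * length * n_next)
        if n_mut > 0:
            store.grow(n_mut)
            Hn = store.H[nxt, :n_next, : ncols + n_mut]
            cols = np.arange(ncols, ncols + n_mut)
            store.pos[cols] = rng.uniform(0.0, length, size=n_mut)
            Hn[rng.integers(0, n_next, size=n_mut), cols] = 1
            store.n_cols = ncols + n_mut

        store.cur = nxt
        store.n_rows = n_next
        fid[:n_next] = new_fid

        # prune lost/fixed columns before the buffer of transient new
        # mutations dominates the per-generation copy cost
        if store.n_cols > store.base_cols + 4096 or g % 32 == 0:
            sel_col = store.prune(sel_col)

    H = store.active().copy()
    return H, store.pos[: store.n_cols].copy(), sel_col, fid[: store.n_rows].copy()
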
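"""Sweep-type classification and soft-shoulder correction.

A significant site's (iHSL, RiHS) pair is classified as neutral / hard /
soft by majority vote among its k nearest points (Euclidean distance in the
standardized plane, k = 200 by default) in a simulated reference
distribution built under a matching demographic model.

Hard sweeps also leave soft-sweep-like signatures at flanking loci (the
"soft shoulder").  The correction: sites whose surrounding SNPs are
sufficiently enriched for significant p-values become *core* SNPs; maximal
runs of core SNPs form sweep regions; each region takes the sweep type of
its leading (most significant) SNP, overwriting the per-SNP calls of its
members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceDistribution",
    "SweepRegion",
    "classify_site",
    "classify_points",
    "find_core_snps",
    "call_regions",
    "apply_region_labels",
]

LABELS = ("neutral", "hard", "soft")


@dataclass
class ReferenceDistribution:
    """Labelled (iHSL, RiHS) points from demographic-model simulations."""

    points: np.ndarray  # (k, 2) standardized (iHSL, RiHS)
    labels: np.ndarray  # (k,) strings from LABELS
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (k, 2)")
        if self.labels.shape[0] != self.points.shape[0]:
            raise ValueError("one label per point required")
        if not np.isfinite(self.points).all():
            raise ValueError("reference points must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]

    def class_counts(self) -> dict[str, int]:
        return {lab: int((self.labels == lab).sum()) for lab in np.unique(self.labels)}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points, columns=["ihsl", "rihs"])
        df["label"] = self.labels
        for key, val in self.provenance.items():
            df.attrs[key] = val
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceDistribution":
        return cls(df[["ihsl", "rihs"]].to_numpy(), df["label"].to_numpy(), dict(df.attrs))


def classify_site(
    point: tuple[float, float], ref: ReferenceDistribution, k: int = 200
) -> str:
    """Modal label among the k nearest reference points; a majority tie
    falls back to the label of the single nearest point."""
    return classify_points(np.asarray(point, dtype=float)[None, :], ref, k)[0]


def classify_points(
    points: np.ndarray, ref: ReferenceDistribution, k: int = 200
) -> np.ndarray:
    """Vectorized kNN classification of (n, 2) query points."""
    points = np.asarray(points, dtype=float)
    if len(ref) < k:
        raise ValueError(f"reference holds {len(ref)} points, need at least k={k}")
    out = np.empty(points.shape[0], dtype=object)
    d2 = (
        (points[:, None, 0] - ref.points[None, :, 0]) ** 2
        + (points[:, None, 1] - ref.points[None, :, 1]) ** 2
    )
    for i in range(points.shape[0]):
        row = d2[i]
        near = np.argpartition(row, k - 1)[:k]
        labs, counts = np.unique(ref.labels[near].astype(str), return_counts=True)
        best = counts.max()
        winners = labs[counts == best]
        if winners.size == 1:
            out[i] = winners[0]
        else:
            out[i] = str(ref.labels[np.argmin(row)])
    return out


@dataclass
class SweepRegion:
    """Contiguous genomic stretch of significant core SNPs with a single
    sweep type (taken from its leading SNP)."""

    start_index: int  # half-open site-index interval [start, end)
    end_index: int
    start_bp: float
    end_bp: float
    leading_index: int
    label: str
    core_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def find_core_snps(
    scores: pd.DataFrame,
    sig_p: float = 1e-3,
    window: int = 50,
    min_prop: float = 0.2,
    p_column: str = "p_rihsl",
) -> np.ndarray:
    """Indices (into ``scores`` rows) of significant core SNPs.

    A SNP is core iff it is itself significant and the proportion of
    significant SNPs among its ``window`` nearest neighbours on each side
    (edge-truncated) is at least ``min_prop``.
    """
    p = scores[p_column].to_numpy()
    sig = np.nan_to_num(p, nan=1.0) < sig_p
    n = sig.size
    core = []
    for i in np.flatnonzero(sig):
        lo, hi = max(0, i - window), min(n, i + window + 1)
        neigh = np.delete(sig[lo:hi], i - lo)
        if neigh.size and neigh.mean() >= min_prop:
            core.append(i)
    return np.asarray(core, dtype=int)


def call_regions(
    scores: pd.DataFrame,
    core_snps: np.ndarray,
    ref: ReferenceDistribution,
    max_gap: int = 10,
    k: int = 200,
    p_column: str = "p_rihsl",
) -> list[SweepRegion]:
    """Group core SNPs into maximal runs (gaps of up to ``max_gap`` non-core
    SNPs allowed) and label each region by kNN classification of its
    leading (smallest-p) SNP."""
    core_snps = np.sort(np.asarray(core_snps, dtype=int))
    if core_snps.size == 0:
        return []
    p = scores[p_column].to_numpy()
    pos = scores["pos_bp"].to_numpy()
    pts = scores[["ihsl", "rihs"]].to_numpy()
    regions: list[SweepRegion] = []
    breaks = np.flatnonzero(np.diff(core_snps) > max_gap + 1)
    bounds = np.concatenate(([0], breaks + 1, [core_snps.size]))
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        members = core_snps[b0:b1]
        leading = int(members[np.argmin(p[members])])
        label = classify_site((pts[leading, 0], pts[leading, 1]), ref, k)
        regions.append(
            SweepRegion(
                start_index=int(members[0]),
                end_index=int(members[-1]) + 1,
                start_bp=float(pos[members[0]]),
                end_bp=float(pos[members[-1]]),
                leading_index=leading,
                label=label,
                core_indices=members,
            )
        )
    return regions


def apply_region_labels(scores: pd.DataFrame, regions: list[SweepRegion]) -> pd.DataFrame:
    """Overwrite member SNPs' sweep labels with their region's label (the
    soft-shoulder revision); returns a copy."""
    out = scores.copy()
    labels = out["sweep_label"].to_numpy(dtype=object)
    for reg in regions:
        span = slice(reg.start_index, reg.end_index)
        called = np.isin(labels[span], ("hard", "soft"))
        labels[span] = np.where(called, reg.label, labels[span])
    out["sweep_label"] = labels
    return out
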
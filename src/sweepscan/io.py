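"""Readers and writers: phased VCF, ms-format blocks, genetic maps, score
tables, reference distributions and region calls.

Coordinate conventions: internal site indices are 0-based; physical
positions in files are 1-based bp (VCF convention); region output is
BED-style half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ReferenceDistribution, SweepRegion
from .matrix import HaplotypeMatrix

__all__ = [
    "GeneticMap",
    "read_genetic_map",
    "read_phased_vcf",
    "read_ms",
    "write_ms",
    "write_scores",
    "read_scores",
    "write_reference",
    "read_reference",
    "write_regions",
]


@dataclass
class GeneticMap:
    """Sorted (physical bp, cumulative cM) anchors for one chromosome."""

    bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        self.bp = np.asarray(self.bp, dtype=float)
        self.cm = np.asarray(self.cm, dtype=float)
        if self.bp.size == 0:
            raise ValueError("empty genetic map")
        if np.any(np.diff(self.bp) <= 0):
            raise ValueError("genetic-map physical positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("genetic-map cM must be non-decreasing")

    def interpolate(self, phys_pos: np.ndarray) -> np.ndarray:
        """Piecewise-linear interpolation; beyond the map ends, extrapolate
        with the terminal segment's recombination rate."""
        phys_pos = np.asarray(phys_pos, dtype=float)
        out = np.interp(phys_pos, self.bp, self.cm)
        if self.bp.size >= 2:
            lo_rate = (self.cm[1] - self.cm[0]) / (self.bp[1] - self.bp[0])
            hi_rate = (self.cm[-1] - self.cm[-2]) / (self.bp[-1] - self.bp[-2])
            below = phys_pos < self.bp[0]
            above = phys_pos > self.bp[-1]
            out[below] = self.cm[0] + (phys_pos[below] - self.bp[0]) * lo_rate
            out[above] = self.cm[-1] + (phys_pos[above] - self.bp[-1]) * hi_rate
        return out


def read_genetic_map(path: str | Path, chromosome: str | None = None) -> GeneticMap:
    """Read a whitespace-separated genetic map.

    Accepts either 4 columns (chrom, bp, rate, cumulative cM) or 3 columns
    (bp, rate, cumulative cM); a header line is skipped automatically.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", skip_blank_lines=True)
    if not str(df.iloc[0, df.shape[1] - 1]).replace(".", "", 1).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] >= 4:
        if chromosome is not None:
            df = df[df.iloc[:, 0].astype(str) == str(chromosome)]
        bp, cm = df.iloc[:, 1], df.iloc[:, 3]
    elif df.shape[1] == 3:
        bp, cm = df.iloc[:, 0], df.iloc[:, 2]
    else:
        raise ValueError("genetic map needs 3 or 4 columns")
    return GeneticMap(bp.astype(float).to_numpy(), cm.astype(float).to_numpy())


def constant_rate_map(phys_pos: np.ndarray, cm_per_mb: float = 1.25) -> np.ndarray:
    """Fallback genetic positions under a uniform recombination rate."""
    return np.asarray(phys_pos, dtype=float) * cm_per_mb / 1e6


def read_phased_vcf(
    path: str | Path,
    aa_field: str = "AA",
    gmap: GeneticMap | None = None,
    cm_per_mb: float = 1.25,
    on_unphased: str = "error",
) -> tuple[HaplotypeMatrix, dict]:
    """Load a phased biallelic-SNP VCF into a polarized haplotype matrix.

    The ancestral allele is taken from the INFO field ``aa_field``
    (case-insensitive match against REF or ALT); sites whose ancestral
    state matches neither are dropped and counted.  Unphased or missing
    genotypes either raise (``on_unphased='error'``) or drop the site
    (``'drop'``).  Returns (matrix, info-dict with drop counts).
    """
    from cyvcf2 import VCF

    if on_unphased not in ("error", "drop"):
        raise ValueError("on_unphased must be 'error' or 'drop'")
    vcf = VCF(str(path))
    samples = vcf.samples
    columns, positions = [], []
    info = {"dropped_unpolarized": 0, "dropped_unphased": 0, "dropped_not_biallelic": 0}
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            info["dropped_not_biallelic"] += 1
            continue
        aa = var.INFO.get(aa_field)
        aa = (aa or "").split("|")[0].strip().upper()
        if aa == var.REF.upper():
            flip = False
        elif aa == var.ALT[0].upper():
            flip = True
        else:
            info["dropped_unpolarized"] += 1
            continue
        gts = var.genotype.array()
        alleles = gts[:, :-1]
        phased = gts[:, -1]
        if np.any(alleles < 0) or not np.all(phased):
            if on_unphased == "error":
                raise ValueError(
                    f"unphased or missing genotype at {var.CHROM}:{var.POS}"
                )
            info["dropped_unphased"] += 1
            continue
        hap = alleles.reshape(-1).astype(np.uint8)
        if flip:
            hap = (1 - hap).astype(np.uint8)
        columns.append(hap)
        positions.append(var.POS)
    if not columns:
        raise ValueError("no usable sites in VCF")
    alleles = np.stack(columns, axis=1)
    phys = np.asarray(positions, dtype=float)
    gen = gmap.interpolate(phys) if gmap is not None else constant_rate_map(phys, cm_per_mb)
    labels = [f"{s}_{h}" for s in samples for h in (0, 1)]
    return HaplotypeMatrix(alleles, phys, gen, labels), info


# ---------------------------------------------------------------------------
# ms-format text blocks


def read_ms(
    path: str | Path, length: float | None = None, cm_per_mb: float = 1.25
) -> list[HaplotypeMatrix]:
    """Parse ms-format output (// blocks with segsites / positions / 0-1
    rows) into one matrix per replicate.  ``length`` rescales the unit
    positions to bp; when omitted it is read from an ``ms``-style command
    line if present, else defaults to 1e6."""
    text = Path(path).read_text().splitlines()
    if length is None:
        length = 1e6
        for tok_line in text[:2]:
            if "-r" in tok_line.split():
                toks = tok_line.split()
                try:
                    length = float(toks[toks.index("-r") + 2])
                except (IndexError, ValueError):
                    pass
    out: list[HaplotypeMatrix] = []
    i = 0
    while i < len(text):
        if not text[i].startswith("//"):
            i += 1
            continue
        i += 1
        if i >= len(text) or not text[i].startswith("segsites:"):
            raise ValueError(f"line {i + 1}: expected 'segsites:' after '//'")
        segsites = int(text[i].split()[1])
        i += 1
        if segsites == 0:
            out.append(
                HaplotypeMatrix(np.zeros((2, 0), dtype=np.uint8), np.zeros(0), np.zeros(0))
            )
            continue
        if not text[i].startswith("positions:"):
            raise ValueError(f"line {i + 1}: expected 'positions:'")
        rel = np.array([float(x) for x in text[i].split()[1:]])
        if rel.size != segsites:
            raise ValueError(f"line {i + 1}: {rel.size} positions for {segsites} segsites")
        i += 1
        rows = []
        while i < len(text) and text[i].strip() and not text[i].startswith("//"):
            row = text[i].strip()
            if not set(row) <= {"0", "1"}:
                raise ValueError(f"line {i + 1}: non-binary haplotype row")
            if len(row) != segsites:
                raise ValueError(f"line {i + 1}: row length {len(row)} != {segsites}")
            rows.append(np.frombuffer(row.encode(), dtype=np.uint8) - ord("0"))
            i += 1
        phys = rel * length
        # guard against duplicate positions from low-precision output
        phys = np.maximum.accumulate(phys + np.arange(segsites) * 1e-9)
        out.append(
            HaplotypeMatrix(np.stack(rows), phys, constant_rate_map(phys, cm_per_mb))
        )
    return out


def write_ms(
    path: str | Path,
    matrices: list[HaplotypeMatrix],
    length: float,
    sidecar: dict | None = None,
) -> None:
    """Write replicates as ms-format text; optional JSON sidecar (same stem,
    .json) carries simulation metadata (parameters, trajectory, seed)."""
    path = Path(path)
    lines = [f"ms {matrices[0].n_haplotypes if matrices else 0} {len(matrices)} "
             f"-r 0 {length:g}", "0 0 0", ""]
    for hm in matrices:
        lines.append("//")
        lines.append(f"segsites: {hm.n_sites}")
        if hm.n_sites:
            rel = hm.phys_pos / length
            lines.append("positions: " + " ".join(f"{x:.8f}" for x in rel))
            for row in hm.alleles:
                lines.append("".join("1" if a else "0" for a in row))
        lines.append("")
    path.write_text("\n".join(lines))
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, default=_jsonify, indent=1))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)


# ---------------------------------------------------------------------------
# tables


_SCORE_COLUMNS = [
    "site", "pos_bp", "pos_cm", "freq", "uihsl", "ihsl", "rihs", "rihsl",
    "p_ihsl", "p_rihsl", "sweep_label",
]


def write_scores(path: str | Path, scores: pd.DataFrame) -> None:
    cols = [c for c in _SCORE_COLUMNS if c in scores.columns]
    cols += [c for c in scores.columns if c not in cols]
    scores.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.6g")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_reference(path: str | Path, ref: ReferenceDistribution) -> None:
    df = pd.DataFrame(ref.points, columns=["ihsl", "rihs"])
    df["label"] = ref.labels
    with open(path, "w") as fh:
        for key, val in ref.provenance.items():
            fh.write(f"#{key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_reference(path: str | Path) -> ReferenceDistribution:
    prov = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            prov[key] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return ReferenceDistribution(df[["ihsl", "rihs"]].to_numpy(), df["label"].to_numpy(), prov)


def write_regions(
    path: str | Path, regions: list[SweepRegion], scores: pd.DataFrame, chrom: str = "1"
) -> None:
    """BED-style TSV: chrom, start, end, label, leading-SNP p-value."""
    p = scores["p_rihsl"].to_numpy()
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlabel\tleading_p\n")
        for reg in regions:
            fh.write(
                f"{chrom}\t{int(reg.start_bp)}\t{int(reg.end_bp) + 1}\t{reg.label}\t"
                f"{p[reg.leading_index]:.4g}\n"
            )
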
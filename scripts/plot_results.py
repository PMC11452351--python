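"""Regenerate the standard figures from saved result files.

* power curves (power vs present-day adaptive-allele frequency, one line
  per statistic) from the JSON a power study writes, and
* the (iHSL, RiHS) reference scatter with class colours from a reference
  TSV.

Usage:
    python scripts/plot_results.py power results/power_sgv.json -o power.png
    python scripts/plot_results.py reference yri_ref.tsv -o scatter.png
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_power(path: Path, out: Path) -> None:
    payload = json.loads(Path(path).read_text())
    cells = payload["cells"]
    powers = payload["cell_power"]
    fig, ax = plt.subplots(figsize=(6, 4))
    s_values = sorted({c["s"] for c in cells})
    styles = {"ihsl": "-o", "ihs": "--s", "nsl": "-.^", "h12": ":v"}
    for method, style in styles.items():
        if method not in powers:
            continue
        for s in s_values:
            xs = [sum(c["bin"]) / 2 for c in cells if c["s"] == s]
            ys = [p for c, p in zip(cells, powers[method]) if c["s"] == s]
            ax.plot(xs, ys, style, alpha=0.5 + 0.5 * (s == s_values[-1]),
                    label=f"{method} (s={s})" if s == s_values[0] else None)
    ax.set_xlabel("present-day adaptive allele frequency")
    ax.set_ylabel("power at 1% FPR")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    ax.set_title(payload.get("mode", ""))
    fig.tight_layout()
    fig.savefig(out, dpi=150)


def plot_reference(path: Path, out: Path) -> None:
    import sys

    sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
    from sweepscan import io

    ref = io.read_reference(path)
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"neutral": "0.6", "hard": "tab:blue", "soft": "tab:red"}
    for label, color in colors.items():
        sel = ref.labels == label
        ax.scatter(ref.points[sel, 1], ref.points[sel, 0], s=4, c=color,
                   label=label, alpha=0.5)
    ax.set_xlabel("RiHS (standardized)")
    ax.set_ylabel("iHSL (standardized)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out, dpi=150)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("kind", choices=["power", "reference"])
    ap.add_argument("input", type=Path)
    ap.add_argument("-o", "--out", type=Path, required=True)
    args = ap.parse_args()
    if args.kind == "power":
        plot_power(args.input, args.out)
    else:
        plot_reference(args.input, args.out)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
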
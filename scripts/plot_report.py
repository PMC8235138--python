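#!/usr/bin/env python
"""Summary figure for a simulation report: mean / variance / worst-case vs n.

Usage:  python scripts/plot_report.py report.json [-o figure.png]
"""

import argparse
import json

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("report", help="JSON report written by `minimaxkl simulate`")
    ap.add_argument("-o", "--out", default="report.png")
    args = ap.parse_args()

    with open(args.report) as fh:
        rep = json.load(fh)
    metrics = ["mean", "variance", "worst_case"]
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6), sharex=True)
    for ax, metric in zip(axes, metrics):
        for est, per_n in rep["cells"].items():
            ns = sorted(int(n) for n in per_n)
            ax.plot(ns, [per_n[str(n)][metric] for n in ns], marker="o", label=est)
        ax.set_xlabel("n")
        ax.set_ylabel(f"{metric} ({rep.get('metric', 'kl')}, bits)")
        ax.set_xscale("log")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(args.out, dpi=150)
    print(f"wrote {args.out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
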
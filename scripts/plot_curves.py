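#!/usr/bin/env python
"""Render association-field style integral-curve fans.

Draws the spatial traces of the two standard fans — X1 + c2*X2 (circular
arcs through a common point and orientation, swept in curvature) and
X3 + c4*X4 (straight transversal lines swept in frequency drift) — and
writes a two-panel PNG.

Usage:
    python scripts/plot_curves.py --out scratch/fans.png
"""

import argparse
from pathlib import Path

import numpy as np


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("scratch/fans.png"))
    parser.add_argument("--t-max", type=float, default=3.0)
    args = parser.parse_args()

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from gaborlift.bank import FeaturePoint
    from gaborlift.curves import CurveCoefficients, curve_fan

    times = np.linspace(0.0, args.t_max, 200)
    init = FeaturePoint(0.0, 0.0, 0.0, 1.0, 0.0)

    fig, axes = plt.subplots(1, 2, figsize=(10, 5))
    values = np.linspace(-1.0, 1.0, 11)
    for curve in curve_fan(init, CurveCoefficients(c1=1.0), "c2", values, times):
        axes[0].plot(curve.samples[:, 0], curve.samples[:, 1], lw=1)
    axes[0].set_title("X1 + c2 X2 fan (arcs, curvature swept)")
    for curve in curve_fan(init, CurveCoefficients(c3=1.0), "c4", values, times):
        axes[1].plot(curve.samples[:, 0], curve.samples[:, 1], lw=1)
    axes[1].set_title("X3 + c4 X4 fan (theta constant)")
    for ax in axes:
        ax.set_aspect("equal")
        ax.set_xlabel("q1 (px)")
        ax.set_ylabel("q2 (px)")
    fig.tight_layout()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(args.out, dpi=150)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
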
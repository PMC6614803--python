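"""Waterfall summaries: per-lane smear curves in sequential order."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pixulchip.errors import ValidationError
from pixulchip.gel.smear import LaneQuant, SmearCurve


@dataclass
class WaterfallData:
    """Ordered lane curves on a shared bp grid plus their statistics."""

    curves: list[SmearCurve]
    quants: list[LaneQuant]

    def __post_init__(self) -> None:
        if len(self.curves) != len(self.quants):
            raise ValidationError("curves and quants must have equal length")


def _union_grid(curves: list[SmearCurve]) -> np.ndarray:
    steps = [c.grid_step for c in curves]
    if not np.allclose(steps, steps[0], rtol=1e-9):
        raise ValidationError(f"curves have incompatible grid steps {sorted(set(steps))}")
    step = steps[0]
    lo = min(c.bp_grid[0] for c in curves)
    hi = max(c.bp_grid[-1] for c in curves)
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def build_waterfall(
    curves: list[SmearCurve],
    quants: list[LaneQuant],
    out_path: str | None = None,
) -> WaterfallData:
    """Assemble (and optionally render) a waterfall of lane curves.

    Curves on different sub-ranges of a compatible grid are resampled onto
    the union grid (zero outside their own range).  When ``out_path`` is
    given, a ridge-style figure is written with per-lane mean size and
    in-range fraction in the labels.
    """
    if not curves:
        raise ValidationError("waterfall needs at least one curve")
    if len(curves) != len(quants):
        raise ValidationError("curves and quants must have equal length")
    grid = _union_grid(curves)
    resampled = [
        SmearCurve(
            bp_grid=grid,
            density=np.interp(grid, c.bp_grid, c.density, left=0.0, right=0.0),
            lane_label=c.lane_label,
        )
        for c in curves
    ]
    data = WaterfallData(curves=resampled, quants=list(quants))
    if out_path is not None:
        _render(data, out_path)
    return data


def _render(data: WaterfallData, out_path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(data.curves)
    fig, ax = plt.subplots(figsize=(8, max(4, 0.7 * n + 2)))
    offset = 1.1
    for i, (curve, quant) in enumerate(zip(data.curves, data.quants)):
        base = (n - 1 - i) * offset
        label = curve.lane_label or f"lane {i + 1}"
        if np.isfinite(quant.mean_bp):
            label += f"  mean={quant.mean_bp:.0f} bp, frac={quant.frac_in_range:.2f}"
        ax.fill_between(curve.bp_grid, base, base + curve.density, alpha=0.6, lw=0)
        ax.plot(curve.bp_grid, base + curve.density, lw=1.0, color="k")
        ax.text(curve.bp_grid[-1], base + 0.1, " " + label, fontsize=7, va="bottom")
    ax.set_xlabel("Size (bp)")
    ax.set_yticks([])
    ax.set_ylabel("lane (first on top)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
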
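"""Migration-distance <-> fragment-size calibration.

Migration follows the empirical semi-log law ``row = a - b*log10(bp)`` for
the size range of interest (roughly 100-1500 bp on agarose).  Two models are
offered: a least-squares semi-log line, and a monotone piecewise-linear
interpolant in (row, log10 bp) for gels that deviate from one regime.
Extrapolation beyond the outermost ladder bands is limited to half of the
ladder's end gaps for both models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from pixulchip.errors import CalibrationError, ValidationError

MODELS = ("semilog_linear", "monotone_interpolation")


@dataclass
class MigrationCalibration:
    """Monotone map between migration row and fragment size (bp)."""

    model: str
    a: float  # row = a - b*log10(bp)
    b: float
    knots: tuple[tuple[float, float], ...]  # (row, bp), rows increasing
    valid_row_range: tuple[float, float]
    fit_r2: float

    def bp(self, rows: np.ndarray | float) -> np.ndarray | float:
        """Fragment size at given row(s); strictly decreasing in row."""
        rows_arr = np.asarray(rows, dtype=float)
        if self.model == "semilog_linear":
            out = 10.0 ** ((self.a - rows_arr) / self.b)
        else:
            knot_rows = np.array([r for r, _ in self.knots])
            knot_logs = np.log10([s for _, s in self.knots])
            out = 10.0 ** _interp_with_extrapolation(rows_arr, knot_rows, knot_logs)
        return float(out) if np.isscalar(rows) else out

    def row(self, bp: np.ndarray | float) -> np.ndarray | float:
        """Inverse map: expected migration row of fragment size(s)."""
        bp_arr = np.asarray(bp, dtype=float)
        if self.model == "semilog_linear":
            out = self.a - self.b * np.log10(bp_arr)
        else:
            # knot logs decrease with row; invert on the reversed axis
            knot_rows = np.array([r for r, _ in self.knots])
            knot_logs = np.log10([s for _, s in self.knots])
            out = _interp_with_extrapolation(np.log10(bp_arr), knot_logs[::-1], knot_rows[::-1])
        return float(out) if np.isscalar(bp) else out

    @property
    def bp_range(self) -> tuple[float, float]:
        """Calibrated (bp_min, bp_max) over valid_row_range."""
        lo_row, hi_row = self.valid_row_range
        return float(self.bp(hi_row)), float(self.bp(lo_row))


def _interp_with_extrapolation(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp plus linear extrapolation using the end-segment slopes."""
    y = np.interp(x, xp, fp)
    left = x < xp[0]
    if np.any(left):
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y = np.where(left, fp[0] + slope * (x - xp[0]), y)
    right = x > xp[-1]
    if np.any(right):
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y = np.where(right, fp[-1] + slope * (x - xp[-1]), y)
    return y


def fit_calibration(
    bands: Sequence[tuple[float, float]], model: str = "semilog_linear"
) -> MigrationCalibration:
    """Fit a migration calibration from (row, bp) ladder bands.

    Parameters
    ----------
    bands : sequence of (row, bp)
        Rows strictly increasing, sizes strictly decreasing; at least 3.
    model : {"semilog_linear", "monotone_interpolation"}

    Raises
    ------
    ValidationError
        Fewer than 3 bands or non-monotone input.
    CalibrationError
        Fitted slope ``b <= 0`` (sizes not decreasing with distance).
    """
    if model not in MODELS:
        raise ValidationError(f"unknown model {model!r}; expected one of {MODELS}")
    if len(bands) < 3:
        raise ValidationError(f"calibration needs >= 3 bands, got {len(bands)}")
    rows = np.array([r for r, _ in bands], dtype=float)
    sizes = np.array([s for _, s in bands], dtype=float)
    if np.any(np.diff(rows) <= 0):
        raise ValidationError(f"band rows must be strictly increasing, got {rows.tolist()}")
    if np.any(np.diff(sizes) >= 0) or np.any(sizes <= 0):
        raise ValidationError(f"band sizes must be positive and strictly decreasing, got {sizes.tolist()}")

    logs = np.log10(sizes)
    # least squares row = a - b*log10(bp)
    design = np.column_stack([np.ones_like(logs), -logs])
    coef, *_ = np.linalg.lstsq(design, rows, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    if b <= 0:
        raise CalibrationError(f"fitted migration slope b={b:.3g} <= 0; ladder not resolvable")
    pred = a - b * logs
    ss_res = float(np.sum((rows - pred) ** 2))
    ss_tot = float(np.sum((rows - rows.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot

    ext_top = 0.5 * (rows[1] - rows[0])
    ext_bot = 0.5 * (rows[-1] - rows[-2])
    valid = (float(rows[0] - ext_top), float(rows[-1] + ext_bot))

    if model == "monotone_interpolation":
        fit_r2 = 1.0  # interpolant passes through every knot
    else:
        fit_r2 = float(np.clip(r2, 0.0, 1.0))

    return MigrationCalibration(
        model=model,
        a=a,
        b=b,
        knots=tuple((float(r), float(s)) for r, s in bands),
        valid_row_range=valid,
        fit_r2=fit_r2,
    )
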
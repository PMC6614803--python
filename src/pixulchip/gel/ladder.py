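"""Ladder band detection: monotone assignment of peaks to known sizes.

A ladder lane shows K discrete bands whose migration distances follow, to a
good approximation, a straight line in (log10 size, row).  Real profiles also
contain spurious maxima (dust, specks, partial bands), so the K ladder sizes
are assigned to K of the candidate maxima by minimizing total squared
deviation from a semi-log line — a dynamic program over candidate peaks that
is deterministic and robust to outlier specks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from pixulchip.errors import CalibrationError, ValidationError
from pixulchip.gel.lanes import LaneProfile

#: minimum peak prominence, as a fraction of the profile maximum
PEAK_PROMINENCE_FRACTION = 0.02


@dataclass(frozen=True)
class LadderSpec:
    """Ordered fragment sizes of a DNA ladder, largest first."""

    sizes_bp: tuple[float, ...]
    name: str = "ladder"

    def __post_init__(self) -> None:
        sizes = tuple(float(s) for s in self.sizes_bp)
        if len(sizes) < 3:
            raise ValidationError(f"ladder needs >= 3 sizes, got {len(sizes)}")
        if any(s <= 0 for s in sizes):
            raise ValidationError("ladder sizes must be positive")
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValidationError(f"ladder sizes must be strictly decreasing, got {sizes}")
        object.__setattr__(self, "sizes_bp", sizes)

    def __len__(self) -> int:
        return len(self.sizes_bp)


def _candidate_peaks(profile: np.ndarray) -> np.ndarray:
    if profile.max() <= 0:
        return np.array([], dtype=int)
    peaks, _ = signal.find_peaks(
        profile, prominence=PEAK_PROMINENCE_FRACTION * profile.max()
    )
    return peaks


def _assignment_cost(
    rows: np.ndarray, logs: np.ndarray, i: int, j: int
) -> tuple[float, list[int]]:
    """Best monotone assignment with size[0] -> candidate i, size[-1] -> candidate j.

    Intermediate sizes are matched to strictly increasing candidate rows in
    (i, j), minimizing summed squared deviation from the line through the two
    anchor candidates in (log10 size, row) space.
    """
    k = len(logs)
    pred = rows[i] + (rows[j] - rows[i]) * (logs[0] - logs) / (logs[0] - logs[-1])
    if k == 2:
        return 0.0, [i, j]
    inner = list(range(i + 1, j))
    m = len(inner)
    need = k - 2
    if m < need:
        return np.inf, []
    # dp[s][c]: min cost assigning intermediate sizes 0..s to candidates with
    # the s-th size on inner[c]; candidates strictly increasing.
    dev = np.array([[(rows[c] - pred[s + 1]) ** 2 for c in inner] for s in range(need)])
    dp = np.full((need, m), np.inf)
    back = np.zeros((need, m), dtype=int)
    dp[0, :] = dev[0, :]
    for s in range(1, need):
        best = np.inf
        best_c = -1
        for c in range(s, m):
            if dp[s - 1, c - 1] < best:  # strict < keeps the leftmost on ties
                best = dp[s - 1, c - 1]
                best_c = c - 1
            dp[s, c] = best + dev[s, c]
            back[s, c] = best_c
    end = int(np.argmin(dp[need - 1, :]))
    cost = float(dp[need - 1, end])
    chosen = [0] * need
    c = end
    for s in range(need - 1, -1, -1):
        chosen[s] = inner[c]
        c = back[s, c] if s > 0 else c
    return cost, [i] + chosen + [j]


def detect_ladder_bands(
    profile: LaneProfile, ladder: LadderSpec
) -> list[tuple[int, float]]:
    """Assign ladder sizes to profile maxima; returns (row, bp) pairs.

    Rows are strictly increasing and sizes strictly decreasing in the result.

    Raises
    ------
    CalibrationError
        If fewer candidate maxima than ladder sizes are found.
    """
    rows_all = _candidate_peaks(profile.intensity_by_row)
    k = len(ladder)
    if len(rows_all) < k:
        raise CalibrationError(
            f"found only {len(rows_all)} candidate bands, ladder {ladder.name!r} needs {k}"
        )
    rows = rows_all.astype(float)
    logs = np.log10(np.asarray(ladder.sizes_bp))

    best_cost = np.inf
    best_idx: list[int] = []
    m = len(rows)
    for i in range(m - k + 1):
        for j in range(i + k - 1, m):
            cost, idx = _assignment_cost(rows, logs, i, j)
            if cost < best_cost:
                best_cost = cost
                best_idx = idx
    if not best_idx:
        raise CalibrationError("no monotone band assignment found")
    values = profile.intensity_by_row
    assigned_rows = [
        _subpixel_apex(values, int(rows_all[c])) + profile.row_offset for c in best_idx
    ]
    return list(zip(assigned_rows, ladder.sizes_bp))


def _subpixel_apex(values: np.ndarray, peak: int) -> float:
    """Refine a peak row by parabolic interpolation through its 3-point apex.

    Interpolates log-intensity when all three samples are positive (exact
    for a Gaussian band), falling back to raw intensity otherwise.
    """
    if peak <= 0 or peak >= len(values) - 1:
        return float(peak)
    y = values[peak - 1 : peak + 2].astype(float)
    if np.all(y > 0):
        y = np.log(y)
    denom = y[0] - 2.0 * y[1] + y[2]
    if denom >= 0:
        return float(peak)
    delta = 0.5 * (y[0] - y[2]) / denom
    if not -0.5 <= delta <= 0.5:
        return float(peak)
    return float(peak) + float(delta)
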
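"""Lane detection and per-lane migration profiles."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from pixulchip.errors import ValidationError
from pixulchip.gel.image import GelImage

#: half-width as a fraction of the median inter-lane gap
HALF_WIDTH_GAP_FRACTION = 0.4
#: baseline window as a fraction of image rows; must exceed the widest smear,
#: otherwise the rolling minimum follows the smear and subtracts real signal
BASELINE_WINDOW_FRACTION = 0.6


@dataclass
class LaneGeometry:
    """Lateral lane layout: centers (columns), shared half-width, ladder index.

    ``ladder_lane_index`` is 1-based, matching gel-lane numbering.
    ``low_confidence`` marks the equal-spacing fallback used when fewer
    intensity maxima than lanes were found.
    """

    lane_centers: list[int]
    lane_half_width: int
    ladder_lane_index: int
    low_confidence: bool = False

    def __post_init__(self) -> None:
        centers = list(self.lane_centers)
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValidationError(f"lane centers must be strictly increasing, got {centers}")
        if not 1 <= self.ladder_lane_index <= len(centers):
            raise ValidationError(
                f"ladder_lane_index {self.ladder_lane_index} outside 1..{len(centers)}"
            )
        if self.lane_half_width < 0:
            raise ValidationError("lane_half_width must be non-negative")
        self.lane_centers = centers

    @property
    def n_lanes(self) -> int:
        return len(self.lane_centers)

    def window(self, lane_index: int) -> tuple[int, int]:
        """Inclusive column window (lo, hi) of a 1-based lane index."""
        if not 1 <= lane_index <= self.n_lanes:
            raise ValidationError(f"lane index {lane_index} outside 1..{self.n_lanes}")
        c = self.lane_centers[lane_index - 1]
        return c - self.lane_half_width, c + self.lane_half_width


@dataclass
class LaneProfile:
    """Background-subtracted intensity summed across a lane window, by row."""

    intensity_by_row: np.ndarray
    row_offset: int = 0
    baseline: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensity_by_row = np.asarray(self.intensity_by_row, dtype=float)
        if self.intensity_by_row.ndim != 1:
            raise ValidationError("lane profile must be 1-D")
        if np.any(self.intensity_by_row < 0):
            raise ValidationError("lane profile must be non-negative after clamping")

    def __len__(self) -> int:
        return len(self.intensity_by_row)


def detect_lanes(img: GelImage, n_lanes: int, ladder_lane: int) -> LaneGeometry:
    """Locate lane centers from the smoothed column-sum projection.

    The ``n_lanes`` highest-prominence local maxima become lane centers
    (ties broken toward the leftmost column).  When fewer maxima exist the
    layout falls back to equal spacing across the occupied span and the
    geometry is flagged ``low_confidence``.
    """
    if n_lanes < 1:
        raise ValidationError(f"n_lanes must be >= 1, got {n_lanes}")
    if not 1 <= ladder_lane <= n_lanes:
        raise ValidationError(f"ladder_lane {ladder_lane} outside 1..{n_lanes}")
    n_cols = img.n_cols
    if n_lanes > n_cols / 4:
        raise ValidationError(f"{n_lanes} lanes exceed image width {n_cols} / 4")

    projection = img.pixels.sum(axis=0)
    sigma = max(1.0, n_cols / (8.0 * n_lanes))
    smooth = ndimage.gaussian_filter1d(projection, sigma=sigma, mode="nearest")

    peaks, _ = signal.find_peaks(smooth)
    low_confidence = False
    if len(peaks) >= n_lanes and smooth.max() > 0:
        prominences = signal.peak_prominences(smooth, peaks)[0]
        # stable: highest prominence first, leftmost column breaks ties
        order = sorted(range(len(peaks)), key=lambda i: (-prominences[i], peaks[i]))
        centers = sorted(int(peaks[i]) for i in order[:n_lanes])
    else:
        low_confidence = True
        if smooth.max() > 0:
            occupied = np.flatnonzero(smooth > 0.05 * smooth.max())
            lo, hi = int(occupied[0]), int(occupied[-1])
        else:
            lo, hi = 0, n_cols - 1
        span = hi - lo + 1
        centers = [int(lo + (i + 0.5) * span / n_lanes) for i in range(n_lanes)]
    # equal-spacing fallback can collide on narrow spans; force monotonicity
    for i in range(1, len(centers)):
        if centers[i] <= centers[i - 1]:
            centers[i] = centers[i - 1] + 1

    if len(centers) > 1:
        half_width = int(np.floor(np.median(np.diff(centers)) * HALF_WIDTH_GAP_FRACTION))
    else:
        half_width = max(1, n_cols // 8)
    if not low_confidence and smooth.max() > 0:
        # tighten to the lanes' own widths so empty gutter columns do not
        # add noise to the profiles; FWHM of the smoothed projection peaks
        widths = signal.peak_widths(smooth, np.asarray(centers), rel_height=0.5)[0]
        fwhm_half = int(np.ceil(0.5 * np.median(widths)))
        if fwhm_half >= 2:
            half_width = min(half_width, fwhm_half)
    # shrink so every window fits inside the image
    half_width = min(half_width, centers[0], n_cols - 1 - centers[-1])
    half_width = max(half_width, 0)

    return LaneGeometry(
        lane_centers=centers,
        lane_half_width=half_width,
        ladder_lane_index=ladder_lane,
        low_confidence=low_confidence,
    )


def _rolling_min_baseline(raw: np.ndarray, window: int) -> np.ndarray:
    """Morphological-opening baseline: rolling minimum then rolling maximum.

    Exact on linear background ramps and removes any feature narrower than
    ``window``; clipped so it never exceeds the data.
    """
    eroded = ndimage.minimum_filter1d(raw, size=window, mode="nearest")
    opened = ndimage.maximum_filter1d(eroded, size=window, mode="nearest")
    return np.minimum(opened, raw)


def _robust_poly_baseline(raw: np.ndarray, degree: int = 1, max_iter: int = 30) -> np.ndarray:
    """Iteratively reweighted polynomial baseline.

    Rows well above the current fit are excluded and the polynomial refit
    until the selection stabilizes: only background rows remain, so smears of
    any width sit on top of — never inside — the baseline.  Exact for a
    noiseless polynomial background of the given degree.
    """
    n = len(raw)
    x = np.linspace(-1.0, 1.0, n)
    mask = np.ones(n, dtype=bool)
    fit = np.zeros(n)
    for _ in range(max_iter):
        coefs = np.polynomial.polynomial.polyfit(x[mask], raw[mask], degree)
        fit = np.polynomial.polynomial.polyval(x, coefs)
        resid = raw - fit
        neg = resid[resid <= 0]
        sigma = float(neg.std()) if neg.size >= 5 else float(resid.std())
        tol = 2.5 * sigma + 1e-12 * max(1.0, float(np.abs(raw).max()))
        new_mask = resid < tol
        if new_mask.sum() < max(degree + 2, n // 20):
            break
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
    return np.minimum(fit, raw)


def _noise_sigma(values: np.ndarray) -> float:
    """Robust per-row noise scale from first differences (MAD estimator)."""
    diffs = np.diff(values)
    mad = np.median(np.abs(diffs - np.median(diffs)))
    return float(mad / (0.67448975 * np.sqrt(2.0)))


def extract_profile(
    img: GelImage,
    geom: LaneGeometry,
    lane_index: int,
    denoise: bool = True,
) -> LaneProfile:
    """Sum intensities across one lane window and subtract the baseline.

    The baseline is a robust low-order polynomial fit to the background rows
    (iteratively excluding rows above the fit), which tracks smooth camera /
    staining gradients without cutting into smears of any width.  Camera
    noise leaves a small positive pedestal after clamping; rows whose
    smoothed signal is indistinguishable from that noise (< 2.5 robust
    sigma) are zeroed, so background regions contribute nothing while
    in-signal values stay untouched.  Residual negatives are clamped to zero.
    """
    lo, hi = geom.window(lane_index)
    lo = max(lo, 0)
    hi = min(hi, img.n_cols - 1)
    raw = img.pixels[:, lo : hi + 1].sum(axis=1)
    baseline = _robust_poly_baseline(raw)
    corrected = np.clip(raw - baseline, 0.0, None)
    if denoise:
        sigma = _noise_sigma(corrected)
        if sigma > 0:
            smooth = ndimage.gaussian_filter1d(corrected, sigma=3.0, mode="nearest")
            support = smooth > 2.5 * sigma
            # generous margin so faint smear tails are not shaved off
            margin = max(5, int(round(0.04 * img.n_rows)))
            support = ndimage.binary_dilation(support, iterations=margin)
            corrected = np.where(support, corrected, 0.0)
    return LaneProfile(intensity_by_row=corrected, row_offset=0, baseline=baseline)
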
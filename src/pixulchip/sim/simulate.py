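"""Render synthetic gel images with exact per-lane ground truth.

Rendering model
---------------
Fragment mass is mapped to rows by the semi-log law ``d = a - b*log10(bp)``:
the mass landing in row ``r`` is the mixture CDF difference between the sizes
at the row's edges (exact, no sampling).  The per-row mass is convolved with
a Gaussian point-spread along the migration axis, spread uniformly across the
lane's column window and scaled by ``exposure``.  The ladder is rendered as
discrete bands at its mapped rows.  A linear vertical background gradient and
additive Gaussian pixel noise complete the image; intensities are clipped to
``[0, 1]``.

Ground truth is computed by quadrature from the input distributions over the
calibrated size range under the selected re-indexing convention, never from
the rendered pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from pixulchip.errors import ConfigurationError, ValidationError
from pixulchip.gel.image import GelImage
from pixulchip.gel.ladder import LadderSpec
from pixulchip.sim.distributions import CONVENTIONS, FragmentDistribution, true_stats


@dataclass
class GelSimConfig:
    """Physics and layout of one synthetic gel."""

    a: float = 1080.0  # row = a - b*log10(bp)
    b: float = 320.0
    psf_sigma: float = 2.0
    background: tuple[float, float] = (0.05, 0.0001)  # base, per-row gradient
    noise_sigma: float = 0.01  # fraction of full-scale intensity
    image_shape: tuple[int, int] = (480, 560)
    lane_centers: tuple[int, ...] = tuple(30 + 42 * i for i in range(13))
    lane_half_width: int = 14
    ladder_lane_index: int = 1  # 1-based
    exposure: float = 0.5  # per-lane peak pixel intensity target
    seed: int = 0
    range_lo: float = 200.0
    range_hi: float = 600.0
    convention: str = "no_jacobian"

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValidationError("migration slope b must be positive")
        if self.psf_sigma <= 0:
            raise ValidationError("psf_sigma must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")
        rows, cols = self.image_shape
        for c in self.lane_centers:
            if c - self.lane_half_width < 0 or c + self.lane_half_width >= cols:
                raise ValidationError(f"lane at column {c} does not fit in width {cols}")
        if not 1 <= self.ladder_lane_index <= len(self.lane_centers):
            raise ValidationError("ladder_lane_index outside lane layout")
        if self.convention not in CONVENTIONS:
            raise ValidationError(f"unknown convention {self.convention!r}")

    @property
    def n_lanes(self) -> int:
        return len(self.lane_centers)

    def row_of(self, bp: float | np.ndarray) -> float | np.ndarray:
        return self.a - self.b * np.log10(bp)

    def bp_of(self, row: float | np.ndarray) -> float | np.ndarray:
        return 10.0 ** ((self.a - np.asarray(row, dtype=float)) / self.b)


@dataclass
class SimTruth:
    """Analytic ground truth accompanying a simulated gel."""

    lane_mean_bp: list[float]
    lane_frac_in_range: list[float]
    ladder_band_rows: list[float]
    range_lo: float
    range_hi: float
    bp_domain: tuple[float, float]
    convention: str
    lane_components: list[list[tuple[float, float, float]]] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "lane_mean_bp": self.lane_mean_bp,
            "lane_frac_in_range": self.lane_frac_in_range,
            "ladder_band_rows": self.ladder_band_rows,
            "range_lo": self.range_lo,
            "range_hi": self.range_hi,
            "bp_domain": list(self.bp_domain),
            "convention": self.convention,
            "lane_components": [[list(c) for c in lane] for lane in self.lane_components],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _calibrated_domain(cfg: GelSimConfig, ladder: LadderSpec) -> tuple[float, float]:
    """bp range reachable by the analysis pipeline: ladder rows extended by
    half the end gaps, clipped to the image."""
    rows = np.sort(np.asarray(cfg.row_of(np.asarray(ladder.sizes_bp))))
    lo_row = rows[0] - 0.5 * (rows[1] - rows[0])
    hi_row = rows[-1] + 0.5 * (rows[-1] - rows[-2])
    lo_row = max(lo_row, 0.0)
    hi_row = min(hi_row, cfg.image_shape[0] - 1.0)
    return float(cfg.bp_of(hi_row)), float(cfg.bp_of(lo_row))


def _lane_row_signal(dist: FragmentDistribution, cfg: GelSimConfig) -> np.ndarray:
    rows = np.arange(cfg.image_shape[0] + 1, dtype=float)
    sizes_at_edges = np.asarray(cfg.bp_of(rows))
    cdf = np.asarray(dist.cdf(sizes_at_edges))
    return np.clip(cdf[:-1] - cdf[1:], 0.0, None)  # mass per row, exact


def _ladder_row_signal(ladder: LadderSpec, cfg: GelSimConfig) -> tuple[np.ndarray, list[float]]:
    n_rows = cfg.image_shape[0]
    signal = np.zeros(n_rows)
    band_rows: list[float] = []
    per_band = 1.0 / len(ladder)
    for size in ladder.sizes_bp:
        r = float(cfg.row_of(size))
        if not 0.0 <= r <= n_rows - 1:
            raise ConfigurationError(
                f"ladder band {size:g} bp maps to row {r:.1f}, outside 0..{n_rows - 1}"
            )
        band_rows.append(r)
        lo = int(np.floor(r))
        frac = r - lo
        signal[lo] += per_band * (1.0 - frac)
        if lo + 1 < n_rows:
            signal[lo + 1] += per_band * frac
    return signal, band_rows


def simulate_gel(
    dists: Sequence[FragmentDistribution],
    ladder: LadderSpec,
    cfg: GelSimConfig,
) -> tuple[GelImage, SimTruth]:
    """Render a gel image and its analytic truth.

    One distribution per sample lane is required (``cfg.n_lanes - 1``); the
    ladder occupies ``cfg.ladder_lane_index``.  The same seed yields a
    bit-identical image; different seeds change only the noise layer.
    """
    n_samples = cfg.n_lanes - 1
    if len(dists) != n_samples:
        raise ConfigurationError(
            f"need {n_samples} sample distributions for {cfg.n_lanes} lanes, got {len(dists)}"
        )
    n_rows, n_cols = cfg.image_shape
    image = np.zeros((n_rows, n_cols))

    lane_signals: list[np.ndarray] = []
    ladder_rows: list[float] = []
    dist_iter = iter(dists)
    for lane_no, center in enumerate(cfg.lane_centers, start=1):
        if lane_no == cfg.ladder_lane_index:
            row_signal, ladder_rows = _ladder_row_signal(ladder, cfg)
        else:
            row_signal = _lane_row_signal(next(dist_iter), cfg)
        row_signal = ndimage.gaussian_filter1d(row_signal, sigma=cfg.psf_sigma, mode="constant")
        lane_signals.append(row_signal)

    for row_signal, center in zip(lane_signals, cfg.lane_centers):
        # per-lane gain: every lane is loaded to reach the target peak
        peak = row_signal.max()
        gain = cfg.exposure / peak if peak > 0 else 0.0
        lo, hi = center - cfg.lane_half_width, center + cfg.lane_half_width
        image[:, lo : hi + 1] += gain * row_signal[:, None]

    base, gradient = cfg.background
    image += base + gradient * np.arange(n_rows)[:, None]

    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        image = image + rng.normal(0.0, cfg.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    domain = _calibrated_domain(cfg, ladder)
    means, fracs = [], []
    for dist in dists:
        m, f = true_stats(
            dist, cfg.range_lo, cfg.range_hi, convention=cfg.convention, domain=domain
        )
        means.append(m)
        fracs.append(f)
    truth = SimTruth(
        lane_mean_bp=means,
        lane_frac_in_range=fracs,
        ladder_band_rows=ladder_rows,
        range_lo=cfg.range_lo,
        range_hi=cfg.range_hi,
        bp_domain=domain,
        convention=cfg.convention,
        lane_components=[list(d.components) for d in dists],
    )
    gel = GelImage(pixels=image, orientation="wells_top", bit_depth=16, source_path="<simulated>")
    return gel, truth


def load_sim_config(path: str) -> tuple[list[FragmentDistribution], LadderSpec, GelSimConfig]:
    """Parse the JSON mirror of (distributions, ladder, GelSimConfig)."""
    with open(path) as fh:
        payload = json.load(fh)
    try:
        ladder = LadderSpec(
            sizes_bp=tuple(payload["ladder"]["sizes_bp"]),
            name=payload["ladder"].get("name", "ladder"),
        )
        dists = [
            FragmentDistribution(tuple(tuple(c) for c in lane["components"]))
            for lane in payload["lanes"]
        ]
        cfg_fields = {k: v for k, v in payload.items() if k not in ("ladder", "lanes")}
        for key in ("background", "image_shape", "lane_centers"):
            if key in cfg_fields:
                cfg_fields[key] = tuple(cfg_fields[key])
        cfg = GelSimConfig(**cfg_fields)
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"invalid simulator config {path!r}: {exc}") from exc
    return dists, ladder, cfg
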
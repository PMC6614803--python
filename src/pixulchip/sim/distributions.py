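"""Fragment-size distributions (log-normal mixtures) and their exact statistics.

The mixture density is interpreted as DNA *mass* per unit size — an
ethidium-bromide-like staining model where signal tracks mass, not molar
count.  ``true_stats`` integrates the density under the same row->bp
re-indexing convention the analysis pipeline uses, so it serves as the
quadrature oracle for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from pixulchip.errors import ValidationError

LN10 = np.log(10.0)

CONVENTIONS = ("no_jacobian", "jacobian")


@dataclass(frozen=True)
class FragmentDistribution:
    """Mixture of log-normal components ``(weight, median_bp, sigma_log10)``."""

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        comps = tuple((float(w), float(m), float(s)) for w, m, s in self.components)
        if not comps:
            raise ValidationError("distribution needs >= 1 component")
        weights = np.array([w for w, _, _ in comps])
        if np.any(weights <= 0):
            raise ValidationError("component weights must be positive")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValidationError(f"weights must sum to 1, got {weights.sum():.12f}")
        if any(m <= 0 for _, m, _ in comps):
            raise ValidationError("component medians must be positive")
        if any(s <= 0 for _, _, s in comps):
            raise ValidationError("component sigmas must be positive")
        object.__setattr__(self, "components", comps)

    @classmethod
    def single(cls, median_bp: float, sigma_log10: float) -> "FragmentDistribution":
        return cls(((1.0, median_bp, sigma_log10),))

    def _frozen(self):
        return [
            (w, stats.lognorm(s=sig * LN10, scale=med))
            for w, med, sig in self.components
        ]

    def pdf(self, size_bp: np.ndarray | float) -> np.ndarray | float:
        """Mass density per bp at the given size(s)."""
        x = np.asarray(size_bp, dtype=float)
        out = sum(w * d.pdf(x) for w, d in self._frozen())
        return float(out) if np.isscalar(size_bp) else out

    def cdf(self, size_bp: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(size_bp, dtype=float)
        out = sum(w * d.cdf(x) for w, d in self._frozen())
        return float(out) if np.isscalar(size_bp) else out

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` fragment sizes (mass-weighted mixture draw)."""
        weights = np.array([w for w, _, _ in self.components])
        which = rng.choice(len(weights), size=n, p=weights)
        sizes = np.empty(n)
        for k, (_, med, sig) in enumerate(self.components):
            m = which == k
            sizes[m] = med * 10.0 ** rng.normal(0.0, sig, size=int(m.sum()))
        return sizes

    def support(self, tail: float = 1e-9) -> tuple[float, float]:
        """Interval containing all but ``tail`` probability of every component."""
        lows, highs = [], []
        for _, d in self._frozen():
            lows.append(d.ppf(tail))
            highs.append(d.ppf(1.0 - tail))
        return float(min(lows)), float(max(highs))


def true_stats(
    dist: FragmentDistribution,
    range_lo: float,
    range_hi: float,
    convention: str = "no_jacobian",
    domain: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Exact (mean_bp, frac_in_range) of a distribution by adaptive quadrature.

    Under the ``no_jacobian`` convention the lane curve seen by the pipeline
    is proportional to ``pdf(s) * s`` (the row-space signal re-indexed by
    size without a density correction), so statistics are taken against that
    weight.  Under ``jacobian`` the weight is ``pdf(s)`` itself.  ``domain``
    restricts integration to the calibrated size range; default is the
    distribution's full (numerical) support.
    """
    if range_lo >= range_hi:
        raise ValidationError(f"range_lo {range_lo} must be < range_hi {range_hi}")
    if convention not in CONVENTIONS:
        raise ValidationError(f"unknown convention {convention!r}")
    lo, hi = domain if domain is not None else dist.support()
    if lo >= hi:
        raise ValidationError(f"empty integration domain ({lo}, {hi})")

    if convention == "no_jacobian":
        weight = lambda s: dist.pdf(s) * s  # noqa: E731
    else:
        weight = dist.pdf

    medians = [m for _, m, _ in dist.components if lo < m < hi]

    def _quad(f, a, b):
        if b <= a:
            return 0.0
        pts = [m for m in medians if a < m < b]
        val, _ = integrate.quad(f, a, b, points=pts or None, limit=200, epsrel=1e-9)
        return val

    z = _quad(weight, lo, hi)
    if z <= 0:
        raise ValidationError("distribution has no mass inside the domain")
    m1 = _quad(lambda s: s * weight(s), lo, hi)
    fr = _quad(weight, max(lo, range_lo), min(hi, range_hi))
    return m1 / z, fr / z
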
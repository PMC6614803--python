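"""ChIP-qPCR quantification: standard curves, fraction of input, significance.

Workflow: fit one standard curve per primer pair from a genomic-DNA dilution
series (Ct vs log10 concentration, ordinary least squares), convert each
sample's *average* Ct to a DNA quantity through that curve, and express
ChIP signal as fraction of input (input rescaled to undiluted equivalents).
Pairwise group differences use a two-tailed Student's t-test (pooled
variance by default, Welch behind a flag) encoded as circle marks:
large for p < 0.01, small for 0.01 <= p < 0.05, none otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pixulchip.errors import ValidationError

R2_WARN_THRESHOLD = 0.98

MARK_NONE = "none"
MARK_SMALL = "small_circle"
MARK_LARGE = "large_circle"


@dataclass(frozen=True)
class DilutionPoint:
    """One point of a standard-curve dilution series."""

    concentration: float
    ct: float

    def __post_init__(self) -> None:
        if not (self.concentration > 0):
            raise ValidationError(f"concentration must be > 0, got {self.concentration}")
        if not (np.isfinite(self.ct) and self.ct > 0):
            raise ValidationError(f"ct must be finite and > 0, got {self.ct}")


@dataclass(frozen=True)
class StandardCurve:
    """Ct = m * log10(concentration) + b, with fit quality and efficiency."""

    slope: float
    intercept: float
    r2: float
    efficiency: float
    primer_pair: str = ""
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ChIPMeasurement:
    """Replicate Ct values for one sample/target/antibody well set."""

    sample_id: str
    target: str
    ct_replicates: tuple[float, ...]
    antibody: str = ""
    is_input: bool = False
    input_dilution: float = 1.0

    def __post_init__(self) -> None:
        cts = tuple(float(c) for c in self.ct_replicates)
        if not cts:
            raise ValidationError("measurement needs >= 1 Ct replicate")
        if not all(np.isfinite(c) for c in cts):
            raise ValidationError(f"non-finite Ct in {self.sample_id}/{self.target}")
        if self.input_dilution < 1:
            raise ValidationError(f"input_dilution must be >= 1, got {self.input_dilution}")
        object.__setattr__(self, "ct_replicates", cts)

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_replicates))


@dataclass(frozen=True)
class FractionOfInput:
    value: float
    sample_id: str
    target: str
    antibody: str = ""
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class SignificanceMark:
    p_value: float
    mark: str


def fit_standard_curve(points: Sequence[DilutionPoint], primer_pair: str = "") -> StandardCurve:
    """Least-squares fit of Ct on log10(concentration) for one primer pair.

    Amplification efficiency is ``E = 10^(-1/m) - 1`` (E = 1 for perfect
    doubling).  A warning flag is set when the slope is non-negative or
    r-squared falls below 0.98; fitting still succeeds so the caller can
    inspect the curve.
    """
    if len(points) < 3:
        raise ValidationError(f"standard curve needs >= 3 points, got {len(points)}")
    conc = np.array([p.concentration for p in points])
    ct = np.array([p.ct for p in points])
    logc = np.log10(conc)
    if np.unique(logc).size < 2:
        raise ValidationError("all dilution concentrations are equal; cannot fit a slope")
    fit = stats.linregress(logc, ct)
    m, b = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue**2)
    efficiency = float(10.0 ** (-1.0 / m) - 1.0) if m != 0 else float("inf")
    flags = []
    if m >= 0:
        flags.append("nonnegative_slope")
    if r2 < R2_WARN_THRESHOLD:
        flags.append("low_r2")
    return StandardCurve(
        slope=m,
        intercept=b,
        r2=r2,
        efficiency=efficiency,
        primer_pair=primer_pair,
        flags=tuple(flags),
    )


def ct_to_quantity(ct: float | Sequence[float], curve: StandardCurve) -> float:
    """Convert a Ct (or replicate list, averaged first) to a DNA quantity."""
    if curve.slope >= 0:
        raise ValidationError(
            f"standard curve {curve.primer_pair!r} has slope {curve.slope:.3g} >= 0; "
            "cannot convert Ct to quantity"
        )
    ct_value = float(np.mean(np.asarray(ct, dtype=float)))
    return float(10.0 ** ((ct_value - curve.intercept) / curve.slope))


def fraction_of_input(
    ip: ChIPMeasurement, input_ref: ChIPMeasurement, curve: StandardCurve
) -> FractionOfInput:
    """ChIP quantity divided by the input quantity rescaled to undiluted.

    ``value = Q(ip) / (Q(input) * input_dilution)``: the measured input is
    multiplied by its dilution factor so the denominator represents the
    undiluted chromatin equivalent.
    """
    if not input_ref.is_input:
        raise ValidationError(f"reference measurement {input_ref.sample_id!r} is not an input")
    if ip.target != input_ref.target:
        raise ValidationError(
            f"target mismatch: {ip.target!r} (ip) vs {input_ref.target!r} (input)"
        )
    q_ip = ct_to_quantity(ip.ct_replicates, curve)
    q_in = ct_to_quantity(input_ref.ct_replicates, curve) * input_ref.input_dilution
    if q_in <= 0:
        return FractionOfInput(
            value=float("nan"),
            sample_id=ip.sample_id,
            target=ip.target,
            antibody=ip.antibody,
            flags=("undefined_input",),
        )
    return FractionOfInput(
        value=q_ip / q_in, sample_id=ip.sample_id, target=ip.target, antibody=ip.antibody
    )


def mark_from_p(p: float) -> str:
    if p < 0.01:
        return MARK_LARGE
    if p < 0.05:
        return MARK_SMALL
    return MARK_NONE


def pairwise_significance(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = False
) -> SignificanceMark:
    """Two-tailed Student's t-test between two groups, encoded as a circle mark.

    Pooled-variance Student's t by default; ``welch=True`` switches to the
    unequal-variance form.  Two constant groups give p = 1 when equal and
    p = 0 when different.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 values for a t-test")
    if a.std() == 0 and b.std() == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)
    return SignificanceMark(p_value=p, mark=mark_from_p(p))


# ---------------------------------------------------------------------------
# tabular I/O and plate-level driver


def read_dilution_series(path: str) -> dict[str, list[DilutionPoint]]:
    """Read a standards table (primer_pair, concentration, ct) -> series per primer."""
    df = _read_table(path, required={"primer_pair", "concentration", "ct"})
    series: dict[str, list[DilutionPoint]] = {}
    for _, row in df.iterrows():
        series.setdefault(str(row["primer_pair"]), []).append(
            DilutionPoint(concentration=float(row["concentration"]), ct=float(row["ct"]))
        )
    return series


def read_plate_table(path: str) -> list[ChIPMeasurement]:
    """Read a plate table with columns sample_id, target, antibody, is_input,
    input_dilution and ct_1..ct_k (missing replicates left blank)."""
    df = _read_table(path, required={"sample_id", "target"})
    ct_cols = sorted(
        (c for c in df.columns if c.startswith("ct_")), key=lambda c: int(c.split("_")[1])
    )
    if not ct_cols:
        raise ValidationError(f"plate table {path!r} has no ct_1..ct_k columns")
    out = []
    for _, row in df.iterrows():
        cts = tuple(float(row[c]) for c in ct_cols if pd.notna(row[c]))
        out.append(
            ChIPMeasurement(
                sample_id=str(row["sample_id"]),
                target=str(row["target"]),
                antibody=str(row.get("antibody", "") or ""),
                is_input=_as_bool(row.get("is_input", False)),
                input_dilution=float(row.get("input_dilution", 1.0) or 1.0),
                ct_replicates=cts,
            )
        )
    return out


def quantify_plate(
    measurements: Sequence[ChIPMeasurement], curves: dict[str, StandardCurve]
) -> list[FractionOfInput]:
    """Compute fraction of input for every non-input measurement.

    The input reference for a ChIP well is the input measurement sharing its
    sample_id and target; when none exists, a target's sole input (or a
    plate-wide ``*`` input) serves the whole plate.
    """
    inputs: dict[tuple[str, str], ChIPMeasurement] = {}
    by_target: dict[str, list[ChIPMeasurement]] = {}
    for m in measurements:
        if m.is_input:
            inputs[(m.sample_id, m.target)] = m
            by_target.setdefault(m.target, []).append(m)
    results = []
    for m in measurements:
        if m.is_input:
            continue
        if m.target not in curves:
            raise ValidationError(f"no standard curve for target/primer {m.target!r}")
        ref = inputs.get((m.sample_id, m.target)) or inputs.get(("*", m.target))
        if ref is None and len(by_target.get(m.target, [])) == 1:
            ref = by_target[m.target][0]
        if ref is None:
            raise ValidationError(f"no input measurement for {m.sample_id!r}/{m.target!r}")
        results.append(fraction_of_input(m, ref, curves[m.target]))
    return results


def _read_table(path: str, required: set[str]) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"table {path!r} missing columns {sorted(missing)}")
    return df


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes", "y")
    return bool(value) and not pd.isna(value)
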
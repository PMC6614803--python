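"""Peak filtering, interval overlap, TSS mark assignment, expression strata.

Coordinates are 0-based half-open (BED convention) throughout.  Overlap means
sharing at least one base pair; there is no reciprocal-fraction requirement.
Filter thresholds are strict inequalities: a peak is kept iff its q-value is
strictly below the rule's cutoff AND its fold enrichment strictly above.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import math

from pixulchip.errors import ConfigurationError, FormatError, ValidationError


@dataclass(frozen=True)
class Peak:
    """Half-open genomic interval with broadPeak scores."""

    chrom: str
    start: int
    end: int
    fold_enrichment: float
    neg_log10_q: float
    mark: str = ""
    name: str = "."
    score: int = 0
    strand: str = "."
    neg_log10_p: float = -1.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if not (math.isfinite(self.fold_enrichment) and math.isfinite(self.neg_log10_q)):
            raise ValidationError(f"non-finite scores on {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True)
class FilterRule:
    """Keep peaks with q-value < q_max and fold enrichment > fold_min.

    ``mark_set=None`` makes this the default rule for all marks not claimed
    by another rule.
    """

    q_max: float
    fold_min: float
    mark_set: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.q_max < 1:
            raise ValidationError(f"q_max must be in (0, 1), got {self.q_max}")
        if self.fold_min <= 0:
            raise ValidationError(f"fold_min must be > 0, got {self.fold_min}")
        if self.mark_set is not None:
            object.__setattr__(self, "mark_set", frozenset(self.mark_set))

    @property
    def neg_log10_q_min(self) -> float:
        return -math.log10(self.q_max)

    def keeps(self, peak: Peak) -> bool:
        return peak.neg_log10_q > self.neg_log10_q_min and peak.fold_enrichment > self.fold_min


#: published filtering: permissive for the broad marks, stringent otherwise
RELAXED_MARKS = frozenset({"H3K4m1", "H3K27m3", "H3K27Ac"})
DEFAULT_FILTER_RULES = (
    FilterRule(q_max=1e-3, fold_min=2.0, mark_set=RELAXED_MARKS),
    FilterRule(q_max=1e-10, fold_min=5.0, mark_set=None),
)


@dataclass(frozen=True)
class TSSRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValidationError(f"TSS must be >= 0, got {self.tss} for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class ExpressionStrata:
    """Genes split by mark presence, with per-stratum expression summaries."""

    with_mark: list[tuple[str, float]]
    without_mark: list[tuple[str, float]]
    summary: dict[str, dict[str, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# broadPeak I/O (BED6+3: chrom start end name score strand signal pValue qValue)


def read_broadpeak(path: str, mark: str = "") -> list[Peak]:
    """Parse a broadPeak file; malformed lines raise with their line number."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 9:
                raise FormatError(
                    f"{path}:{lineno}: broadPeak needs >= 9 columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                fold = float(fields[6])
                neg_p = float(fields[7])
                neg_q = float(fields[8])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            try:
                peaks.append(
                    Peak(
                        chrom=fields[0],
                        start=start,
                        end=end,
                        name=fields[3],
                        score=int(float(fields[4])),
                        strand=fields[5],
                        fold_enrichment=fold,
                        neg_log10_p=neg_p,
                        neg_log10_q=neg_q,
                        mark=mark,
                    )
                )
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_broadpeak(peaks: Iterable[Peak], path: str) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        str(p.score),
                        p.strand,
                        repr(p.fold_enrichment),
                        repr(p.neg_log10_p),
                        repr(p.neg_log10_q),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# filtering


def _rule_for(mark: str, rules: Sequence[FilterRule]) -> FilterRule:
    matches = [r for r in rules if r.mark_set is not None and mark in r.mark_set]
    if len(matches) > 1:
        raise ConfigurationError(f"mark {mark!r} matches {len(matches)} rules; must be exactly one")
    if matches:
        return matches[0]
    defaults = [r for r in rules if r.mark_set is None]
    if len(defaults) > 1:
        raise ConfigurationError("more than one default ('all other marks') rule supplied")
    if defaults:
        return defaults[0]
    raise ConfigurationError(f"mark {mark!r} matches no filter rule and no default is given")


def filter_peaks(
    peaks: Sequence[Peak], rules: Sequence[FilterRule] = DEFAULT_FILTER_RULES
) -> list[Peak]:
    """Keep peaks passing their mark's rule (strict thresholds); order preserved."""
    rule_cache: dict[str, FilterRule] = {}
    kept = []
    for p in peaks:
        rule = rule_cache.get(p.mark)
        if rule is None:
            rule = _rule_for(p.mark, rules)
            rule_cache[p.mark] = rule
        if rule.keeps(p):
            kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# interval overlap (sort + merge + binary search per chromosome)


def _merged_by_chrom(intervals: Iterable[tuple[str, int, int]]) -> dict[str, tuple[list[int], list[int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts: list[int] = []
        ends: list[int] = []
        for s, e in ivs:
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (starts, ends)
    return merged


def _hits(merged: dict[str, tuple[list[int], list[int]]], chrom: str, start: int, end: int) -> bool:
    if chrom not in merged:
        return False
    starts, ends = merged[chrom]
    i = bisect_right(starts, start)
    # candidate intervals: the one starting at/before `start`, or the next one
    if i > 0 and ends[i - 1] > start:
        return True
    return i < len(starts) and starts[i] < end


@dataclass(frozen=True)
class OverlapResult:
    count_a: int
    count_overlapping: int
    percent: float  # NaN when count_a == 0
    flags: tuple[str, ...] = ()


def overlap_fraction(peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]) -> OverlapResult:
    """Count peaks in A sharing >= 1 bp with any peak in B.

    Half-open intersection; B is merged per chromosome and each A peak is
    located by binary search (merging never changes the answer).
    """
    merged = _merged_by_chrom((p.chrom, p.start, p.end) for p in peaks_b)
    count = sum(1 for p in peaks_a if _hits(merged, p.chrom, p.start, p.end))
    n = len(peaks_a)
    if n == 0:
        return OverlapResult(0, 0, float("nan"), flags=("undefined_percent",))
    return OverlapResult(n, count, 100.0 * count / n)


# ---------------------------------------------------------------------------
# TSS mark assignment and expression strata


def assign_tss_marks(
    peaks: Sequence[Peak],
    tss: Sequence[TSSRecord],
    window: int = 2000,
    include_gene_body: bool = False,
    gene_spans: dict[str, tuple[str, int, int]] | None = None,
) -> dict[str, bool]:
    """Flag each gene whose TSS window (or gene body) intersects any peak.

    The window is strand-independent: ``[tss - window, tss + window)``
    clamped at zero.  With ``include_gene_body`` the gene's span counts too;
    spans are then required for every gene.
    """
    if window <= 0:
        raise ValidationError(f"window must be > 0, got {window}")
    if include_gene_body and gene_spans is None:
        raise ConfigurationError("include_gene_body=True requires gene_spans")
    merged = _merged_by_chrom((p.chrom, p.start, p.end) for p in peaks)
    flags: dict[str, bool] = {}
    for rec in tss:
        lo = max(0, rec.tss - window)
        hi = rec.tss + window
        hit = _hits(merged, rec.chrom, lo, hi)
        if not hit and include_gene_body:
            span = gene_spans.get(rec.gene_id)
            if span is None:
                raise ConfigurationError(f"no gene span for {rec.gene_id!r}")
            hit = _hits(merged, span[0], span[1], span[2])
        flags[rec.gene_id] = hit
    return flags


def expression_strata(
    flags: dict[str, bool], expression: Sequence[tuple[str, float]]
) -> ExpressionStrata:
    """Partition genes by mark flag and summarize expression per stratum.

    Genes absent from ``flags`` are treated as without-mark.  Summaries give
    mean and median on the raw FPKM and log2(FPKM+1) scales.
    """
    if not expression:
        raise ValidationError("expression table is empty")
    with_mark: list[tuple[str, float]] = []
    without_mark: list[tuple[str, float]] = []
    for gene_id, fpkm in expression:
        fpkm = float(fpkm)
        if fpkm < 0 or not math.isfinite(fpkm):
            raise ValidationError(f"FPKM must be finite and >= 0, got {fpkm} for {gene_id}")
        (with_mark if flags.get(gene_id, False) else without_mark).append((gene_id, fpkm))

    def _summary(values: list[tuple[str, float]]) -> dict[str, float]:
        import numpy as np

        if not values:
            return {"n": 0}
        fpkm = np.array([v for _, v in values])
        log2 = np.log2(fpkm + 1.0)
        return {
            "n": len(values),
            "mean_fpkm": float(fpkm.mean()),
            "median_fpkm": float(np.median(fpkm)),
            "mean_log2": float(log2.mean()),
            "median_log2": float(np.median(log2)),
        }

    return ExpressionStrata(
        with_mark=with_mark,
        without_mark=without_mark,
        summary={"with_mark": _summary(with_mark), "without_mark": _summary(without_mark)},
    )


# ---------------------------------------------------------------------------
# annotation I/O


def read_tss_bed(path: str) -> list[TSSRecord]:
    """BED6 -> TSS records: start for + strand, end - 1 for - strand."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            tss = start_i if strand == "+" else end_i - 1
            records.append(TSSRecord(gene_id=name, chrom=chrom, tss=tss, strand=strand))
    return records


def read_gene_spans_bed(path: str) -> dict[str, tuple[str, int, int]]:
    spans: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: need chrom/start/end/name, got {len(fields)} cols")
            spans[fields[3]] = (fields[0], int(fields[1]), int(fields[2]))
    return spans
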
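"""Nucleotide composition, strand skew, and intergenic gap/overlap accounting.

AT and GC skew are the standard strand-asymmetry statistics

    AT skew = (A - T) / (A + T),    GC skew = (G - C) / (G + C)

computed from raw counts and reported to three decimals; base percentages are
reported to one decimal.  Intergenic distances follow the convention

    IGN(next, prev) = start(next) - end(prev) - 1

so touching genes score 0, a 1-bp gap scores 1, and overlapping genes score
negative.  Records are circular: the wrap-around pair (last feature, first
feature) is a real adjacency and is included in all totals.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .annotation_io import MitogenomeRecord, ValidationError

__all__ = [
    "CompositionStats",
    "AdjacencyReport",
    "base_composition",
    "skew_from_composition",
    "region_composition_table",
    "adjacency_report",
    "pcg_summary",
]

REGION_LABELS = ("full_genome", "PCGs", "tRNAs", "rRNAs", "control_region")

_REGION_BY_TYPE = {"PCG": "PCGs", "tRNA": "tRNAs", "rRNA": "rRNAs",
                   "control_region": "control_region"}


@dataclass(frozen=True)
class CompositionStats:
    """Base composition and skew of one genomic region.

    Percentages are reported to one decimal, skews to three decimals; a skew
    whose denominator is zero is NaN.
    """

    region_label: str
    size: int
    a_pct: float
    t_pct: float
    g_pct: float
    c_pct: float
    at_content: float
    gc_content: float
    at_skew: float
    gc_skew: float


def _skew(x: float, y: float) -> float:
    total = x + y
    if total == 0:
        return math.nan
    return round((x - y) / total, 3)


def base_composition(sequence: str, region_label: str = "full_genome") -> CompositionStats:
    """Composition and skew statistics of a nucleotide string.

    ``N`` bases are excluded from all denominators; the reported size is the
    full span length.  Raises on empty or all-N input.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    counts = Counter(sequence.upper())
    bad = set(counts) - set("ACGTN")
    if bad:
        raise ValidationError(f"invalid characters in sequence: {bad}")
    a, t, g, c = counts["A"], counts["T"], counts["G"], counts["C"]
    denom = a + t + g + c
    if denom == 0:
        raise ValidationError("sequence contains no unambiguous bases")
    pct = lambda n: round(100.0 * n / denom, 1)
    return CompositionStats(
        region_label=region_label,
        size=len(sequence),
        a_pct=pct(a), t_pct=pct(t), g_pct=pct(g), c_pct=pct(c),
        at_content=pct(a + t), gc_content=pct(g + c),
        at_skew=_skew(a, t), gc_skew=_skew(g, c),
    )


def skew_from_composition(a_pct: float, t_pct: float,
                          g_pct: float, c_pct: float) -> tuple[float, float]:
    """AT and GC skew from base percentages (or counts — scale cancels).

    Returns (at_skew, gc_skew) rounded to three decimals; NaN when the
    corresponding denominator is zero.
    """
    if min(a_pct, t_pct, g_pct, c_pct) < 0:
        raise ValidationError("composition values must be non-negative")
    return _skew(a_pct, t_pct), _skew(g_pct, c_pct)


def region_composition_table(record: MitogenomeRecord) -> list[CompositionStats]:
    """Per-region composition rows: full genome, PCGs, tRNAs, rRNAs, CR.

    Region rows concatenate the feature spans as they lie on the reference
    strand (no reverse complementing): the statistics describe the molecule's
    majority-strand content, the convention under which whole-molecule and
    per-region accounting add up.  Missing regions are omitted with a warning.
    """
    if record.sequence is None:
        raise ValidationError(f"record {record.id} has no sequence attached")
    rows = [base_composition(record.sequence, "full_genome")]
    for label in REGION_LABELS[1:]:
        ftype = next(k for k, v in _REGION_BY_TYPE.items() if v == label)
        spans = [record.sequence[f.start - 1:f.end]
                 for f in record.features_of_type(ftype)]
        if not spans:
            warnings.warn(f"{record.id}: no {label} features; row omitted",
                          stacklevel=2)
            continue
        rows.append(base_composition("".join(spans), label))
    return rows


def composition_frame(rows: list[CompositionStats]) -> pd.DataFrame:
    """Composition rows as a DataFrame in the conventional column order."""
    return pd.DataFrame([{
        "region": r.region_label, "size_bp": r.size,
        "T%": r.t_pct, "C%": r.c_pct, "A%": r.a_pct, "G%": r.g_pct,
        "AT%": r.at_content, "GC%": r.gc_content,
        "AT_skew": r.at_skew, "GC_skew": r.gc_skew,
    } for r in rows])


@dataclass(frozen=True)
class AdjacencyReport:
    """Circular gap/overlap accounting over consecutive features.

    ``pairs`` holds (upstream, downstream, intergenic_bp) for every circular
    adjacency in start order; negative intergenic values are overlaps.
    """

    genome_id: str
    pairs: tuple[tuple[str, str, int], ...]
    gap_total: int
    overlap_total: int
    longest_gap: tuple[str, str, int] | None
    longest_overlap: tuple[str, str, int] | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs,
                            columns=["upstream", "downstream", "intergenic_bp"])


def adjacency_report(record: MitogenomeRecord) -> AdjacencyReport:
    """Intergenic gaps and overlaps over all circular adjacencies.

    Overlaps (negative intergenic lengths) are legal; a feature fully nested
    inside another triggers a warning but is still reported.
    """
    feats = record.features
    if len(feats) < 2:
        raise ValidationError("adjacency report needs at least two features")
    for f in feats:
        for g in feats:
            if f is not g and f.start >= g.start and f.end <= g.end:
                warnings.warn(f"{record.id}: {f.name} nested within {g.name}",
                              stacklevel=2)
    pairs = []
    for a, b in zip(feats, feats[1:]):
        pairs.append((a.name, b.name, b.start - a.end - 1))
    last, first = feats[-1], feats[0]
    pairs.append((last.name, first.name,
                  first.start + (record.length - last.end) - 1))
    gaps = [p for p in pairs if p[2] > 0]
    overlaps = [p for p in pairs if p[2] < 0]
    return AdjacencyReport(
        genome_id=record.id,
        pairs=tuple(pairs),
        gap_total=sum(p[2] for p in gaps),
        overlap_total=sum(-p[2] for p in overlaps),
        longest_gap=max(gaps, key=lambda p: p[2]) if gaps else None,
        longest_overlap=min(overlaps, key=lambda p: p[2]) if overlaps else None,
    )


def pcg_summary(record: MitogenomeRecord) -> tuple[int, float]:
    """Total protein-coding span and its share of the genome.

    Returns (total_pcg_bp, percent_of_genome) with the percentage rounded to
    two decimals.
    """
    pcgs = record.features_of_type("PCG")
    if not pcgs:
        raise ValidationError(f"record {record.id} has no protein-coding genes")
    total = sum(f.size for f in pcgs)
    return total, round(100.0 * total / record.length, 2)
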
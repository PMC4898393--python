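"""Cross-platform overlap verification and literature comparison.

A query call is verified if an evidence interval of the same animal overlaps
it by at least 1 bp (half-open arithmetic).  Literature comparison annotates
each external CNVR with the number of studies it appears in and whether this
pipeline's CNVR set detects it, then aggregates by study count.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._intervals import as_array, overlaps_any
from ._util import round_half_up
from .data_model_io import StudySet
from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VerificationReport:
    platform: str
    verified: int
    not_verified: int
    records: tuple = field(default=(), repr=False)

    def __post_init__(self):
        if self.verified < 0 or self.not_verified < 0:
            raise ValidationError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.verified + self.not_verified

    def percent_verified(self, ndigits: int = 2) -> float:
        if self.total == 0:
            return float("nan")
        return round_half_up(100.0 * self.verified / self.total, ndigits)

    @classmethod
    def from_counts(cls, platform: str, verified: int,
                    not_verified: int) -> "VerificationReport":
        return cls(platform=platform, verified=verified, not_verified=not_verified)


def overlap_verify(query: Mapping[str, Mapping[str, np.ndarray]],
                   evidence: Mapping[str, Mapping[str, np.ndarray]],
                   platform: str = "evidence",
                   min_overlap: int = 1) -> VerificationReport:
    """Verify per-animal query intervals against same-animal evidence.

    ``query`` and ``evidence`` map animal -> chrom -> (n, 2) interval arrays.
    Animals missing from the evidence contribute only not-verified records.
    """
    records = []
    n_ver = n_not = 0
    for animal in sorted(query):
        ev = evidence.get(animal)
        if ev is None:
            log.info("animal %s absent from evidence; its calls count as "
                     "not-verified", animal)
        for chrom in sorted(query[animal]):
            q = as_array(query[animal][chrom])
            if len(q) == 0:
                continue
            subject = ev.get(chrom, np.empty((0, 2), dtype=np.int64)) \
                if ev is not None else np.empty((0, 2), dtype=np.int64)
            hits = overlaps_any(q, subject, min_overlap=min_overlap)
            for (s, e), hit in zip(q, hits):
                records.append((animal, chrom, int(s), int(e), bool(hit)))
                if hit:
                    n_ver += 1
                else:
                    n_not += 1
    return VerificationReport(platform=platform, verified=n_ver,
                              not_verified=n_not, records=tuple(records))


@dataclass(frozen=True)
class ComparisonRow:
    study_count: int
    n_total: int
    n_detected: int


@dataclass(frozen=True)
class ComparisonTable:
    """Literature CNVRs aggregated by the number of studies observing them."""
    rows: tuple  # ComparisonRow, ascending study_count
    reciprocal_fraction: float = float("nan")  # our CNVRs overlapping any study

    @classmethod
    def from_rows(cls, rows) -> "ComparisonTable":
        parsed = tuple(sorted((ComparisonRow(*r) if not isinstance(r, ComparisonRow)
                               else r for r in rows), key=lambda r: r.study_count))
        return cls(rows=parsed)

    def grand_total(self) -> int:
        return sum(r.n_total for r in self.rows)

    def grand_detected(self) -> int:
        return sum(r.n_detected for r in self.rows)

    def multi_study_total(self, min_count: int = 2) -> int:
        return sum(r.n_total for r in self.rows if r.study_count >= min_count)

    def multi_study_detected(self, min_count: int = 2) -> int:
        return sum(r.n_detected for r in self.rows if r.study_count >= min_count)

    def detection_percent(self, min_count: int = 1, ndigits: int = 0) -> float:
        total = sum(r.n_total for r in self.rows if r.study_count >= min_count)
        det = sum(r.n_detected for r in self.rows if r.study_count >= min_count)
        if total == 0:
            return float("nan")
        return round_half_up(100.0 * det / total, ndigits)


def compare_to_studies(our_cnvrs: Mapping[str, np.ndarray],
                       studies: Sequence[StudySet],
                       min_overlap: int = 1) -> ComparisonTable:
    """Annotate each literature CNVR with its cross-study count and detection.

    A literature CNVR's study count is 1 plus the number of OTHER studies
    containing an interval overlapping it by >= min_overlap bp; it is
    detected if any of our CNVRs overlaps it by >= min_overlap bp.
    """
    if not studies:
        raise ValidationError("empty study list")
    labels = [s.label for s in studies]
    if len(set(labels)) != len(labels):
        raise ValidationError("study labels must be unique")
    counts: dict = {}
    ours_detected = 0
    ours_n = 0
    for study in studies:
        for chrom, arr in study.intervals.items():
            arr = as_array(arr)
            if len(arr) == 0:
                continue
            study_count = np.ones(len(arr), dtype=int)
            for other in studies:
                if other.label == study.label:
                    continue
                other_arr = other.intervals.get(chrom,
                                                np.empty((0, 2), dtype=np.int64))
                study_count += overlaps_any(arr, other_arr,
                                            min_overlap=min_overlap).astype(int)
            detected = overlaps_any(
                arr, our_cnvrs.get(chrom, np.empty((0, 2), dtype=np.int64)),
                min_overlap=min_overlap)
            for sc, det in zip(study_count, detected):
                tot, d = counts.get(int(sc), (0, 0))
                counts[int(sc)] = (tot + 1, d + int(det))
    # reciprocal: fraction of our CNVRs overlapping any literature interval
    all_lit: dict = {}
    for study in studies:
        for chrom, arr in study.intervals.items():
            all_lit.setdefault(chrom, []).append(as_array(arr))
    for chrom, arr in our_cnvrs.items():
        arr = as_array(arr)
        ours_n += len(arr)
        lit = np.concatenate(all_lit[chrom]) if chrom in all_lit else \
            np.empty((0, 2), dtype=np.int64)
        ours_detected += int(overlaps_any(arr, lit, min_overlap=min_overlap).sum())
    rows = tuple(ComparisonRow(sc, tot, det)
                 for sc, (tot, det) in sorted(counts.items()))
    recip = ours_detected / ours_n if ours_n else float("nan")
    return ComparisonTable(rows=rows, reciprocal_fraction=recip)
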
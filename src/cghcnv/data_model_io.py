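"""Domain types, coordinate conventions, and file readers/writers.

All internal coordinates are 0-based half-open.  Array-report TSV files are
declared 1-based inclusive by default and converted at the boundary; every
reader/writer pair round-trips losslessly.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._intervals import as_array
from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

# spacer between consecutive scaffolds on the virtual "unknown" chromosome
CHRUN_SPACER = 100


class CallType(str, enum.Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def call_type_from_l2r(l2r: float) -> CallType:
    """Negative mean log2 ratio is a deletion, non-negative a duplication."""
    return CallType.DELETION if l2r < 0 else CallType.DUPLICATION


@dataclass(frozen=True)
class Scaffold:
    """One scaffold interval on the virtual unknown chromosome."""
    name: str
    start: int
    stop: int

    @property
    def length(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths plus the autosome / X / chrUn partition."""
    lengths: Mapping[str, int]
    autosomes: frozenset
    x_name: str | None = None
    chrun_name: str | None = None
    chrun_scaffolds: tuple = ()

    def __post_init__(self):
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValidationError(f"chromosome {chrom} has non-positive length {length}")
        for name in self.autosomes:
            if name not in self.lengths:
                raise ValidationError(f"autosome {name} missing from lengths")
        prev = None
        for sc in self.chrun_scaffolds:
            if sc.stop <= sc.start:
                raise ValidationError(f"scaffold {sc.name} has stop <= start")
            if prev is not None and sc.start - prev.stop != CHRUN_SPACER:
                raise ValidationError(
                    f"scaffolds {prev.name} and {sc.name} are separated by "
                    f"{sc.start - prev.stop} bp, expected exactly {CHRUN_SPACER}")
            prev = sc

    def is_autosome(self, chrom: str) -> bool:
        return chrom in self.autosomes

    @property
    def autosome_length(self) -> int:
        return sum(self.lengths[c] for c in self.autosomes)

    def scaffold_at(self, start: int, stop: int):
        """Scaffold fully containing [start, stop), or None."""
        for sc in self.chrun_scaffolds:
            if start >= sc.start and stop <= sc.stop:
                return sc
        return None


@dataclass(frozen=True)
class SegmentCall:
    """One platform-reported CGH segment for one animal.

    Coordinates are 0-based half-open; ``datapoints`` is the probe count and
    must equal ``last_probe - first_probe + 1``.
    """
    animal: str
    chrom: str
    start: int
    stop: int
    first_probe: int
    last_probe: int
    l2r: float
    datapoints: int

    def __post_init__(self):
        if self.stop <= self.start:
            raise ValidationError(
                f"call {self.animal}:{self.chrom}:{self.start}-{self.stop}: stop <= start")
        if self.datapoints < 1:
            raise ValidationError(f"call {self.animal}:{self.chrom}:{self.start}: "
                                  f"datapoints {self.datapoints} < 1")
        if self.datapoints != self.last_probe - self.first_probe + 1:
            raise ValidationError(
                f"call {self.animal}:{self.chrom}:{self.start}: datapoints "
                f"{self.datapoints} != probe span {self.last_probe - self.first_probe + 1}")

    @property
    def length(self) -> int:
        return self.stop - self.start

    @property
    def absl2r(self) -> float:
        return abs(self.l2r)


@dataclass(frozen=True)
class CnvCall(SegmentCall):
    """A segment call accepted as a true CNV, typed by l2r sign."""
    type: CallType = CallType.DELETION
    p: float = 1.0

    def __post_init__(self):
        super().__post_init__()
        if self.type != call_type_from_l2r(self.l2r):
            raise ValidationError(f"call type {self.type} inconsistent with l2r {self.l2r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"model probability {self.p} outside [0, 1]")

    @classmethod
    def from_segment(cls, call: SegmentCall, p: float) -> "CnvCall":
        return cls(animal=call.animal, chrom=call.chrom, start=call.start,
                   stop=call.stop, first_probe=call.first_probe,
                   last_probe=call.last_probe, l2r=call.l2r,
                   datapoints=call.datapoints,
                   type=call_type_from_l2r(call.l2r), p=p)


@dataclass(frozen=True)
class Cnvr:
    """A merged copy-number-variable region across animals."""
    chrom: str
    start: int
    stop: int
    type: str  # deletion | duplication | both
    animals: frozenset = field(default_factory=frozenset)
    calls: tuple = ()

    def __post_init__(self):
        if self.stop - self.start < 1:
            raise ValidationError(f"CNVR {self.chrom}:{self.start}-{self.stop} empty")
        if self.type not in ("deletion", "duplication", "both"):
            raise ValidationError(f"bad CNVR type {self.type!r}")
        for c in self.calls:
            if c.stop <= self.start or c.start >= self.stop:
                raise ValidationError("supporting call does not overlap its CNVR")

    @property
    def length(self) -> int:
        return self.stop - self.start


@dataclass
class DepthTrack:
    """Per-base read depth for one chromosome with a repeat mask and GC track."""
    chrom: str
    depth: np.ndarray
    mask: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    gc: np.ndarray | None = None  # per-base GC value (indicator or local fraction)

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=np.float64)
        self.mask = as_array(self.mask)
        if np.any(self.depth < 0):
            raise ValidationError(f"{self.chrom}: negative depth values")
        n = len(self.depth)
        if len(self.mask) and (self.mask[:, 0].min() < 0 or self.mask[:, 1].max() > n):
            raise ValidationError(f"{self.chrom}: mask interval outside chromosome bounds")
        if self.gc is not None:
            self.gc = np.asarray(self.gc, dtype=np.float64)
            if len(self.gc) != n:
                raise ValidationError(f"{self.chrom}: GC track length mismatch")

    def masked_bool(self) -> np.ndarray:
        m = np.zeros(len(self.depth), dtype=bool)
        for s, e in self.mask:
            m[s:e] = True
        return m


@dataclass(frozen=True)
class StudySet:
    """A labelled set of intervals on a shared coordinate system."""
    label: str
    intervals: Mapping[str, np.ndarray]  # chrom -> (n, 2) array

    def __post_init__(self):
        object.__setattr__(self, "intervals",
                           {c: as_array(v) for c, v in self.intervals.items()})
        for c, arr in self.intervals.items():
            if len(arr) and np.any(arr[:, 1] <= arr[:, 0]):
                raise ValidationError(f"study {self.label}: invalid interval on {c}")

    def n_intervals(self) -> int:
        return sum(len(v) for v in self.intervals.values())


@dataclass(frozen=True)
class Pedigree:
    """Trios, sexes, the reference animal and the self-self hybridisation."""
    trios: tuple  # ((child, sire, dam), ...)
    sex: Mapping[str, str]  # animal -> 'M' | 'F'
    reference: str
    selfself: str | None = None  # defaults to the reference animal

    def __post_init__(self):
        if self.selfself is None:
            object.__setattr__(self, "selfself", self.reference)

    @property
    def animals(self) -> tuple:
        seen = []
        for child, sire, dam in self.trios:
            for a in (child, sire, dam):
                if a not in seen:
                    seen.append(a)
        for a in self.sex:
            if a not in seen:
                seen.append(a)
        return tuple(seen)

    @property
    def test_animals(self) -> tuple:
        """Animals assayed against the reference (excludes the self-self array)."""
        return tuple(a for a in self.animals if a != self.selfself)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

SEGMENT_COLUMNS = ["animal", "chrom", "start", "stop", "first_probe",
                   "last_probe", "l2r", "datapoints"]


def read_segment_calls(path, dialect: str = "1-based-inclusive") -> list:
    """Read a tab-separated segment-call table.

    The array-report dialect stores 1-based inclusive coordinates; they are
    converted to the internal 0-based half-open convention on read.
    Malformed rows are reported with their file line numbers.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"animal": str, "chrom": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file without header")
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    offset = 1 if dialect == "1-based-inclusive" else 0
    calls, problems = [], []
    for idx, row in enumerate(df.itertuples(index=False)):
        lineno = idx + 2  # header is line 1
        try:
            calls.append(SegmentCall(
                animal=str(row.animal), chrom=str(row.chrom),
                start=int(row.start) - offset, stop=int(row.stop),
                first_probe=int(row.first_probe), last_probe=int(row.last_probe),
                l2r=float(row.l2r), datapoints=int(row.datapoints)))
        except (ValidationError, ValueError) as exc:
            problems.append(f"line {lineno}: {exc}")
    if problems:
        raise ValidationError(f"{path}: {len(problems)} malformed row(s): "
                              + "; ".join(problems))
    return calls


def write_segment_calls(calls: Iterable[SegmentCall], path,
                        dialect: str = "1-based-inclusive") -> None:
    offset = 1 if dialect == "1-based-inclusive" else 0
    rows = [{"animal": c.animal, "chrom": c.chrom, "start": c.start + offset,
             "stop": c.stop, "first_probe": c.first_probe,
             "last_probe": c.last_probe, "l2r": c.l2r,
             "datapoints": c.datapoints} for c in calls]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_cnvr_bed(cnvrs: Sequence[Cnvr], path) -> None:
    """Write CNVRs as BED; the name column encodes type and animal count."""
    with open(path, "w") as fh:
        for r in cnvrs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.stop}\t{r.type};n={len(r.animals)}\n")


@dataclass(frozen=True)
class BedCnvr:
    chrom: str
    start: int
    stop: int
    type: str
    n_animals: int


def read_cnvr_bed(path) -> list:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 BED columns")
            name = parts[3]
            try:
                typ, nfield = name.split(";")
                n = int(nfield.split("=")[1])
            except (ValueError, IndexError):
                raise FormatError(f"{path}: line {lineno}: bad name field {name!r}")
            out.append(BedCnvr(parts[0], int(parts[1]), int(parts[2]), typ, n))
    return out


def read_bed(path) -> dict:
    """Read a BED file into chrom -> sorted (n, 2) interval arrays."""
    by_chrom: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 BED columns")
            s, e = int(parts[1]), int(parts[2])
            if e <= s:
                raise FormatError(f"{path}: line {lineno}: stop <= start")
            by_chrom.setdefault(parts[0], []).append((s, e))
    return {c: as_array(v) for c, v in by_chrom.items()}


def write_bed(intervals: Mapping[str, np.ndarray], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for s, e in as_array(intervals[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_depth_track(path, mask_path=None, gc_path=None,
                     lengths: Mapping[str, int] | None = None) -> dict:
    """Read a bedGraph depth file (plus optional mask BED and GC bedGraph).

    bedGraph intervals must tile each chromosome without overlap; gaps are
    filled with zero depth.  Returns chrom -> DepthTrack.
    """
    per_chrom = _read_bedgraph(path)
    masks = read_bed(mask_path) if mask_path else {}
    gcs = _read_bedgraph(gc_path) if gc_path else {}
    tracks = {}
    for chrom, rows in per_chrom.items():
        length = (lengths or {}).get(chrom, int(rows[-1][1]))
        depth = _expand_bedgraph(rows, length, f"{path}:{chrom}")
        gc = None
        if chrom in gcs:
            gc = _expand_bedgraph(gcs[chrom], length, f"{gc_path}:{chrom}")
        tracks[chrom] = DepthTrack(chrom=chrom, depth=depth,
                                   mask=masks.get(chrom, np.empty((0, 2), dtype=np.int64)),
                                   gc=gc)
    return tracks


def _read_bedgraph(path) -> dict:
    per_chrom: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 bedGraph columns")
            per_chrom.setdefault(parts[0], []).append(
                (int(parts[1]), int(parts[2]), float(parts[3])))
    return {c: sorted(v) for c, v in per_chrom.items()}


def _expand_bedgraph(rows, length: int, where: str) -> np.ndarray:
    arr = np.zeros(length, dtype=np.float64)
    prev_end = 0
    for s, e, v in rows:
        if s < prev_end:
            raise FormatError(f"{where}: overlapping bedGraph intervals at {s}")
        arr[s:e] = v
        prev_end = e
    return arr


def write_depth_track(tracks: Mapping[str, DepthTrack], path,
                      mask_path=None, gc_path=None) -> None:
    """Write per-base depth as run-length-encoded bedGraph (lossless)."""
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            _write_rle(fh, chrom, tracks[chrom].depth)
    if mask_path is not None:
        write_bed({c: t.mask for c, t in tracks.items()}, mask_path)
    if gc_path is not None:
        with open(gc_path, "w") as fh:
            for chrom in sorted(tracks):
                if tracks[chrom].gc is not None:
                    _write_rle(fh, chrom, np.round(
                        tracks[chrom].gc.astype(np.float64), 6))


def _write_rle(fh, chrom: str, values: np.ndarray) -> None:
    if len(values) == 0:
        return
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(values)]])
    for s, e in zip(starts, stops):
        fh.write(f"{chrom}\t{s}\t{e}\t{values[s]:g}\n")


PEDIGREE_COLUMNS = ["animal", "sire", "dam", "sex", "role"]


def write_pedigree(ped: Pedigree, path) -> None:
    parents = {}
    for child, sire, dam in ped.trios:
        parents[child] = (sire, dam)
    with open(path, "w") as fh:
        fh.write("\t".join(PEDIGREE_COLUMNS) + "\n")
        for a in ped.animals:
            sire, dam = parents.get(a, (".", "."))
            role = "reference" if a == ped.reference else (
                "selfself" if a == ped.selfself else "sample")
            fh.write(f"{a}\t{sire}\t{dam}\t{ped.sex.get(a, '.')}\t{role}\n")


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PEDIGREE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing pedigree column(s) {missing}")
    trios, sex = [], {}
    reference = selfself = None
    for row in df.itertuples(index=False):
        if row.sire != "." and row.dam != ".":
            trios.append((row.animal, row.sire, row.dam))
        if row.sex and row.sex != ".":
            sex[row.animal] = row.sex
        if row.role == "reference":
            reference = row.animal
        if row.role == "selfself":
            selfself = row.animal
    if reference is None:
        raise FormatError(f"{path}: no animal with role 'reference'")
    return Pedigree(trios=tuple(trios), sex=sex, reference=reference,
                    selfself=selfself)
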
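"""Pre-model and post-model filtering of segment calls.

Includes failed-array QC, the pre-model |l2r| >= 0.1 filter, the post-model
autosomal filter (p, length, probe count, |l2r|), the chromosome-X sex rules
and the virtual-unknown-chromosome scaffold rules.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_model_io import (CallType, CnvCall, GenomeLayout, SegmentCall,
                            call_type_from_l2r)
from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterPolicy:
    min_absl2r_prefilter: float = 0.1
    p_threshold: float = 0.95
    min_length: int = 1000
    min_probes: int = 3
    min_absl2r: float = 0.25
    chrun_min_absl2r: float = 0.32   # exclusive threshold
    chrun_min_probes: int = 2
    chrun_min_probes_outside: int = 2
    qc_mad_k: float = 3.0

    def __post_init__(self):
        if not 0 < self.p_threshold < 1:
            raise ValidationError("p_threshold must be in (0, 1)")
        for name in ("min_absl2r_prefilter", "min_length", "min_probes",
                     "min_absl2r", "chrun_min_absl2r", "qc_mad_k"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def qc_flag_failed_arrays(variances: Mapping[str, float],
                          k: float = 3.0) -> set:
    """Flag animals whose probe-l2r variance exceeds median + k * MAD.

    With fewer than three animals QC is skipped (empty set, warning).
    """
    if len(variances) < 3:
        log.warning("QC skipped: need >= 3 animals, got %d", len(variances))
        return set()
    vals = np.array(list(variances.values()), dtype=float)
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    cutoff = med + k * mad
    return {a for a, v in variances.items() if v > cutoff}


def prefilter_ratio(calls: Iterable[SegmentCall],
                    min_absl2r: float = 0.1) -> list:
    """Remove calls with absolute log2 ratio below 0.1 (boundary kept)."""
    return [c for c in calls if c.absl2r >= min_absl2r]


def _passes_model_filters(call: SegmentCall, p: float, policy: FilterPolicy) -> bool:
    return (p >= policy.p_threshold
            and call.length >= policy.min_length
            and call.datapoints >= policy.min_probes
            and call.absl2r >= policy.min_absl2r)


def filter_autosomal(calls_with_p: Sequence[tuple],
                     policy: FilterPolicy = FilterPolicy(),
                     layout: GenomeLayout | None = None) -> list:
    """Keep autosomal calls with p >= threshold, length >= 1 kb, >= 3 probes
    and |l2r| >= 0.25; kept calls are typed by l2r sign."""
    out = []
    for call, p in calls_with_p:
        if layout is not None and not layout.is_autosome(call.chrom):
            raise ValidationError(
                f"call on {call.chrom} is not autosomal; route it through "
                f"filter_chrx / filter_chrun")
        if _passes_model_filters(call, p, policy):
            out.append(CnvCall.from_segment(call, p))
    return out


def filter_chrx(calls_with_p: Sequence[tuple], sex: Mapping[str, str],
                policy: FilterPolicy = FilterPolicy()) -> list:
    """Chromosome-X rule: keep female deletions/duplications and male
    duplications; male deletions are inconclusive against a female reference."""
    out = []
    for call, p in calls_with_p:
        if not _passes_model_filters(call, p, policy):
            continue
        s = sex.get(call.animal)
        if s not in ("M", "F"):
            log.warning("call for %s dropped: unknown sex", call.animal)
            continue
        typ = call_type_from_l2r(call.l2r)
        if s == "M" and typ == CallType.DELETION:
            continue
        out.append(CnvCall.from_segment(call, p))
    return out


def filter_chrun(calls: Sequence[SegmentCall], layout: GenomeLayout,
                 policy: FilterPolicy = FilterPolicy(),
                 probes_per_scaffold: Mapping[str, int] | None = None,
                 probe_spacing: int = 1600) -> list:
    """Virtual-unknown-chromosome rules.

    A call is kept iff it lies within a single scaffold, does not contain all
    of that scaffold's probes (>= 2 scaffold probes outside the call),
    |l2r| > 0.32 (exclusive) and it spans >= 2 probes.
    """
    out = []
    for call in calls:
        sc = layout.scaffold_at(call.start, call.stop)
        if sc is None:
            # spans >1 scaffold -> discarded; outside all scaffolds -> error
            if any(call.start < s.stop and call.stop > s.start
                   for s in layout.chrun_scaffolds):
                continue
            raise ValidationError(
                f"call {call.animal}:{call.chrom}:{call.start}-{call.stop} "
                f"falls in an N spacer outside every scaffold")
        if probes_per_scaffold is not None:
            n_probes = probes_per_scaffold[sc.name]
        else:
            n_probes = max(1, sc.length // probe_spacing)
        if call.datapoints < policy.chrun_min_probes:
            continue
        if n_probes - call.datapoints < policy.chrun_min_probes_outside:
            continue
        if call.absl2r <= policy.chrun_min_absl2r:
            continue
        out.append(CnvCall.from_segment(call, 1.0))
    return out
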
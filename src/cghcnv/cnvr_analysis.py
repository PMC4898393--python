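"""Merging CNV calls into CNV regions and testing their spatial distribution.

Calls within 1,500 bp of one another (across animals) collapse transitively
into CNVRs.  Spatial uniformity is tested by comparing observed inter-CNVR
distances against a size-matched simulated uniform placement with the same
region lengths and a > 1,500 bp spacing constraint, via a two-sample
Kolmogorov-Smirnov test.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from . import _intervals
from ._util import round_half_up
from .data_model_io import CnvCall, Cnvr, GenomeLayout
from .errors import CapacityError, ValidationError

log = logging.getLogger(__name__)

MERGE_GAP = 1500


def merge_to_cnvrs(calls: Iterable[CnvCall], gap: int = MERGE_GAP) -> list:
    """Collapse calls whose gap is <= 1,500 bp (or overlapping) into CNVRs.

    The result is independent of input order; CNVR type is deletion,
    duplication or both according to the member call types.
    """
    by_chrom: dict = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    cnvrs = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda c: (c.start, c.stop, c.animal))
        cluster: list = []
        cluster_end = None
        for c in group:
            if cluster and c.start - cluster_end > gap:
                cnvrs.append(_make_cnvr(chrom, cluster))
                cluster = []
            cluster.append(c)
            cluster_end = c.stop if cluster_end is None or len(cluster) == 1 \
                else max(cluster_end, c.stop)
        if cluster:
            cnvrs.append(_make_cnvr(chrom, cluster))
    return cnvrs


def _make_cnvr(chrom: str, cluster: Sequence[CnvCall]) -> Cnvr:
    types = {c.type.value for c in cluster}
    typ = types.pop() if len(types) == 1 else "both"
    return Cnvr(chrom=chrom,
                start=min(c.start for c in cluster),
                stop=max(c.stop for c in cluster),
                type=typ,
                animals=frozenset(c.animal for c in cluster),
                calls=tuple(sorted(cluster, key=lambda c: (c.start, c.stop, c.animal))))


@dataclass(frozen=True)
class FrequencySpectrum:
    """CNVR counts keyed by the number of supporting animals."""
    counts: Mapping[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def singleton_fraction(self) -> float:
        return self.counts.get(1, 0) / self.total if self.total else float("nan")

    @property
    def multi_fraction(self) -> float:
        if not self.total:
            return float("nan")
        return sum(v for k, v in self.counts.items() if k >= 2) / self.total


def frequency_spectrum(cnvrs: Sequence[Cnvr]) -> FrequencySpectrum:
    return FrequencySpectrum(counts=dict(Counter(len(r.animals) for r in cnvrs)))


def multi_animal_percent(n_multi: int, n_total: int, ndigits: int = 0) -> float:
    """Percent of CNVRs supported by >= 2 animals, from the two counts."""
    return round_half_up(100.0 * n_multi / n_total, ndigits)


def mean_calls_per_animal(total_calls: int, n_animals: int) -> int:
    """Mean filtered CNV calls per assayed animal, rounded to an integer."""
    return int(round_half_up(total_calls / n_animals))


def combined_cnvr_total(*counts: int) -> int:
    """Genome-wide CNVR total as the sum of per-compartment counts."""
    return sum(counts)


def flag_reference_effect(cnvrs: Sequence[Cnvr], n_animals: int) -> list:
    """CNVRs supported by every assayed animal: putative reference-animal CNVs."""
    if n_animals == 1:
        log.warning("n_animals=1: every CNVR is trivially flagged")
    return [r for r in cnvrs if len(r.animals) == n_animals]


def genome_fraction(intervals_by_chrom: Mapping[str, np.ndarray],
                    layout: GenomeLayout) -> float:
    """Percent of the autosome length covered by the union of the intervals."""
    covered = 0
    for chrom, arr in intervals_by_chrom.items():
        if chrom not in layout.autosomes:
            continue
        arr = _intervals.as_array(arr)
        if len(arr) and (arr[:, 0].min() < 0 or arr[:, 1].max() > layout.lengths[chrom]):
            raise ValidationError(f"interval beyond end of {chrom}")
        covered += _intervals.union_length(arr)
    return 100.0 * covered / layout.autosome_length


def cnvrs_to_intervals(cnvrs: Sequence[Cnvr]) -> dict:
    out: dict = {}
    for r in cnvrs:
        out.setdefault(r.chrom, []).append((r.start, r.stop))
    return {c: _intervals.as_array(v) for c, v in out.items()}


def calls_to_intervals(calls: Sequence[CnvCall], animal: str | None = None) -> dict:
    out: dict = {}
    for c in calls:
        if animal is not None and c.animal != animal:
            continue
        out.setdefault(c.chrom, []).append((c.start, c.stop))
    return {ch: _intervals.as_array(v) for ch, v in out.items()}


def per_animal_genome_fraction(calls: Sequence[CnvCall],
                               layout: GenomeLayout) -> dict:
    return {a: genome_fraction(calls_to_intervals(calls, a), layout)
            for a in sorted({c.animal for c in calls})}


# ---------------------------------------------------------------------------
# Uniform-null placement and KS uniformity test
# ---------------------------------------------------------------------------

def _place_on_chrom(lengths: np.ndarray, chrom_len: int, min_gap: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Uniformly place intervals of the given lengths with pairwise gaps
    > min_gap - 1 (i.e. >= min_gap), via the order-statistics construction."""
    return _place_on_chrom_ordered(rng.permutation(lengths), chrom_len,
                                   min_gap, rng)


def simulate_uniform_null(cnvr_lengths: Sequence[int], layout: GenomeLayout,
                          min_spacing: int = MERGE_GAP,
                          seed=None, max_retries: int = 100) -> dict:
    """Place the observed lengths uniformly at random on the autosomes.

    Chromosome assignment is proportional to chromosome length; pairwise gaps
    are constrained to exceed min_spacing.  Returns chrom -> (n, 2) array.
    """
    rng = np.random.default_rng(seed)
    lengths = np.asarray(cnvr_lengths, dtype=np.int64)
    chroms = sorted(layout.autosomes)
    weights = np.array([layout.lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    gap = min_spacing + 1  # "within 1,500 bp" is forbidden -> gaps must exceed it
    for _ in range(max_retries):
        assignment = rng.choice(len(chroms), size=len(lengths), p=weights)
        try:
            placed = {}
            for i, chrom in enumerate(chroms):
                sel = lengths[assignment == i]
                arr = _place_on_chrom(sel, layout.lengths[chrom], gap, rng)
                if len(arr):
                    placed[chrom] = arr
            return placed
        except CapacityError:
            continue
    raise CapacityError(
        f"could not place {len(lengths)} intervals after {max_retries} retries")


def place_lengths(cnvr_lengths: Sequence[int], layout: GenomeLayout,
                  min_spacing: int = MERGE_GAP, seed=None,
                  max_retries: int = 100) -> list:
    """Like simulate_uniform_null but preserves input order.

    Returns [(chrom, start, stop), ...] where entry i has length
    cnvr_lengths[i], so per-interval metadata (e.g. CNVR type) stays attached.
    """
    rng = np.random.default_rng(seed)
    lengths = np.asarray(cnvr_lengths, dtype=np.int64)
    chroms = sorted(layout.autosomes)
    weights = np.array([layout.lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    gap = min_spacing + 1
    for _ in range(max_retries):
        assignment = rng.choice(len(chroms), size=len(lengths), p=weights)
        try:
            out: list = [None] * len(lengths)
            for i, chrom in enumerate(chroms):
                idx = np.flatnonzero(assignment == i)
                if len(idx) == 0:
                    continue
                perm = rng.permutation(len(idx))
                arr = _place_on_chrom_ordered(lengths[idx[perm]],
                                              layout.lengths[chrom], gap, rng)
                for j, (s, e) in zip(idx[perm], arr):
                    out[j] = (chrom, int(s), int(e))
            return out
        except CapacityError:
            continue
    raise CapacityError(
        f"could not place {len(lengths)} intervals after {max_retries} retries")


def _place_on_chrom_ordered(lengths: np.ndarray, chrom_len: int, min_gap: int,
                            rng: np.random.Generator) -> np.ndarray:
    """_place_on_chrom without the internal shuffle (caller pre-shuffles)."""
    n = len(lengths)
    if n == 0:
        return np.empty((0, 2), dtype=np.int64)
    free = chrom_len - int(lengths.sum()) - min_gap * (n - 1)
    if free < 0:
        raise CapacityError("insufficient space on chromosome")
    u = np.sort(rng.integers(0, free + 1, size=n))
    offsets = np.concatenate([[0], np.cumsum(lengths[:-1] + min_gap)])
    starts = u + offsets
    return np.stack([starts, starts + lengths], axis=1).astype(np.int64)


def inter_cnvr_distances(intervals_by_chrom: Mapping[str, np.ndarray]) -> np.ndarray:
    """Adjacent-pair gaps between consecutive intervals, per chromosome."""
    gaps = []
    for chrom, arr in intervals_by_chrom.items():
        arr = _intervals.as_array(arr)
        if len(arr) >= 2:
            gaps.append(arr[1:, 0] - arr[:-1, 1])
    if not gaps:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(gaps)


@dataclass(frozen=True)
class SpatialTestResult:
    observed_distances: np.ndarray
    simulated_distances: np.ndarray
    statistic: float
    pvalue: float
    seed: object = None

    def __post_init__(self):
        if len(self.observed_distances) and self.observed_distances.min() < 0:
            raise ValidationError("negative inter-CNVR distance")
        if not 0.0 <= self.statistic <= 1.0:
            raise ValidationError("KS statistic outside [0, 1]")


def ks_uniformity_test(observed: Mapping[str, np.ndarray] | Sequence[Cnvr],
                       layout: GenomeLayout, seed=None,
                       min_spacing: int = MERGE_GAP,
                       replicates: int = 1) -> SpatialTestResult | None:
    """Two-sample KS test of observed inter-CNVR distances against one (or
    more, averaged) simulated uniform placements of the same region lengths.

    Returns None (with a log message) if fewer than two distances exist.
    """
    if not isinstance(observed, Mapping):
        observed = cnvrs_to_intervals(observed)
    obs_d = inter_cnvr_distances(observed)
    if len(obs_d) < 2:
        log.warning("KS test skipped: fewer than 2 inter-CNVR distances")
        return None
    lengths = np.concatenate([
        _intervals.as_array(a)[:, 1] - _intervals.as_array(a)[:, 0]
        for a in observed.values()])
    rng = np.random.default_rng(seed)
    stats_list, sim_d = [], None
    for _ in range(max(1, replicates)):
        sim = simulate_uniform_null(lengths, layout, min_spacing=min_spacing,
                                    seed=rng)
        sim_d = inter_cnvr_distances(sim)
        res = stats.ks_2samp(obs_d, sim_d)
        stats_list.append((res.statistic, res.pvalue))
    d = float(np.mean([s for s, _ in stats_list]))
    p = float(np.mean([p for _, p in stats_list]))
    return SpatialTestResult(observed_distances=obs_d, simulated_distances=sim_d,
                             statistic=d, pvalue=p, seed=seed)
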
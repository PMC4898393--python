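"""Truth-known synthetic inputs for every pipeline stage.

Generates a genome layout with planted CNV regions (per-animal copy numbers,
trio-consistent carriers, an optional CNV-carrying reference animal), noisy
CGH segment calls with self-self false positives, GC-biased per-base depth
tracks, and lower-sensitivity pseudo-platform call sets.  All generators are
deterministic under a fixed seed and every emitted call carries a truth
label.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from ._intervals import as_array
from .cnvr_analysis import MERGE_GAP, place_lengths
from .data_model_io import (DepthTrack, GenomeLayout, Pedigree, SegmentCall,
                            StudySet)
from .errors import ValidationError
from .readdepth_caller import BIN_SIZE, MixtureParams

log = logging.getLogger(__name__)

PROBE_SPACING = 1250  # default autosomal probe grid


@dataclass(frozen=True)
class PlantedCnvr:
    """One true CNVR with per-animal copy numbers (animals absent are CN=2)."""
    id: int
    chrom: str
    start: int
    stop: int
    type: str  # deletion | duplication
    cn: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.stop - self.start < 1000:
            raise ValidationError(f"planted CNVR {self.id} shorter than 1 kb")
        for a, c in self.cn.items():
            if c not in (0, 1, 2, 3, 4):
                raise ValidationError(f"CN {c} for {a} outside 0..4")

    @property
    def length(self) -> int:
        return self.stop - self.start

    def cn_of(self, animal: str) -> int:
        return self.cn.get(animal, 2)


@dataclass(frozen=True)
class TruthSet:
    layout: GenomeLayout
    cnvrs: tuple
    genes: Mapping[str, np.ndarray]
    mask: Mapping[str, np.ndarray]
    pedigree: Pedigree


@dataclass(frozen=True)
class FpProfile:
    """Shape of self-self-like false-positive calls."""
    length_range: tuple = (1000, 10000)
    absl2r_range: tuple = (0.1, 0.3)


@dataclass(frozen=True)
class LabelRecord:
    animal: str
    chrom: str
    start: int
    stop: int
    label: str  # "true" | "false"
    cnvr_id: int | None


def default_layout(n_autosomes: int = 3, autosome_length: int = 10_000_000,
                   x_length: int | None = None) -> GenomeLayout:
    lengths = {f"chr{i + 1}": autosome_length for i in range(n_autosomes)}
    autosomes = frozenset(lengths)
    x_name = None
    if x_length:
        x_name = "chrX"
        lengths["chrX"] = x_length
    return GenomeLayout(lengths=lengths, autosomes=autosomes, x_name=x_name)


def default_pedigree(n_trios: int = 3, n_extra: int = 2) -> Pedigree:
    """Trios plus unrelated extras and a reference animal (self-self array)."""
    trios, sex = [], {}
    for i in range(1, n_trios + 1):
        child, sire, dam = f"C{i}", f"S{i}", f"D{i}"
        trios.append((child, sire, dam))
        sex.update({child: "M" if i % 2 else "F", sire: "M", dam: "F"})
    for i in range(1, n_extra + 1):
        sex[f"E{i}"] = "M" if i % 2 else "F"
    sex["REF"] = "M"
    return Pedigree(trios=tuple(trios), sex=sex, reference="REF")


def simulate_truth(layout: GenomeLayout, n_cnvr: int,
                   length_dist: tuple = (math.log(9000.0), 1.0),
                   del_frac: float = 0.6,
                   freq_spectrum: Callable | None = None,
                   seed=None,
                   pedigree: Pedigree | None = None,
                   de_novo_rate: float = 0.0,
                   ref_carrier_rate: float = 0.0,
                   hom_frac: float = 0.1,
                   min_length: int = 1000,
                   min_spacing: int = MERGE_GAP,
                   n_genes: int = 0,
                   gene_length: int = 2000,
                   mask_frac: float = 0.0,
                   cluster_frac: float = 0.0,
                   cluster_gap: int = 2000) -> TruthSet:
    """Plant non-overlapping CNVRs with truth-known per-animal copy numbers.

    Lengths are log-normal (median ~9 kb by default, long right tail,
    truncated below at 1 kb); regions are >= min_spacing apart unless
    cluster_frac > 0, in which case that fraction of regions is re-placed
    cluster_gap bp after a randomly chosen anchor region.
    """
    rng = np.random.default_rng(seed)
    ped = pedigree if pedigree is not None else default_pedigree()
    meanlog, sdlog = length_dist
    lengths = np.maximum(
        np.exp(rng.normal(meanlog, sdlog, size=n_cnvr)).astype(np.int64),
        max(1000, min_length))
    placed = place_lengths(lengths, layout, min_spacing=min_spacing, seed=rng) \
        if n_cnvr else []

    if cluster_frac > 0 and n_cnvr >= 2:
        placed = _apply_clustering(placed, lengths, layout, cluster_frac,
                                   cluster_gap, rng)

    is_del = rng.random(n_cnvr) < del_frac
    assayable = list(ped.test_animals)
    children = {c for c, _, _ in ped.trios}
    parents_of = {c: (s, d) for c, s, d in ped.trios}
    if freq_spectrum is None:
        def freq_spectrum(r):
            return r.geometric(0.6)  # mostly singletons, geometric tail

    cnvrs = []
    for i, (chrom, start, stop) in enumerate(placed):
        typ = "deletion" if is_del[i] else "duplication"
        k = int(np.clip(freq_spectrum(rng), 1, len(assayable)))
        carriers = set(rng.choice(assayable, size=k, replace=False))
        for child in list(carriers & children):
            sire, dam = parents_of[child]
            if sire not in carriers and dam not in carriers:
                if rng.random() >= de_novo_rate:
                    carriers.add(sire if rng.random() < 0.5 else dam)
        cn = {}
        for a in carriers:
            if typ == "deletion":
                cn[a] = 0 if rng.random() < hom_frac else 1
            else:
                cn[a] = 4 if rng.random() < hom_frac else 3
        if rng.random() < ref_carrier_rate:
            cn[ped.reference] = 1 if typ == "deletion" else 3
        cnvrs.append(PlantedCnvr(id=i, chrom=chrom, start=start, stop=stop,
                                 type=typ, cn=cn))

    genes = _random_intervals(layout, n_genes, gene_length, rng)
    mask = _random_mask(layout, mask_frac, rng)
    return TruthSet(layout=layout, cnvrs=tuple(cnvrs), genes=genes,
                    mask=mask, pedigree=ped)


def _apply_clustering(placed, lengths, layout, cluster_frac, cluster_gap, rng):
    placed = list(placed)
    n = len(placed)
    k = int(cluster_frac * n)
    movable = rng.choice(n, size=k, replace=False)
    for j in movable:
        for _ in range(20):
            anchor = int(rng.integers(0, n))
            if anchor == j or anchor in movable:
                continue
            chrom, _, a_stop = placed[anchor]
            s = a_stop + cluster_gap
            e = s + int(lengths[j])
            if e > layout.lengths[chrom]:
                continue
            if any(c == chrom and s < oe and e > os
                   for idx, (c, os, oe) in enumerate(placed) if idx != j):
                continue
            placed[j] = (chrom, s, e)
            break
    return placed


def _random_intervals(layout, n, mean_length, rng) -> dict:
    out: dict = {}
    if n == 0:
        return out
    chroms = sorted(layout.autosomes)
    w = np.array([layout.lengths[c] for c in chroms], dtype=float)
    w /= w.sum()
    for _ in range(n):
        chrom = chroms[rng.choice(len(chroms), p=w)]
        length = max(200, int(rng.exponential(mean_length)))
        start = int(rng.integers(0, max(1, layout.lengths[chrom] - length)))
        out.setdefault(chrom, []).append((start, start + length))
    return {c: as_array(v) for c, v in out.items()}


def _random_mask(layout, frac, rng) -> dict:
    out: dict = {}
    if frac <= 0:
        return out
    for chrom in sorted(layout.lengths):
        total = int(frac * layout.lengths[chrom])
        pieces = max(1, total // 5000)
        for _ in range(pieces):
            length = max(100, int(rng.exponential(total / pieces)))
            start = int(rng.integers(0, max(1, layout.lengths[chrom] - length)))
            out.setdefault(chrom, []).append((start, start + length))
    return {c: as_array(v) for c, v in out.items()}


# ---------------------------------------------------------------------------
# CGH segment-call simulation
# ---------------------------------------------------------------------------

def _probe_window(start: int, stop: int, spacing: int) -> tuple | None:
    """First/last probe index with position in [start, stop), or None."""
    off = spacing // 2
    first = max(0, math.ceil((start - off) / spacing))
    last = (stop - 1 - off) // spacing
    if last < first:
        return None
    return first, last


def _effective_cn(cn: int, zero_cn: float = 0.15) -> float:
    return float(cn) if cn > 0 else zero_cn


def simulate_cgh_calls(truth: TruthSet, l2r_noise_sd: float = 0.15,
                       fp_rate: float = 10.0,
                       fp_profile: FpProfile = FpProfile(),
                       probe_spacing: int = PROBE_SPACING,
                       seed=None) -> tuple:
    """Emit segment calls plus truth labels for every animal.

    True calls appear wherever an animal's copy number differs from the
    reference animal's (so reference-animal CNVs induce apparent calls in
    every test animal); call boundaries snap to the shared probe grid, making
    carrier parents and progeny report identical first/last probes.  The
    self-self animal receives only false-positive calls.
    """
    rng = np.random.default_rng(seed)
    ped = truth.pedigree
    calls: list = []
    labels: list = []
    ref = ped.reference
    for animal in ped.animals:
        if animal != ped.selfself:
            for r in truth.cnvrs:
                cn_t, cn_r = r.cn_of(animal), r.cn_of(ref)
                if cn_t == cn_r:
                    continue
                window = _probe_window(r.start, r.stop, probe_spacing)
                if window is None:
                    continue
                first, last = window
                pos0 = first * probe_spacing + probe_spacing // 2
                stop = min((last * probe_spacing + probe_spacing // 2)
                           + probe_spacing, truth.layout.lengths[r.chrom])
                l2r = math.log2(_effective_cn(cn_t) / _effective_cn(cn_r)) \
                    + rng.normal(0.0, l2r_noise_sd)
                if l2r == 0.0:
                    continue
                calls.append(SegmentCall(
                    animal=animal, chrom=r.chrom, start=pos0, stop=stop,
                    first_probe=first, last_probe=last, l2r=l2r,
                    datapoints=last - first + 1))
                labels.append(LabelRecord(animal, r.chrom, pos0, stop,
                                          "true", r.id))
        n_fp = rng.poisson(fp_rate)
        chroms = sorted(truth.layout.autosomes)
        w = np.array([truth.layout.lengths[c] for c in chroms], dtype=float)
        w /= w.sum()
        made = 0
        attempts = 0
        while made < n_fp and attempts < n_fp * 20:
            attempts += 1
            chrom = chroms[rng.choice(len(chroms), p=w)]
            length = int(rng.integers(*fp_profile.length_range))
            start = int(rng.integers(0, truth.layout.lengths[chrom] - length))
            window = _probe_window(start, start + length, probe_spacing)
            if window is None:
                continue
            first, last = window
            pos0 = first * probe_spacing + probe_spacing // 2
            stop = (last * probe_spacing + probe_spacing // 2) + probe_spacing
            mag = rng.uniform(*fp_profile.absl2r_range)
            l2r = mag if rng.random() < 0.5 else -mag
            calls.append(SegmentCall(
                animal=animal, chrom=chrom, start=pos0, stop=stop,
                first_probe=first, last_probe=last, l2r=l2r,
                datapoints=last - first + 1))
            labels.append(LabelRecord(animal, chrom, pos0, stop, "false", None))
            made += 1
    return calls, labels


# ---------------------------------------------------------------------------
# Read-depth simulation
# ---------------------------------------------------------------------------

def simulate_depth(truth: TruthSet, animals: Sequence[str] | None = None,
                   mu2: float = 30.0, sigma2_sq: float | None = None,
                   sigma0_sq: float = 1.5,
                   gc_bias: Callable | None = None,
                   block: int = 200, seed=None) -> dict:
    """Per-base depth tracks with planted CN structure and optional GC bias.

    Depth is piecewise constant over `block`-bp blocks; block values are drawn
    so that 1-kb bin means follow the target mixture: mean (CN/2)*mu2*bias(GC)
    and variance (CN/2)*sigma2_sq, with half-normal residual depth in CN=0
    regions.  The GC landscape is shared across animals.
    """
    if mu2 <= 0:
        raise ValidationError("mu2 must be positive")
    if sigma2_sq is None:
        sigma2_sq = mu2
    rng = np.random.default_rng(seed)
    layout = truth.layout
    if animals is None:
        animals = list(truth.pedigree.animals)
    blocks_per_bin = BIN_SIZE // block

    # genome GC landscape, shared across animals
    gc_by_chrom = {}
    for chrom in sorted(layout.autosomes):
        n_blocks = layout.lengths[chrom] // block
        p = np.clip(rng.normal(0.42, 0.07, size=n_blocks), 0.2, 0.7)
        # block-constant local GC fraction: equivalent for binning, and
        # run-length encodes compactly on disk
        gc_by_chrom[chrom] = np.repeat(np.round(p, 4), block)

    tracks: dict = {a: {} for a in animals}
    for chrom in sorted(layout.autosomes):
        n_blocks = layout.lengths[chrom] // block
        length = n_blocks * block
        gc = gc_by_chrom[chrom]
        block_gc = gc.reshape(n_blocks, block)[:, 0]
        bias = gc_bias(block_gc) if gc_bias is not None else np.ones(n_blocks)
        for animal in animals:
            cn = np.full(n_blocks, 2, dtype=np.int8)
            for r in truth.cnvrs:
                if r.chrom != chrom:
                    continue
                c = r.cn_of(animal)
                if c != 2:
                    cn[r.start // block: max(r.start // block + 1,
                                             r.stop // block)] = c
            vals = np.empty(n_blocks)
            zero = cn == 0
            if zero.any():
                vals[zero] = np.abs(rng.normal(
                    0.0, math.sqrt(blocks_per_bin * sigma0_sq), size=zero.sum()))
            nz = ~zero
            mean = (cn[nz] / 2.0) * mu2 * bias[nz]
            sd = np.sqrt(blocks_per_bin * (cn[nz] / 2.0) * sigma2_sq)
            vals[nz] = np.maximum(0.0, rng.normal(mean, sd))
            depth = np.repeat(vals, block)
            mask = truth.mask.get(chrom, np.empty((0, 2), dtype=np.int64))
            mask = mask[mask[:, 0] < length] if len(mask) else mask
            if len(mask):
                mask = np.clip(mask, 0, length)
            tracks[animal][chrom] = DepthTrack(chrom=chrom, depth=depth,
                                               mask=mask, gc=gc[:length])
    return tracks


def simulate_mixture_bins(params: MixtureParams, n: int, seed=None) -> tuple:
    """Draw (depths, cn_labels) straight from the five-component mixture."""
    rng = np.random.default_rng(seed)
    cn = rng.choice(5, size=n, p=params.weights)
    d = np.empty(n)
    zero = cn == 0
    d[zero] = np.abs(rng.normal(0.0, math.sqrt(params.sigma0_sq),
                                size=zero.sum()))
    for k in (1, 2, 3, 4):
        sel = cn == k
        d[sel] = rng.normal((k / 2.0) * params.mu2,
                            math.sqrt((k / 2.0) * params.sigma2_sq),
                            size=sel.sum())
    return d, cn


# ---------------------------------------------------------------------------
# Pseudo-platform call sets
# ---------------------------------------------------------------------------

def simulate_platform_calls(truth: TruthSet, sensitivity: float,
                            min_length: int = 0, jitter: int = 0,
                            seed=None, label: str = "platform") -> StudySet:
    """Emit each true CNVR >= min_length with probability `sensitivity`,
    with coordinates jittered by at most `jitter` bp."""
    if not 0.0 <= sensitivity <= 1.0:
        raise ValidationError("sensitivity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    intervals: dict = {}
    for r in truth.cnvrs:
        if r.length < min_length or rng.random() >= sensitivity:
            continue
        j1 = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        j2 = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        s = max(0, r.start + j1)
        e = min(truth.layout.lengths[r.chrom], max(s + 1, r.stop + j2))
        intervals.setdefault(r.chrom, []).append((s, e))
    return StudySet(label=label, intervals={c: as_array(v)
                                            for c, v in intervals.items()})
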
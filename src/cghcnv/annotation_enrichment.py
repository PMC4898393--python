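"""Gene-overlap proportions and Monte-Carlo enrichment testing.

A CNVR overlaps genes if its intersection with the union of coding-sequence
intervals is at least 1 bp.  Duplication vs deletion overlap proportions are
compared with a 2x2 chi-square; enrichment against random placement is
tested by redistributing the CNVRs uniformly (lengths preserved, >1,500 bp
spacing) and ranking the observed proportion among the simulated ones.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._intervals import as_array, overlaps_any
from .cnvr_analysis import MERGE_GAP, place_lengths
from .data_model_io import Cnvr, GenomeLayout
from .errors import ValidationError

log = logging.getLogger(__name__)

TYPES = ("deletion", "duplication", "both")


@dataclass(frozen=True)
class OverlapResult:
    proportions: Mapping[str, float]   # per type + "all"
    overlapping: tuple                 # CNVRs overlapping genes
    counts: Mapping[str, tuple]        # type -> (n_overlap, n_total)


def gene_overlap(cnvrs: Sequence[Cnvr],
                 cds: Mapping[str, np.ndarray],
                 min_overlap: int = 1) -> OverlapResult:
    """Per-type proportions of CNVRs overlapping the CDS union by >= 1 bp."""
    overlapping = []
    counts = {t: [0, 0] for t in TYPES}
    counts["all"] = [0, 0]
    by_chrom: dict = {}
    for i, r in enumerate(cnvrs):
        by_chrom.setdefault(r.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        subject = cds.get(chrom, np.empty((0, 2), dtype=np.int64))
        q = np.array([(cnvrs[i].start, cnvrs[i].stop) for i in idxs],
                     dtype=np.int64)
        hits = overlaps_any(q, subject, min_overlap=min_overlap)
        for i, hit in zip(idxs, hits):
            r = cnvrs[i]
            for key in (r.type, "all"):
                counts[key][1] += 1
                counts[key][0] += int(hit)
            if hit:
                overlapping.append(r)
    props = {t: (c[0] / c[1] if c[1] else float("nan"))
             for t, c in counts.items()}
    return OverlapResult(proportions=props, overlapping=tuple(overlapping),
                         counts={t: tuple(c) for t, c in counts.items()})


def dup_del_test(n_dup_overlap: int, n_dup: int,
                 n_del_overlap: int, n_del: int,
                 correction: bool = False) -> tuple:
    """2x2 chi-square (no continuity correction by default) comparing the
    duplication and deletion gene-overlap proportions.  Returns (stat, p)."""
    if min(n_dup_overlap, n_del_overlap) < 0 or n_dup <= 0 or n_del <= 0:
        raise ValidationError("invalid counts")
    table = np.array([[n_dup_overlap, n_dup - n_dup_overlap],
                      [n_del_overlap, n_del - n_del_overlap]])
    if np.any(table < 0):
        raise ValidationError("overlap count exceeds total")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("zero margin in 2x2 table")
    if table[0, 1] == 0 and table[1, 1] == 0:
        raise ValidationError("zero margin in 2x2 table")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class EnrichmentResult:
    observed: Mapping[str, float]
    simulated: Mapping[str, np.ndarray]
    pvalues: Mapping[str, float]
    chi2_stat: float
    chi2_p: float
    n_iter: int
    seed: object
    convention: str


def empirical_p(observed: float, simulated: np.ndarray,
                convention: str = "add-one-two-tailed") -> float:
    """Empirical p from ranking the observed value among simulated ones.

    add-one-two-tailed: p = min(1, 2 * min(1 + #{sim >= obs}, 1 + #{sim <= obs})
    / (n + 1)).  one-sided: p = (1 + #{sim >= obs}) / (n + 1).
    """
    sim = np.asarray(simulated, dtype=float)
    n = len(sim)
    r_hi = 1 + int(np.sum(sim >= observed))
    r_lo = 1 + int(np.sum(sim <= observed))
    if convention == "one-sided":
        return r_hi / (n + 1)
    if convention == "add-one-two-tailed":
        return min(1.0, 2.0 * min(r_hi, r_lo) / (n + 1))
    raise ValidationError(f"unknown p convention {convention!r}")


def permute_enrichment(cnvrs: Sequence[Cnvr],
                       cds: Mapping[str, np.ndarray],
                       layout: GenomeLayout,
                       n_iter: int = 100, seed=None,
                       min_spacing: int = MERGE_GAP,
                       convention: str = "add-one-two-tailed") -> EnrichmentResult:
    """Monte-Carlo test of gene-overlap enrichment under random placement.

    Each iteration redistributes all CNVRs (lengths and types preserved)
    uniformly over the autosomes with the merge-distance spacing constraint
    and recomputes per-type overlap proportions.
    """
    if n_iter < 20:
        log.warning("n_iter=%d gives coarse p-value resolution", n_iter)
    rng = np.random.default_rng(seed)
    obs = gene_overlap(cnvrs, cds)
    lengths = np.array([r.length for r in cnvrs], dtype=np.int64)
    types = [r.type for r in cnvrs]
    sim_props: dict = {t: [] for t in list(TYPES) + ["all"]}
    for _ in range(n_iter):
        placed = place_lengths(lengths, layout, min_spacing=min_spacing,
                               seed=rng)
        fake = [Cnvr(chrom=chrom, start=s, stop=e, type=types[j],
                     animals=frozenset({"sim"}))
                for j, (chrom, s, e) in enumerate(placed)]
        res = gene_overlap(fake, cds)
        for t in sim_props:
            sim_props[t].append(res.proportions[t])
    sim_arr = {t: np.array(v, dtype=float) for t, v in sim_props.items()}
    pvals = {}
    for t in sim_arr:
        o = obs.proportions[t]
        valid = ~np.isnan(sim_arr[t])
        pvals[t] = (empirical_p(o, sim_arr[t][valid], convention)
                    if not np.isnan(o) and valid.any() else float("nan"))
    n_dup_overlap, n_dup = obs.counts["duplication"]
    n_del_overlap, n_del = obs.counts["deletion"]
    try:
        chi2_stat, chi2_p = dup_del_test(n_dup_overlap, n_dup,
                                         n_del_overlap, n_del)
    except ValidationError:
        chi2_stat = chi2_p = float("nan")
    return EnrichmentResult(observed=obs.proportions, simulated=sim_arr,
                            pvalues=pvals, chi2_stat=chi2_stat, chi2_p=chi2_p,
                            n_iter=n_iter, seed=seed, convention=convention)
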
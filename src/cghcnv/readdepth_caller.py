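"""Copy-number calling from sequencing read depth.

Depth is summarised in 1-kb sliding-window bins (200-bp step) over unmasked
positions, corrected for GC content by per-stratum median scaling, and
modelled per chromosome as a five-component mixture: a half-normal at zero
for CN=0 and normals for CN=1..4 whose means and variances are (k/2) times
the diploid mean and variance.  Seven free parameters (mu2, sigma2^2,
sigma0^2 and four mixture weights) are fit by bounded numerical maximisation
of the mixture log-likelihood; each bin is then assigned the CN class with
the largest weighted density.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from ._intervals import as_array, overlap_lengths
from .data_model_io import Cnvr, DepthTrack
from .errors import MixtureFitError, ValidationError

log = logging.getLogger(__name__)

BIN_SIZE = 1000
BIN_STEP = 200
CN_CLASSES = (0, 1, 2, 3, 4)

# Box bounds on the seven free parameters: mu2, sigma2^2, sigma0^2,
# pi0, pi1, pi3, pi4.  The four weight caps guarantee pi2 >= 0.5.
PARAM_BOUNDS = ((None, None), (1e-9, None), (0.01, None),
                (0.0, 0.05), (0.0, 0.2), (0.0, 0.2), (0.0, 0.05))
START_WEIGHTS = (0.01, 0.025, 0.001, 0.001)  # pi0, pi1, pi3, pi4
START_SIGMA0_SQ = 1.5


@dataclass(frozen=True)
class MixtureParams:
    """Free parameters of the per-chromosome depth mixture."""
    mu2: float
    sigma2_sq: float
    sigma0_sq: float
    pi0: float
    pi1: float
    pi3: float
    pi4: float

    def __post_init__(self):
        if self.sigma2_sq <= 0:
            raise ValidationError("sigma2_sq must be positive")
        if self.sigma0_sq < 0.01 - 1e-12:
            raise ValidationError("sigma0_sq below its 0.01 lower bound")
        for name, cap in (("pi0", 0.05), ("pi1", 0.2), ("pi3", 0.2), ("pi4", 0.05)):
            v = getattr(self, name)
            if v < -1e-12 or v > cap + 1e-9:
                raise ValidationError(f"{name}={v} outside [0, {cap}]")
        if self.pi2 < -1e-9:
            raise ValidationError("mixture weights sum above 1")

    @property
    def pi2(self) -> float:
        return 1.0 - self.pi0 - self.pi1 - self.pi3 - self.pi4

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.pi0, self.pi1, self.pi2, self.pi3, self.pi4])

    def to_vector(self) -> np.ndarray:
        return np.array([self.mu2, self.sigma2_sq, self.sigma0_sq,
                         self.pi0, self.pi1, self.pi3, self.pi4])

    @classmethod
    def from_vector(cls, v) -> "MixtureParams":
        return cls(mu2=float(v[0]), sigma2_sq=float(v[1]), sigma0_sq=float(v[2]),
                   pi0=float(v[3]), pi1=float(v[4]), pi3=float(v[5]), pi4=float(v[6]))


@dataclass
class DepthBins:
    """Column-oriented table of depth bins for one chromosome."""
    chrom: str
    start: np.ndarray          # genomic start of each 1-kb window
    width: np.ndarray          # unmasked positions per window
    gc_frac: np.ndarray        # GC fraction over unmasked positions
    raw: np.ndarray            # mean depth over unmasked positions
    corrected: np.ndarray | None = None
    cn: np.ndarray | None = None
    posteriors: np.ndarray | None = None  # (n, 5)
    bin_size: int = BIN_SIZE

    def __len__(self) -> int:
        return len(self.start)

    @property
    def stop(self) -> np.ndarray:
        return self.start + self.bin_size


def bin_depth(track: DepthTrack, bin_size: int = BIN_SIZE, step: int = BIN_STEP,
              max_depth: float | None = None,
              max_depth_quantile: float = 0.999) -> DepthBins:
    """Summarise a depth track into overlapping bins.

    Bin means are computed over unmasked positions only.  Bins containing any
    unmasked position whose depth exceeds the per-chromosome maximum-depth
    threshold (default: the 99.9th percentile of unmasked per-base depth) are
    deleted, as are fully masked bins.
    """
    if bin_size % step != 0:
        raise ValidationError(f"bin size {bin_size} is not a multiple of step {step}")
    d = track.depth
    n = len(d)
    if n < bin_size:
        return DepthBins(track.chrom, *(np.empty(0, dtype=t) for t in
                                        (np.int64, np.int64, float, float)),
                         bin_size=bin_size)
    unmasked = ~track.masked_bool()
    if max_depth is None:
        vals = d[unmasked]
        max_depth = float(np.quantile(vals, max_depth_quantile)) if len(vals) else np.inf
    starts = np.arange(0, n - bin_size + 1, step, dtype=np.int64)

    cum_cnt = np.concatenate([[0], np.cumsum(unmasked)])
    cum_sum = np.concatenate([[0.0], np.cumsum(d * unmasked)])
    too_deep = unmasked & (d > max_depth)
    cum_bad = np.concatenate([[0], np.cumsum(too_deep)])
    gc = track.gc if track.gc is not None else np.zeros(n)
    cum_gc = np.concatenate([[0.0], np.cumsum(gc.astype(np.float64) * unmasked)])

    stops = starts + bin_size
    cnt = cum_cnt[stops] - cum_cnt[starts]
    bad = cum_bad[stops] - cum_bad[starts]
    keep = (cnt > 0) & (bad == 0)
    starts, cnt = starts[keep], cnt[keep]
    stops = stops[keep]
    raw = (cum_sum[stops] - cum_sum[starts]) / cnt
    gc_frac = (cum_gc[stops] - cum_gc[starts]) / cnt
    return DepthBins(chrom=track.chrom, start=starts, width=cnt,
                     gc_frac=gc_frac, raw=raw, bin_size=bin_size)


def gc_correct(bins: DepthBins, min_stratum: int = 20) -> DepthBins:
    """Median-scaling GC correction.

    corrected = raw * (global median) / (median of the bin's integer-percent
    GC stratum); strata with fewer than min_stratum bins are left uncorrected.
    """
    if len(bins) == 0:
        bins.corrected = bins.raw.copy() if bins.raw is not None else bins.raw
        return bins
    gmed = float(np.median(bins.raw))
    if gmed <= 0:
        raise ValidationError(f"{bins.chrom}: zero global median depth; track unusable")
    stratum = np.rint(bins.gc_frac * 100).astype(int)
    corrected = bins.raw.copy()
    for s in np.unique(stratum):
        idx = stratum == s
        if idx.sum() < min_stratum:
            continue
        smed = float(np.median(bins.raw[idx]))
        if smed > 0:
            corrected[idx] = bins.raw[idx] * (gmed / smed)
    bins.corrected = corrected
    return bins


def _log_densities(d: np.ndarray, p: MixtureParams) -> np.ndarray:
    """(n, 5) log density of each CN component at the given depths."""
    d = np.asarray(d, dtype=float)
    out = np.empty((len(d), 5))
    # CN=0: half-normal at zero with scale sigma0
    out[:, 0] = (0.5 * np.log(2.0 / (np.pi * p.sigma0_sq))
                 - d ** 2 / (2.0 * p.sigma0_sq))
    out[d < 0, 0] = -np.inf
    for j, k in enumerate((1, 2, 3, 4), start=1):
        var = (k / 2.0) * p.sigma2_sq
        mean = (k / 2.0) * p.mu2
        out[:, j] = -0.5 * np.log(2.0 * np.pi * var) - (d - mean) ** 2 / (2.0 * var)
    return out


def mixture_loglik(d: np.ndarray, p: MixtureParams) -> float:
    logd = _log_densities(d, p)
    with np.errstate(divide="ignore"):
        logw = np.log(p.weights)
    m = logd + logw
    mx = m.max(axis=1)
    return float(np.sum(mx + np.log(np.sum(np.exp(m - mx[:, None]), axis=1))))


def _loglik_and_grad(d: np.ndarray, p: MixtureParams) -> tuple:
    """Mixture log-likelihood and its analytic gradient in the 7 parameters.

    Finite-difference gradients are too noisy at this likelihood scale for
    the box-constrained quasi-Newton optimizer to converge reliably.
    """
    logd = _log_densities(d, p)
    with np.errstate(divide="ignore"):
        logw = np.log(p.weights)
    m = logd + logw
    mx = m.max(axis=1)
    se = np.exp(m - mx[:, None])
    s = se.sum(axis=1)
    ll = float(np.sum(mx + np.log(s)))
    post = se / s[:, None]  # responsibilities w_ik

    grad = np.zeros(7)
    ks = np.array([1.0, 2.0, 3.0, 4.0])
    means = (ks / 2.0) * p.mu2
    varis = (ks / 2.0) * p.sigma2_sq
    resid = d[:, None] - means[None, :]
    wn = post[:, 1:5]
    # mu2 and sigma2^2 through the four normal components
    grad[0] = float(np.sum(wn * resid / varis[None, :] * (ks / 2.0)[None, :]))
    grad[1] = float(np.sum(wn * (ks / 2.0)[None, :]
                           * (-0.5 / varis[None, :]
                              + resid ** 2 / (2.0 * varis[None, :] ** 2))))
    # sigma0^2 through the half-normal
    grad[2] = float(np.sum(post[:, 0] * (-0.5 / p.sigma0_sq
                                         + d ** 2 / (2.0 * p.sigma0_sq ** 2))))
    # free weights pi0, pi1, pi3, pi4 (pi2 absorbs the complement)
    f = np.exp(logd - mx[:, None]) / s[:, None]
    for gi, col in zip((3, 4, 5, 6), (0, 1, 3, 4)):
        grad[gi] = float(np.sum(f[:, col] - f[:, 2]))
    return ll, grad


@dataclass(frozen=True)
class MixtureFit:
    params: MixtureParams
    loglik: float
    start_loglik: float
    converged: bool
    n_bins: int


def fit_mixture(depths: np.ndarray, min_bins: int = 500,
                start: MixtureParams | None = None,
                tol: float = 1e-8) -> MixtureFit:
    """Fit the depth mixture by bounded quasi-Newton likelihood maximisation.

    Raises MixtureFitError on too few bins, degenerate input or failed
    convergence; callers handle failures via fallback_params.
    """
    d = np.asarray(depths, dtype=float)
    if len(d) < min_bins:
        raise MixtureFitError(f"too few bins ({len(d)} < {min_bins})")
    if start is None:
        mean, var = float(np.mean(d)), float(np.var(d, ddof=1))
        if var <= 0 or not np.isfinite(var):
            raise MixtureFitError("degenerate depth distribution (zero variance)")
        starts = [MixtureParams(mean, var, START_SIGMA0_SQ, *START_WEIGHTS)]
        # The sample variance is inflated by the non-diploid components and
        # can trap the optimizer; add a robust (median / scaled-MAD) start
        # and keep whichever optimum achieves the higher likelihood.
        med = float(np.median(d))
        mad_sq = (1.4826 * float(np.median(np.abs(d - med)))) ** 2
        if mad_sq > 0:
            for f in (1.0, 0.7, 0.5):
                starts.append(MixtureParams(med, f * mad_sq, START_SIGMA0_SQ,
                                            *START_WEIGHTS))
    else:
        starts = [start]
    start_ll = mixture_loglik(d, starts[0])

    def nll_and_grad(x):
        try:
            p = MixtureParams.from_vector(x)
        except ValidationError:
            return np.inf, np.zeros(7)
        ll, grad = _loglik_and_grad(d, p)
        if not np.isfinite(ll):
            return np.inf, np.zeros(7)
        return -ll, -grad

    res = None
    for s in starts:
        r = optimize.minimize(nll_and_grad, s.to_vector(), jac=True,
                              method="L-BFGS-B", bounds=PARAM_BOUNDS,
                              options={"ftol": tol, "maxiter": 1000})
        if r.success and np.isfinite(r.fun) and (res is None or r.fun < res.fun):
            res = r
    if res is None:
        raise MixtureFitError("optimizer failed from every start")
    params = MixtureParams.from_vector(res.x)
    ll = -float(res.fun)
    if ll < start_ll - 1e-6:
        raise MixtureFitError("optimizer returned a worse likelihood than the start")
    return MixtureFit(params=params, loglik=ll, start_loglik=start_ll,
                      converged=True, n_bins=len(d))


def fallback_params(fits: Mapping[str, MixtureParams | None]) -> dict:
    """Replace failed chromosomes (None) with the mean of successful fits.

    Averaged weights are renormalised if numerical drift would push pi2
    below zero (cannot happen under the box bounds, but kept as a guard).
    """
    good = {c: p for c, p in fits.items() if p is not None}
    if not good:
        raise MixtureFitError("no chromosome produced a successful mixture fit")
    mats = np.stack([p.to_vector() for p in good.values()])
    mean_vec = mats.mean(axis=0)
    wsum = mean_vec[3:].sum()
    if wsum > 1.0:
        mean_vec[3:] /= wsum
    mean_params = MixtureParams.from_vector(mean_vec)
    return {c: (p if p is not None else mean_params) for c, p in fits.items()}


def assign_cn(bins: DepthBins, params: MixtureParams) -> DepthBins:
    """Assign each bin the CN class maximising weight * density.

    Posterior weights are stored; exact ties break toward CN=2.
    """
    d = bins.corrected if bins.corrected is not None else bins.raw
    logd = _log_densities(d, params)
    with np.errstate(divide="ignore"):
        scores = logd + np.log(params.weights)
    cn = np.argmax(scores, axis=1)
    best = scores[np.arange(len(d)), cn]
    tie_with_2 = scores[:, 2] == best
    cn[tie_with_2] = 2
    mx = np.max(scores, axis=1, keepdims=True)
    w = np.exp(scores - mx)
    bins.posteriors = w / w.sum(axis=1, keepdims=True)
    bins.cn = cn.astype(np.int8)
    return bins


def call_track(track: DepthTrack, params: MixtureParams | None = None,
               **bin_kwargs) -> tuple:
    """bin -> GC-correct -> (fit if needed) -> assign; returns (bins, fit)."""
    bins = gc_correct(bin_depth(track, **bin_kwargs))
    fit = None
    if params is None:
        fit = fit_mixture(bins.corrected)
        params = fit.params
    return assign_cn(bins, params), fit


VERIFIED_STATUSES = ("verified-consistent", "verified-reference-effect",
                     "verified-discordant-type")


def _has_type(cn_values: np.ndarray, typ: str) -> bool:
    if typ == "deletion":
        return bool(np.any(cn_values < 2))
    if typ == "duplication":
        return bool(np.any(cn_values > 2))
    return bool(np.any(cn_values != 2))  # both


def _opposite(typ: str) -> str:
    return {"deletion": "duplication", "duplication": "deletion",
            "both": "both"}[typ]


def verify_cnvrs_by_depth(cnvrs: Sequence[Cnvr],
                          test_bins: Mapping[str, DepthBins],
                          ref_bins: Mapping[str, DepthBins]) -> list:
    """Verify array CNVRs against read-depth CN assignments.

    Per CNVR: 'verified-consistent' if any test-animal bin shows a CNV of the
    array call type; 'verified-reference-effect' if the test animal is
    CN-normal but the reference shows the opposite type (an array deletion is
    induced by a reference duplication, and vice versa);
    'verified-discordant-type' if both animals show CNV bins but not of the
    expected type; otherwise 'not-verified'.  CNVRs with no overlapping bins
    in either animal are 'untestable' and excluded from rates.
    """
    out = []
    for r in cnvrs:
        t_cn = _bins_in(test_bins.get(r.chrom), r)
        r_cn = _bins_in(ref_bins.get(r.chrom), r)
        if len(t_cn) == 0 and len(r_cn) == 0:
            out.append((r, "untestable"))
            continue
        if _has_type(t_cn, r.type):
            out.append((r, "verified-consistent"))
        elif not np.any(t_cn != 2) and _has_type(r_cn, _opposite(r.type)):
            out.append((r, "verified-reference-effect"))
        elif np.any(t_cn != 2) and np.any(r_cn != 2):
            out.append((r, "verified-discordant-type"))
        else:
            out.append((r, "not-verified"))
    return out


def _bins_in(bins: DepthBins | None, r: Cnvr) -> np.ndarray:
    if bins is None or len(bins) == 0 or bins.cn is None:
        return np.empty(0, dtype=np.int8)
    spans = np.stack([bins.start, bins.stop], axis=1)
    hit = overlap_lengths(spans, as_array([(r.start, r.stop)])) >= 1
    return bins.cn[hit]
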
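"""Trio-trained logistic classification of CGH segment calls.

Training positives are progeny calls seen at identical probe boundaries in a
parent; negatives are self-self hybridisation calls.  A forward stepwise
logistic regression selects predictive transforms of the segment's absolute
log2 ratio, length and probe count; the fitted model scores every call with
the probability that it represents a true CNV.
"""
from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model_io import SegmentCall
from .errors import DomainError, TrainingError

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.96, 0.97, 0.98, 0.99)

# Main-effect candidate terms for stepwise selection.
MAIN_TERMS = ("absl2r", "is_del", "length", "ln_length", "lnln_length",
              "length_sq", "datapoints", "ln_datapoints", "lnln_datapoints",
              "datapoints_sq")


def _term_values(calls: Sequence[SegmentCall]) -> pd.DataFrame:
    length = np.array([c.length for c in calls], dtype=float)
    dp = np.array([c.datapoints for c in calls], dtype=float)
    return pd.DataFrame({
        "absl2r": [c.absl2r for c in calls],
        "is_del": [1.0 if c.l2r < 0 else 0.0 for c in calls],
        "length": length,
        "ln_length": np.log(length),
        "lnln_length": np.log(np.log(length)),
        "length_sq": length ** 2,
        "datapoints": dp,
        "ln_datapoints": np.log(dp),
        "lnln_datapoints": np.log(np.log(dp)),
        "datapoints_sq": dp ** 2,
    })


def _design_matrix(frame: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    cols = {}
    for term in terms:
        if "*" in term:
            parts = term.split("*")
            v = frame[parts[0]].to_numpy().copy()
            for p in parts[1:]:
                v = v * frame[p].to_numpy()
            cols[term] = v
        else:
            cols[term] = frame[term].to_numpy()
    return pd.DataFrame(cols, index=frame.index)


@dataclass(frozen=True)
class LogisticModel:
    """logit(p) = intercept + sum coef_i * term_i."""
    intercept: float
    coefficients: Mapping[str, float]
    threshold: float = 0.95
    separation_flagged: bool = False

    def logit(self, call: SegmentCall) -> float:
        frame = _term_values([call])
        x = 0.0
        for term, coef in self.coefficients.items():
            x += coef * float(_design_matrix(frame, [term]).iloc[0, 0])
        return self.intercept + x

    def terms(self) -> tuple:
        return tuple(self.coefficients)


#: Coefficients of the final reported model, threshold 0.95.
PUBLISHED_MODEL = LogisticModel(
    intercept=-0.19,
    coefficients={"absl2r": 29.51, "lnln_length": -4.91, "lnln_datapoints": 8.24},
    threshold=0.95,
)


@dataclass(frozen=True)
class TrainingRecord:
    call: SegmentCall
    outcome: int  # 1 = trio-validated, 0 = self-self

    def __post_init__(self):
        if self.outcome not in (0, 1):
            raise TrainingError(f"outcome {self.outcome} not binary")


def validate_trios(progeny_calls: Iterable[SegmentCall],
                   sire_calls: Iterable[SegmentCall],
                   dam_calls: Iterable[SegmentCall]) -> list:
    """Progeny calls matching a parent call at identical probe boundaries.

    Identity means same chromosome and same first AND last probe index (hence
    same genomic start and stop).  Call type is not required to match.
    """
    parent_keys = {(c.chrom, c.first_probe, c.last_probe)
                   for c in itertools.chain(sire_calls, dam_calls)}
    return [c for c in progeny_calls
            if (c.chrom, c.first_probe, c.last_probe) in parent_keys]


def build_training_set(validated_calls: Iterable[SegmentCall],
                       selfself_calls: Iterable[SegmentCall],
                       autosomes) -> list:
    """Assemble TrainingRecords; only autosomal calls are used."""
    autosomes = set(autosomes)
    records, dropped = [], 0
    for outcome, calls in ((1, validated_calls), (0, selfself_calls)):
        for c in calls:
            if c.chrom in autosomes:
                records.append(TrainingRecord(call=c, outcome=outcome))
            else:
                dropped += 1
    if dropped:
        log.info("dropped %d non-autosomal training call(s)", dropped)
    outcomes = {r.outcome for r in records}
    if outcomes != {0, 1}:
        raise TrainingError("training set must contain both validated and "
                            "self-self calls")
    return records


def predict_p(model: LogisticModel, call: SegmentCall) -> float:
    """Model probability that the call is a true CNV.

    Double-log transforms require length >= 2 and datapoints >= 2.
    """
    if call.length < 2 or call.datapoints < 2:
        raise DomainError(
            f"call {call.animal}:{call.chrom}:{call.start}: length and "
            f"datapoints must be >= 2 for the double-log transforms")
    z = model.logit(call)
    # numerically safe sigmoid
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def predict_batch(model: LogisticModel, calls: Sequence[SegmentCall]) -> np.ndarray:
    """Vectorised predict_p; out-of-domain calls get p = 0 (auto-reject)."""
    p = np.zeros(len(calls), dtype=float)
    ok = [i for i, c in enumerate(calls) if c.length >= 2 and c.datapoints >= 2]
    if not ok:
        return p
    frame = _term_values([calls[i] for i in ok])
    x = np.full(len(ok), model.intercept, dtype=float)
    design = _design_matrix(frame, list(model.coefficients))
    for term, coef in model.coefficients.items():
        x += coef * design[term].to_numpy()
    p[ok] = 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))
    return p


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Fit a logit with an intercept; returns the statsmodels result or None."""
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception:
            return None
    if not np.all(np.isfinite(res.params)):
        return None
    return res


def _interactions(selected_mains: Sequence[str]) -> list:
    """2- and 3-way interactions among already-selected main effects."""
    out = []
    for k in (2, 3):
        for combo in itertools.combinations(selected_mains, k):
            out.append("*".join(combo))
    return out


def stepwise_fit(records: Sequence[TrainingRecord],
                 enter_p: float = 0.3, stay_p: float = 0.35,
                 candidate_terms: Sequence[str] | None = None,
                 threshold: float = 0.95,
                 max_steps: int = 30) -> LogisticModel:
    """Forward stepwise logistic regression on Wald chi-square p-values.

    A term enters if its Wald p <= enter_p (ties broken by the larger Wald
    statistic) and is removed if its p in the updated model exceeds stay_p.
    Interactions are constructed among selected main effects only, keeping
    the candidate set finite.  Deterministic given fixed record order.
    """
    y = np.array([r.outcome for r in records], dtype=float)
    if len(set(y)) < 2:
        raise TrainingError("outcome is constant; model unfittable")
    frame = _term_values([r.call for r in records])
    mains = list(candidate_terms) if candidate_terms is not None else list(MAIN_TERMS)
    selected: list = []
    separation = False

    for _ in range(max_steps):
        pool = [t for t in mains if t not in selected]
        pool += [t for t in _interactions([s for s in selected if "*" not in s])
                 if t not in selected]
        best = None  # (p, -wald, term)
        for term in pool:
            X = _design_matrix(frame, selected + [term])
            if np.ptp(X[term].to_numpy()) == 0:
                continue
            res = _fit_logit(y, X)
            if res is None:
                continue
            wald = (res.params[term] / res.bse[term]) ** 2 if res.bse[term] > 0 else np.inf
            pval = res.pvalues[term]
            if not np.isfinite(pval):
                continue
            cand = (pval, -wald, term)
            if best is None or cand < best:
                best = cand
        if best is None or best[0] > enter_p:
            break
        selected.append(best[2])
        # backward pass: drop terms whose p now exceeds stay_p
        while True:
            res = _fit_logit(y, _design_matrix(frame, selected))
            if res is None:
                separation = True
                break
            worst = max(selected, key=lambda t: res.pvalues[t])
            if res.pvalues[worst] > stay_p:
                selected.remove(worst)
                if not selected:
                    break
            else:
                break

    if not selected:
        res = _fit_logit(y, pd.DataFrame(index=frame.index))
        intercept = float(res.params["const"]) if res is not None else float(
            np.log(y.mean() / (1 - y.mean())))
        return LogisticModel(intercept=intercept, coefficients={},
                             threshold=threshold, separation_flagged=separation)

    res = _fit_logit(y, _design_matrix(frame, selected))
    if res is None or np.abs(res.params).max() > 1e6:
        # perfect separation: fall back to a lightly penalized fit
        log.warning("perfect separation detected; using penalized fallback fit")
        separation = True
        Xc = sm.add_constant(_design_matrix(frame, selected), has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit_regularized(alpha=1.0, disp=0, maxiter=500)
    coefs = {t: float(res.params[t]) for t in selected}
    return LogisticModel(intercept=float(res.params["const"]), coefficients=coefs,
                         threshold=threshold, separation_flagged=separation)


@dataclass(frozen=True)
class CrossvalResult:
    accuracy: Mapping[float, float]
    selected_threshold: float
    predictions: np.ndarray = field(repr=False, default=None)


def loo_crossvalidate(records: Sequence[TrainingRecord],
                      model: LogisticModel,
                      thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                      selected_threshold: float = 0.95) -> CrossvalResult:
    """Leave-one-out crossvalidation of the selected term set.

    Each record is left out in turn, the coefficients are refit on the rest
    (the term set itself is not re-selected), and the left-out record is
    scored.  Accuracy per threshold is the fraction of records whose
    thresholded prediction matches the label.
    """
    n = len(records)
    if n < 10:
        raise TrainingError("need >= 10 records for crossvalidation")
    y = np.array([r.outcome for r in records], dtype=float)
    if len(set(y)) < 2:
        raise TrainingError("outcome is constant")
    frame = _term_values([r.call for r in records])
    terms = list(model.coefficients)
    X = _design_matrix(frame, terms) if terms else pd.DataFrame(index=frame.index)
    preds = np.full(n, np.nan)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        if len(set(y[keep])) < 2:
            log.warning("fold %d skipped: a class is absent after omission", i)
            continue
        res = _fit_logit(y[keep], X.iloc[keep])
        if res is None:
            log.warning("fold %d skipped: refit failed", i)
            continue
        xi = np.concatenate([[1.0], X.iloc[i].to_numpy()]) if terms else np.array([1.0])
        z = float(np.dot(res.params.to_numpy(), xi))
        preds[i] = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
    valid = ~np.isnan(preds)
    acc = {}
    for t in thresholds:
        acc[t] = float(np.mean((preds[valid] >= t) == (y[valid] == 1)))
    return CrossvalResult(accuracy=acc, selected_threshold=selected_threshold,
                          predictions=preds)
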
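import math

import numpy as np
import pytest

from cghcnv.data_model_io import SegmentCall
from cghcnv.errors import DomainError, TrainingError
from cghcnv.segment_classifier import (DEFAULT_THRESHOLDS, PUBLISHED_MODEL,
                                       LogisticModel, TrainingRecord,
                                       build_training_set, loo_crossvalidate,
                                       predict_batch, predict_p, stepwise_fit,
                                       validate_trios)
from tests.conftest import make_call


def hand_logit(absl2r, length, datapoints):
    """Independent evaluation of the published equation."""
    return (-0.19 + 29.51 * absl2r
            - 4.91 * math.log(math.log(length))
            + 8.24 * math.log(math.log(datapoints)))


def hand_p(absl2r, length, datapoints):
    return 1.0 / (1.0 + math.exp(-hand_logit(absl2r, length, datapoints)))


def simulate_records(n, seed, spacing=1250):
    """Generative oracle: features drawn broadly, labels Bernoulli(published p)."""
    rng = np.random.default_rng(seed)
    calls = []
    for _ in range(n):
        length = int(np.exp(rng.uniform(np.log(1000), np.log(200_000))))
        dp = max(2, int(rng.poisson(length / spacing)))
        absl2r = rng.uniform(0.05, 0.8)
        sign = -1.0 if rng.random() < 0.5 else 1.0
        calls.append(SegmentCall("A", "chr1", 0, length, 0, dp - 1,
                                 sign * absl2r, dp))
    p = predict_batch(PUBLISHED_MODEL, calls)
    y = (rng.random(n) < p).astype(int)
    return [TrainingRecord(c, int(o)) for c, o in zip(calls, y)]


class TestPredictP:
    def test_hand_evaluation_high(self):
        call = make_call(length=28_706, datapoints=9, l2r=0.54)
        assert predict_p(PUBLISHED_MODEL, call) == pytest.approx(
            hand_p(0.54, 28_706, 9), rel=1e-12)
        assert predict_p(PUBLISHED_MODEL, call) == pytest.approx(0.99998, abs=1e-5)

    def test_hand_evaluation_low(self):
        call = make_call(length=1003, datapoints=3, l2r=0.25)
        assert predict_p(PUBLISHED_MODEL, call) == pytest.approx(
            hand_p(0.25, 1003, 3), rel=1e-12)
        assert predict_p(PUBLISHED_MODEL, call) == pytest.approx(0.178, abs=1e-3)

    def test_null_model_gives_half(self):
        null = LogisticModel(intercept=0.0, coefficients={"absl2r": 0.0})
        assert predict_p(null, make_call()) == 0.5

    def test_domain_error(self):
        with pytest.raises(DomainError):
            predict_p(PUBLISHED_MODEL, make_call(length=5000, datapoints=1))

    def test_batch_auto_rejects_out_of_domain(self):
        calls = [make_call(), make_call(datapoints=1)]
        p = predict_batch(PUBLISHED_MODEL, calls)
        assert p[0] > 0 and p[1] == 0.0

    def test_batch_matches_scalar(self, rng):
        calls = [make_call(length=int(l), datapoints=int(d), l2r=float(r))
                 for l, d, r in zip(rng.integers(1000, 100_000, 50),
                                    rng.integers(2, 40, 50),
                                    rng.uniform(-1, 1, 50))]
        batch = predict_batch(PUBLISHED_MODEL, calls)
        for c, pb in zip(calls, batch):
            assert pb == pytest.approx(predict_p(PUBLISHED_MODEL, c), rel=1e-12)

    def test_monotonicity_properties(self, rng):
        # strictly increasing in absl2r and datapoints, decreasing in length
        for _ in range(200):
            length = int(rng.integers(1000, 200_000))
            dp = int(rng.integers(2, 50))
            r = float(rng.uniform(0.05, 1.5))
            base_c = make_call(length=length, datapoints=dp, l2r=r)
            up_r_c = make_call(length=length, datapoints=dp, l2r=r + 0.05)
            up_dp_c = make_call(length=length, datapoints=dp + 1, l2r=r)
            up_len_c = make_call(length=length + 5000, datapoints=dp, l2r=r)
            base = PUBLISHED_MODEL.logit(base_c)
            # strict on the logit scale (p saturates in float arithmetic)
            assert PUBLISHED_MODEL.logit(up_r_c) > base
            assert PUBLISHED_MODEL.logit(up_dp_c) > base
            assert PUBLISHED_MODEL.logit(up_len_c) < base
            p0 = predict_p(PUBLISHED_MODEL, base_c)
            assert predict_p(PUBLISHED_MODEL, up_r_c) >= p0
            assert predict_p(PUBLISHED_MODEL, up_len_c) <= p0


class TestValidateTrios:
    def test_identical_boundaries_validate(self):
        child = [make_call(animal="C", first_probe=10, datapoints=5)]
        sire = [make_call(animal="S", first_probe=10, datapoints=5)]
        assert validate_trios(child, sire, []) == child

    def test_differing_boundary_not_validated(self):
        child = [make_call(animal="C", first_probe=10, datapoints=5)]
        dam = [make_call(animal="D", first_probe=10, datapoints=6)]
        assert validate_trios(child, [], dam) == []

    def test_empty_parents(self):
        child = [make_call(animal="C")]
        assert validate_trios(child, [], []) == []

    def test_type_not_required_to_match(self):
        child = [make_call(animal="C", l2r=-0.5)]
        sire = [make_call(animal="S", l2r=+0.5)]
        assert validate_trios(child, sire, []) == child


class TestBuildTrainingSet:
    def test_counts(self):
        val = [make_call(animal=f"C{i}") for i in range(10)]
        ss = [make_call(animal="REF", l2r=0.15) for _ in range(5)]
        recs = build_training_set(val, ss, {"chr1"})
        assert len(recs) == 15
        assert sum(r.outcome for r in recs) == 10

    def test_chrx_excluded(self):
        val = [make_call(), make_call(chrom="chrX")]
        ss = [make_call(l2r=0.1)]
        recs = build_training_set(val, ss, {"chr1"})
        assert len(recs) == 2

    def test_missing_class_errors(self):
        with pytest.raises(TrainingError):
            build_training_set([make_call()], [], {"chr1"})


class TestStepwiseFit:
    def test_recovers_published_structure(self):
        # Generative recovery: labels drawn from the published model; over 20
        # seeds a majority of fits must select absl2r (+), a datapoints
        # transform (+) and a length transform (-).  Computed with the
        # simulate_records oracle; the ln/lnln length transforms are nearly
        # collinear so either counts as recovery of the length effect.
        hits = 0
        for seed in range(20):
            model = stepwise_fit(simulate_records(2000, seed))
            c = model.coefficients
            terms = set(c)
            length_terms = [t for t in ("lnln_length", "ln_length") if t in terms]
            dp_terms = [t for t in ("lnln_datapoints", "ln_datapoints") if t in terms]
            ok = ("absl2r" in terms and c["absl2r"] > 0
                  and dp_terms and c[dp_terms[0]] > 0
                  and (not length_terms or c[length_terms[0]] < 0))
            hits += int(ok)
        assert hits >= 12

    def test_pure_noise_candidate_rarely_enters(self, rng):
        # Type-I behaviour: a single noise candidate enters with prob ~ 0.3,
        # so a majority of seeds must yield an intercept-only model.
        empty = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            calls = [make_call(l2r=float(r.uniform(0.1, 1.0)))
                     for _ in range(200)]
            recs = [TrainingRecord(c, int(r.random() < 0.5)) for c in calls]
            model = stepwise_fit(recs, candidate_terms=["absl2r"])
            empty += int(not model.coefficients)
        assert empty >= 11

    def test_constant_outcome_errors(self):
        recs = [TrainingRecord(make_call(), 1) for _ in range(10)]
        with pytest.raises(TrainingError):
            stepwise_fit(recs)


class TestLooCrossvalidate:
    def _separable_records(self):
        pos = [make_call(animal=f"P{i}", l2r=1.0 + 0.01 * i, length=5000 + i)
               for i in range(8)]
        neg = [make_call(animal=f"N{i}", l2r=0.1 + 0.005 * i, length=5000 + i)
               for i in range(8)]
        return ([TrainingRecord(c, 1) for c in pos]
                + [TrainingRecord(c, 0) for c in neg])

    def test_separable_data_perfect_accuracy(self):
        recs = self._separable_records()
        model = LogisticModel(intercept=-10.0, coefficients={"absl2r": 20.0})
        res = loo_crossvalidate(recs, model, thresholds=(0.5,))
        assert res.accuracy[0.5] == 1.0

    def test_shape_contract(self):
        recs = self._separable_records()[3:13]
        model = LogisticModel(intercept=0.0, coefficients={"absl2r": 1.0})
        res = loo_crossvalidate(recs, model)
        assert len(res.accuracy) == len(DEFAULT_THRESHOLDS)
        assert res.selected_threshold == 0.95

    def test_permuted_labels_give_chance_accuracy(self):
        # with no signal, accuracy at t=0.5 ~ majority-class fraction (0.6)
        accs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            calls = [make_call(l2r=float(r.uniform(0.1, 1.0)))
                     for _ in range(50)]
            y = np.array([1] * 30 + [0] * 20)
            r.shuffle(y)
            recs = [TrainingRecord(c, int(o)) for c, o in zip(calls, y)]
            model = LogisticModel(intercept=0.0, coefficients={"absl2r": 1.0})
            accs.append(loo_crossvalidate(recs, model,
                                          thresholds=(0.5,)).accuracy[0.5])
        assert 0.45 <= np.mean(accs) <= 0.72

    def test_order_invariance(self):
        recs = self._separable_records()
        model = LogisticModel(intercept=-10.0, coefficients={"absl2r": 20.0})
        a = loo_crossvalidate(recs, model, thresholds=(0.5, 0.9))
        b = loo_crossvalidate(list(reversed(recs)), model, thresholds=(0.5, 0.9))
        assert a.accuracy == b.accuracy

    def test_too_few_records(self):
        with pytest.raises(TrainingError):
            loo_crossvalidate(self._separable_records()[:5], PUBLISHED_MODEL)
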
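import numpy as np
import pytest

from scprognosis import (ClinicalTable, CoxModel, ExpressionMatrix,
                         SurvivalDataset, ValidationError, c_index,
                         cross_validate, fit_cox, hazard_ratio, km_logrank,
                         risk_score, simulate_bulk_survival, stratify)
from scprognosis.survival import cox_standard_errors


def brute_force_cindex(times, events, scores):
    """Literal pairwise-indicator oracle."""
    num = den = 0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i >= j:
                continue
            if times[i] < times[j] and events[i] == 1:
                den += 1
                num += scores[i] > scores[j]
            elif times[i] > times[j] and events[j] == 1:
                den += 1
                num += scores[j] > scores[i]
    return num / den


class TestFitCox:
    def test_recovers_single_gene_effect(self):
        bulk = simulate_bulk_survival(["g"], n_samples=500, effect=[0.8],
                                      censor_rate=0.0, seed=0)
        model = fit_cox(bulk, ["g"])
        se = cox_standard_errors(bulk, ["g"])["g"]
        sd = bulk.expression.values[0].std()
        # the simulator applies the effect on the standardized scale
        assert abs(model.beta[0] * sd - 0.8) < 3 * se * sd

    def test_null_gene_covered_by_zero(self):
        bulk = simulate_bulk_survival(["g"], n_samples=500, effect=[0.0],
                                      censor_rate=0.2, seed=1)
        model = fit_cox(bulk, ["g"])
        se = cox_standard_errors(bulk, ["g"])["g"]
        assert abs(model.beta[0]) < 3 * se

    def test_duplicated_samples_leave_fit_unchanged(self):
        bulk = simulate_bulk_survival(["g"], n_samples=120, effect=[0.5],
                                      censor_rate=0.2, seed=2)
        model = fit_cox(bulk, ["g"])
        expr2 = ExpressionMatrix(
            np.hstack([bulk.expression.values] * 2), ["g"],
            [f"{s}_{i}" for i in range(2) for s in bulk.expression.cell_ids])
        clin2 = ClinicalTable(expr2.cell_ids,
                              np.tile(bulk.clinical.time, 2),
                              np.tile(bulk.clinical.event, 2))
        model2 = fit_cox(SurvivalDataset(expr2, clin2), ["g"])
        # equality is exact in the partial likelihood; the optimizer's own
        # stopping tolerance bounds the numerical gap
        assert model2.beta[0] == pytest.approx(model.beta[0], rel=2e-2)

    def test_zero_events_error(self):
        bulk = simulate_bulk_survival(["g"], n_samples=30, censor_rate=0.0,
                                      effect=[0.0], seed=3)
        clin = ClinicalTable(bulk.clinical.sample_ids, bulk.clinical.time,
                             np.zeros(30, dtype=int))
        with pytest.raises(ValidationError, match="no events"):
            fit_cox(SurvivalDataset(bulk.expression, clin), ["g"])


class TestRiskScore:
    def _model(self):
        return CoxModel(["g1", "g2"], [1.0, 0.0], [3.0, 10.0])

    def test_training_means_score_zero(self):
        expr = ExpressionMatrix(np.array([[3.0], [10.0]]), ["g1", "g2"], ["s"])
        assert risk_score(self._model(), expr)["s"] == 0.0

    def test_dot_product(self):
        expr = ExpressionMatrix(np.array([[5.0], [109.0]]), ["g1", "g2"], ["s"])
        assert risk_score(self._model(), expr)["s"] == pytest.approx(2.0)

    def test_constant_shift_linearity(self):
        rng = np.random.default_rng(4)
        vals = rng.random((2, 6)) + 1
        expr = ExpressionMatrix(vals, ["g1", "g2"], [f"s{i}" for i in range(6)])
        shifted = ExpressionMatrix(vals + np.array([[2.0], [0.0]]),
                                   ["g1", "g2"], expr.cell_ids)
        delta = risk_score(self._model(), shifted) - risk_score(self._model(), expr)
        np.testing.assert_allclose(delta, 2.0 * 1.0)

    def test_missing_gene_named(self):
        expr = ExpressionMatrix(np.array([[1.0]]), ["g1"], ["s"])
        with pytest.raises(ValidationError, match="g2"):
            risk_score(self._model(), expr)


class TestCIndex:
    def test_perfect_concordance_and_discordance(self):
        t = np.array([5.0, 3.0, 8.0, 1.0])
        e = np.ones(4, dtype=int)
        assert c_index(t, e, -t) == 1.0
        assert c_index(t, e, t) == 0.0

    def test_matches_brute_force_on_censored_data(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 200)
        e = rng.integers(0, 2, 200)
        s = rng.normal(0, 1, 200)
        assert c_index(t, e, s) == brute_force_cindex(t, e, s)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        t, e, s = rng.exponential(5, 80), rng.integers(0, 2, 80), rng.normal(0, 1, 80)
        assert c_index(t, e, s) == c_index(t, e, np.exp(3 * s))

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(ValidationError, match="comparable"):
            c_index([1.0, 2.0], [0, 0], [1.0, 2.0])


class TestStratify:
    def test_median_split(self):
        groups = stratify([1.0, 2.0, 3.0, 4.0])
        assert list(groups) == ["low", "low", "high", "high"]

    def test_score_equal_to_median_goes_low(self):
        assert list(stratify([1.0, 2.0, 3.0])) == ["low", "low", "high"]

    def test_duplicate_median_values_all_low(self):
        assert list(stratify([1.0, 2.0, 2.0, 2.0, 9.0])) == \
            ["low", "low", "low", "low", "high"]

    def test_identical_scores_error(self):
        with pytest.raises(ValidationError, match="identical"):
            stratify([2.0, 2.0, 2.0])


class TestHazardRatio:
    def _clinical(self, times, events):
        return ClinicalTable([f"s{i}" for i in range(len(times))], times, events)

    def test_null_groups_cover_one(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(10, 1000)
        clin = self._clinical(t, np.ones(1000, dtype=int))
        groups = np.array(["high", "low"] * 500)
        hr, (lo, hi) = hazard_ratio(groups, clin)
        assert lo < 1.0 < hi

    def test_true_ratio_two_covered(self):
        rng = np.random.default_rng(8)
        t = np.concatenate([rng.exponential(5, 250), rng.exponential(10, 250)])
        clin = self._clinical(t, np.ones(500, dtype=int))
        groups = np.array(["high"] * 250 + ["low"] * 250)
        hr, (lo, hi) = hazard_ratio(groups, clin)
        assert lo < 2.0 < hi

    def test_relabel_inverts(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(8, 120)
        clin = self._clinical(t, rng.integers(0, 2, 120) | 1)
        groups = np.array(["high"] * 60 + ["low"] * 60)
        swapped = np.where(groups == "high", "low", "high")
        hr, _ = hazard_ratio(groups, clin)
        hr_sw, _ = hazard_ratio(swapped, clin)
        assert hr_sw == pytest.approx(1.0 / hr, abs=1e-9)


class TestKmLogrank:
    def test_hand_computed_product_limit(self):
        # 6 patients, events at 1,2,4,6; censored at 3,5
        clin = ClinicalTable([f"s{i}" for i in range(12)],
                             [1, 2, 3, 4, 5, 6] * 2,
                             [1, 1, 0, 1, 0, 1] * 2)
        groups = np.array(["high"] * 6 + ["low"] * 6)
        curves, p = km_logrank(groups, clin)
        high = curves["high"].set_index("time")["survival"]
        assert high[1.0] == pytest.approx(5 / 6)
        assert high[2.0] == pytest.approx(5 / 6 * 4 / 5)
        assert high[4.0] == pytest.approx(2 / 3 * 2 / 3)
        assert high[6.0] == pytest.approx(0.0)
        # identical groups: log-rank statistic 0, p = 1
        assert p == pytest.approx(1.0)

    def test_curves_non_increasing_from_one(self, null_bulk):
        scores = null_bulk.expression.values[0]
        curves, _ = km_logrank(stratify(scores), null_bulk.clinical)
        for curve in curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] <= 1.0 + 1e-12
            assert np.all(np.diff(s) <= 1e-12)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(10)
        t = np.concatenate([rng.exponential(3, 150), rng.exponential(9, 150)])
        clin = ClinicalTable([f"s{i}" for i in range(300)], t,
                             np.ones(300, dtype=int))
        groups = np.array(["high"] * 150 + ["low"] * 150)
        _, p = km_logrank(groups, clin)
        assert p < 0.05

    def test_no_events_error(self):
        clin = ClinicalTable(["a", "b"], [1.0, 2.0], [0, 0])
        with pytest.raises(ValidationError, match="events"):
            km_logrank(np.array(["high", "low"]), clin)


class TestCrossValidate:
    def test_deterministic_given_seed(self, null_bulk):
        genes = list(null_bulk.expression.gene_ids)[:3]
        a = cross_validate(null_bulk, genes, folds=5, runs=2, seed=11)
        b = cross_validate(null_bulk, genes, folds=5, runs=2, seed=11)
        assert a.per_run.equals(b.per_run)

    def test_planted_signal_detected(self):
        genes = [f"g{i}" for i in range(10)]
        bulk = simulate_bulk_survival(genes, n_samples=400, censor_rate=0.3,
                                      seed=12)
        cv = cross_validate(bulk, genes, folds=10, runs=3, seed=0)
        assert cv.mean_cindex >= 0.65

    def test_supports_many_runs_protocol(self):
        bulk = simulate_bulk_survival(["g"], n_samples=60, effect=[0.5],
                                      censor_rate=0.2, seed=13)
        cv = cross_validate(bulk, ["g"], folds=10, runs=12, seed=1)
        assert len(cv.per_run) == 12
        assert np.isfinite(cv.mean_cindex)
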
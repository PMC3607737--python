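"""Direct and composite mapping specifications and their prediction rules."""

import json

import numpy as np
import pandas as pd
import pytest

from oksmap.direct_models import (
    DEFAULT_MERGE_MAPS,
    FittedPart,
    MappingFit,
    eq1_prediction,
    eq2_prediction,
    fit_mapping,
    observed_outcome_classes,
    observed_utilities,
)
from oksmap.evaluation import accuracy
from oksmap.oks import ITEM_COLUMNS
from oksmap.tariff import EQ5D_COLUMNS


class TestPredictionConstructors:
    @pytest.mark.parametrize(
        "p, u, expected",
        [(1.0, 0.2, 1.0), (0.0, 0.37, 0.37), (0.5, 0.5, 0.75)],
    )
    def test_two_part_combination(self, p, u, expected):
        assert eq1_prediction(p, u) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "pp, pn, un, um, expected",
        [
            (0.1, 0.5, 0.2, 0.7, 0.48),
            (1.0, 0.0, 0.0, 0.0, 1.0),
        ],
    )
    def test_three_part_combination(self, pp, pn, un, um, expected):
        assert eq2_prediction(pp, pn, un, um) == pytest.approx(expected, abs=1e-15)

    def test_three_part_reduces_to_two_part_without_severe_class(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pp, um = rng.random(), rng.uniform(-0.5, 1)
            assert eq2_prediction(pp, 0.0, 0.3, um) == pytest.approx(
                eq1_prediction(pp, um), abs=1e-15
            )

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(1)
        pp = rng.random(100)
        pn = (1 - pp) * rng.random(100)
        un = rng.uniform(-0.594, 1, 100)
        um = rng.uniform(-0.594, 1, 100)
        pred = eq2_prediction(pp, pn, un, um)
        lo = np.minimum(np.minimum(un, um), 1.0)
        hi = np.maximum(np.maximum(un, um), 1.0)
        assert np.all(pred >= lo - 1e-12) and np.all(pred <= hi + 1e-12)
        # Eq. 1 form is increasing in the ceiling probability below 1
        u = 0.4
        grid = eq1_prediction(np.linspace(0, 1, 11), u)
        assert np.all(np.diff(grid) > 0)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            eq1_prediction(1.2, 0.5)
        with pytest.raises(ValueError):
            eq2_prediction(0.7, 0.5, 0.2, 0.3)


def _cohort_from_items(items, eq_levels):
    data = pd.DataFrame(items, columns=list(ITEM_COLUMNS))
    for col, lvl in zip(EQ5D_COLUMNS, np.asarray(eq_levels).T):
        data[col] = lvl
    return data


class TestSimpleFits:
    def test_ols_slope_recovery_and_ceiling(self, uk):
        rng = np.random.default_rng(7)
        totals = rng.integers(0, 49, size=5000)
        # build item scores consistent with each total
        items = np.zeros((5000, 12), dtype=int)
        for i, t in enumerate(totals):
            alloc = rng.multinomial(t, np.ones(12) / 12)
            items[i] = np.minimum(alloc, 4)
        data = pd.DataFrame(items, columns=list(ITEM_COLUMNS))
        real_total = items.sum(axis=1)
        y = 0.9 - 0.01 * real_total + rng.normal(0, 0.05, size=5000)
        import statsmodels.api as sm

        from oksmap.oks import design_matrix

        X = design_matrix(data, "total1")
        res = sm.OLS(y, sm.add_constant(X)).fit()
        assert res.params["total_oks"] == pytest.approx(-0.01, abs=0.003)

        # predictions above the ceiling are truncated to exactly 1
        part = FittedPart(
            kind="linear", feature_names=("total_oks",), params=np.array([1.09, -0.01])
        )
        fit = MappingFit(spec_id="ols", coding="total1", parts={"mean": part})
        few = pd.DataFrame(
            [[0] * 12, [2] * 12], columns=list(ITEM_COLUMNS)
        )  # totals 0 and 24
        pred = fit.predict(few, uk)
        assert pred[0] == 1.0  # raw 1.09 capped
        assert pred[1] == pytest.approx(0.85)  # untouched below the ceiling

    def test_ols_rank_deficiency_reported(self, mixed_cohort, uk):
        data = mixed_cohort[mixed_cohort["oks_pain"] != 0].copy()
        with pytest.raises(ValueError, match="pain_0"):
            fit_mapping(data, "ols")

    @pytest.mark.parametrize("spec", ["glm_gamma", "glm_log_gaussian"])
    def test_glm_intercept_only_recovers_mean_disutility(self, spec, uk):
        """With OKS carrying no signal, the back-transformed GLM prediction
        is the mean disutility subtracted from full health."""
        items = np.full((400, 12), 2)
        state_a = (2, 1, 1, 2, 1)  # 1 - 0.081 - 0.069 - 0.123 = 0.727
        state_b = (2, 2, 1, 2, 1)  # 0.727 - 0.104 = 0.623
        eq = np.array([state_a] * 200 + [state_b] * 200)
        data = _cohort_from_items(items, eq)
        target = observed_utilities(data, uk).mean()
        fit = fit_mapping(data, spec, coding="total1")
        pred = fit.predict(data, uk)
        assert np.allclose(pred, target, atol=1e-6)

    def test_fractional_logit_intercept_and_bounds(self, uk):
        items = np.full((400, 12), 2)
        # two states symmetric around utility_0-1 = 0.5 (utility 0.203):
        # mean utility0-1 = 0.5 -> predicted utility 0.203
        state_a = (1, 1, 1, 1, 1)  # utility 1 -> rescaled 1
        state_b = (3, 3, 3, 3, 3)  # utility -0.594 -> rescaled 0
        eq = np.array([state_a] * 200 + [state_b] * 200)
        data = _cohort_from_items(items, eq)
        fit = fit_mapping(data, "fractional_logit", coding="total1")
        pred = fit.predict(data, uk)
        assert np.allclose(pred, 0.203, atol=1e-6)
        assert np.all((pred > uk.minimum) & (pred < uk.maximum))

    def test_gamma_zero_policy(self, uk):
        items = np.full((100, 12), 3)
        eq = np.array([(1, 1, 1, 1, 1)] * 50 + [(1, 1, 1, 2, 1)] * 50)
        data = _cohort_from_items(items, eq)
        with pytest.warns(UserWarning, match="zero disutilities"):
            fit_mapping(data, "glm_gamma", coding="total1")
        fit = fit_mapping(data, "glm_gamma", coding="total1", gamma_zero_policy="drop")
        assert fit.parts["disutility"].meta["nobs"] == 50
        with pytest.raises(ValueError, match="gamma_zero_policy"):
            fit_mapping(data, "glm_gamma", coding="total1", gamma_zero_policy="bogus")


class TestCompositeFits:
    def test_two_part_prediction_matches_manual_combination(self, mixed_cohort, uk):
        fit = fit_mapping(mixed_cohort, "two_part")
        assert fit.merge_map == DEFAULT_MERGE_MAPS["two_part"]
        from oksmap.oks import design_matrix

        Xm = design_matrix(mixed_cohort, "dummies48", fit.merge_map)
        X = design_matrix(mixed_cohort, "dummies48")
        manual = eq1_prediction(
            fit.parts["ceiling"].predict(Xm), fit.parts["conditional"].predict(X)
        )
        assert np.allclose(fit.predict(mixed_cohort, uk), manual)

    def test_three_part_prediction_matches_manual_combination(self, mixed_cohort, uk):
        fit = fit_mapping(mixed_cohort, "three_part")
        from oksmap.oks import design_matrix

        Xm = design_matrix(mixed_cohort, "dummies48", fit.merge_map)
        X = design_matrix(mixed_cohort, "dummies48")
        probs = fit.parts["classes"].predict(Xm)
        manual = eq2_prediction(
            probs[:, 0],
            probs[:, 1],
            fit.parts["u_n3"].predict(X),
            fit.parts["u_mm"].predict(X),
        )
        assert np.allclose(fit.predict(mixed_cohort, uk), manual)
        classes = observed_outcome_classes(mixed_cohort)
        assert set(classes) <= {"perfect", "n3", "mild_moderate"}

    def test_two_part_requires_both_outcomes(self, mixed_cohort):
        data = mixed_cohort[mixed_cohort["utility"] < 1].copy()
        with pytest.raises(ValueError, match="ceiling"):
            fit_mapping(data, "two_part")


class TestCodingHierarchy:
    def test_in_sample_mse_is_monotone_in_design_richness(self, mixed_cohort, uk):
        """scores are linear in the dummies and the total in the scores, so
        richer codings can only reduce in-sample OLS error."""
        y = observed_utilities(mixed_cohort, uk)
        mses = {}
        for coding in ("dummies48", "scores12", "total1"):
            fit = fit_mapping(mixed_cohort, "ols", coding=coding)
            # compare raw (untruncated) least-squares fits
            from oksmap.oks import design_matrix

            raw = fit.parts["mean"].predict(design_matrix(mixed_cohort, coding))
            mses[coding] = accuracy(y, raw).mse
        assert mses["dummies48"] <= mses["scores12"] + 1e-12
        assert mses["scores12"] <= mses["total1"] + 1e-12


class TestSerialization:
    @pytest.mark.parametrize("spec", ["ols", "two_part", "rm_multinomial"])
    def test_json_roundtrip_preserves_predictions(self, tmp_path, mixed_cohort, uk, spec):
        fit = fit_mapping(mixed_cohort, spec)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        restored = MappingFit.from_json(path)
        assert restored.spec_id == spec
        assert np.allclose(
            fit.predict(mixed_cohort, uk), restored.predict(mixed_cohort, uk)
        )
        payload = json.loads(path.read_text())
        assert payload["format"] == "oksmap-mapping-fit"

    def test_unknown_spec_rejected(self, mixed_cohort):
        with pytest.raises(ValueError, match="unknown specification"):
            fit_mapping(mixed_cohort, "ridge")
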
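"""Published model loading, level-probability prediction, and valuation."""

import numpy as np
import pandas as pd
import pytest

from oksmap.oks import DUMMY_COLUMNS
from oksmap.response_mapping import (
    CoefficientIntegrityError,
    DegenerateOutcomeError,
    DomainCoefficientBlock,
    ResponseMappingModel,
    expected_utility,
    fit_response_mapping,
    highest_probability_assignment,
    load_published_model,
    monte_carlo_utility,
    predict_expected_utilities,
)
from oksmap.tariff import DOMAINS


def random_distributions(n, seed):
    rng = np.random.default_rng(seed)
    raw = rng.gamma(1.0, size=(n, 5, 3))
    return raw / raw.sum(axis=2, keepdims=True)


def degenerate(level):
    d = np.zeros((5, 3))
    d[:, level - 1] = 1.0
    return d


class TestPublishedModel:
    def test_structure(self, published_model):
        assert set(published_model.blocks) == set(DOMAINS)
        for block in published_model.blocks.values():
            assert block.coef.shape == (2, 48)
            assert block.intercept.shape == (2,)
        assert published_model.link == "multinomial"

    def test_anchor_coefficients(self, published_model):
        idx = {name: j for j, name in enumerate(DUMMY_COLUMNS)}
        pd_block = published_model.blocks["pain_discomfort"]
        assert pd_block.coef[1, idx["pain_0"]] == pytest.approx(3.729)
        mob = published_model.blocks["mobility"]
        assert mob.coef[0, idx["shopping_0"]] == pytest.approx(1.837)
        assert mob.intercept[0] == pytest.approx(-2.444)
        assert mob.intercept[1] == pytest.approx(-10.015)
        sc = published_model.blocks["self_care"]
        assert sc.coef[0, idx["washing_1"]] == pytest.approx(3.855)

    def test_tampered_file_rejected(self, tmp_path):
        import oksmap.response_mapping as rm

        table = pd.read_csv(rm._packaged_data("response_mapping_coefficients.csv"))
        mask = (
            (table["question"] == "pain")
            & (table["level"] == 0)
            & (table["eq5d_domain"] == "pain_discomfort")
            & (table["contrast"] == "L3vsL1")
        )
        table.loc[mask, "coefficient"] = 0.0
        bad = tmp_path / "coefficients.csv"
        table.to_csv(bad, index=False)
        with pytest.raises(CoefficientIntegrityError):
            load_published_model(bad)

    def test_no_problems_respondent_probabilities(self, published_model):
        """With every OKS item at 'no problems' the design is the zero vector
        and the intercepts alone drive the softmax."""
        dists = published_model.predict_distributions(np.zeros(48))
        mob = dists[0, 0]
        assert mob[1] == pytest.approx(0.080, abs=5e-4)
        assert mob[2] == pytest.approx(4.1e-5, rel=0.05)
        assert np.allclose(dists.sum(axis=2), 1.0)

    def test_probabilities_sum_to_one_and_utilities_in_range(
        self, published_model, uk
    ):
        rng = np.random.default_rng(11)
        design = np.zeros((200, 48))
        for row in design:
            for i in range(12):
                lvl = rng.integers(0, 5)
                if lvl < 4:
                    row[4 * i + lvl] = 1.0
        dists = published_model.predict_distributions(design)
        assert np.allclose(dists.sum(axis=2), 1.0, atol=1e-12)
        eu = expected_utility(dists, uk)
        assert np.all(eu >= uk.minimum - 1e-12) and np.all(eu <= uk.maximum + 1e-12)


def test_uniform_distribution_from_null_model():
    blocks = {
        d: DomainCoefficientBlock(
            domain=d,
            feature_names=DUMMY_COLUMNS,
            coef=np.zeros((2, 48)),
            intercept=np.zeros(2),
        )
        for d in DOMAINS
    }
    model = ResponseMappingModel(blocks=blocks)
    dists = model.predict_distributions(np.zeros(48))
    assert np.allclose(dists, 1 / 3)


class TestExpectedValueMethod:
    def test_degenerate_boundaries(self, uk):
        assert expected_utility(degenerate(1), uk) == pytest.approx(1.0)
        assert expected_utility(degenerate(3), uk) == pytest.approx(-0.594)

    def test_enumeration_matches_decomposition(self, uk):
        dists = random_distributions(200, seed=1)
        enum = expected_utility(dists, uk, method="enumeration")
        deco = expected_utility(dists, uk, method="decomposition")
        assert np.max(np.abs(enum - deco)) < 1e-10

    def test_invalid_distribution_rejected(self, uk):
        bad = np.full((5, 3), 0.5)
        with pytest.raises(ValueError, match="summing to 1"):
            expected_utility(bad, uk)
        with pytest.raises(ValueError, match="unknown method"):
            expected_utility(degenerate(1), uk, method="other")


class TestMonteCarlo:
    def test_degenerate_is_exact(self, uk):
        assert monte_carlo_utility(degenerate(3), uk, n_draws=10, seed=0) == pytest.approx(
            -0.594
        )

    def test_seed_determinism(self, uk):
        dists = random_distributions(3, seed=2)
        a = monte_carlo_utility(dists, uk, n_draws=500, seed=9)
        b = monte_carlo_utility(dists, uk, n_draws=500, seed=9)
        assert np.array_equal(a, b)

    def test_converges_to_expected_value(self, uk):
        dists = random_distributions(1, seed=3)
        target = expected_utility(dists, uk)[0]
        mc = monte_carlo_utility(dists, uk, n_draws=100_000, seed=4)[0]
        # conservative bound: per-draw SD of a utility is < 0.6
        assert abs(mc - target) < 3 * 0.6 / np.sqrt(100_000)


def test_highest_probability_assignment_and_tie_break():
    base = np.array([[0.5, 0.3, 0.2]] * 5)
    assert highest_probability_assignment(base).levels == (1,) * 5
    severe = np.array([[0.1, 0.2, 0.7]] * 5)
    assert highest_probability_assignment(severe).levels == (3,) * 5
    tie = np.array([[0.4, 0.4, 0.2]] * 5)
    assert highest_probability_assignment(tie).levels == (1,) * 5  # healthier level


class TestFitting:
    def test_degenerate_level_reported(self, mixed_cohort):
        data = mixed_cohort.copy()
        data["eq_mo"] = 1
        with pytest.raises(DegenerateOutcomeError, match="mobility.*[23]"):
            fit_response_mapping(data)

    def test_refit_reproduces_generator_mean_utility(self, mixed_cohort, uk):
        """Refitting on data generated from the packaged model produces
        predicted mean utility close to the cohort's realized mean."""
        fit = fit_response_mapping(mixed_cohort, cluster_col="patient_id")
        pred = predict_expected_utilities(fit, mixed_cohort, uk)
        observed_mean = mixed_cohort["utility"].mean()
        se = mixed_cohort["utility"].std() / np.sqrt(len(mixed_cohort))
        assert abs(pred.mean() - observed_mean) < 4 * se
        assert np.all((pred >= uk.minimum) & (pred <= uk.maximum))

    def test_ordinal_fit_produces_valid_distributions(self, mixed_cohort):
        fit = fit_response_mapping(mixed_cohort, link="ordinal")
        from oksmap.oks import dummy_design

        dists = fit.predict_distributions(dummy_design(mixed_cohort).to_numpy())
        assert dists.shape == (len(mixed_cohort), 5, 3)
        assert np.allclose(dists.sum(axis=2), 1.0)
        assert np.all(dists >= 0)

    def test_missing_eq5d_column_rejected(self, mixed_cohort):
        with pytest.raises(ValueError, match="eq_ad"):
            fit_response_mapping(mixed_cohort.drop(columns=["eq_ad"]))
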
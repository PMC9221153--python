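"""Linear sequence-score model: OLS fit, inference, prediction,
Spearman statistics."""

import numpy as np
import pandas as pd
import pytest

from gapmertox.features import FeatureVector, feature_table
from gapmertox.gapmer import AsoPanel, parse_gapmer
from gapmertox.scoring_model import (
    PARAM_NAMES,
    SequenceScoreModel,
    SequenceScoreResults,
    calculate_score,
    feature_score_correlations,
    fit_linear_model,
    linear_scores,
    median_score_by_count,
    spearman_test,
)
from gapmertox.synthetic_data import simulate_target_premrna, tile_asos

TRUE = {
    "p_A": 3.0,
    "p_T": 1.0,
    "p_C": 1.0,
    "p_G": -8.0,
    "p_3": 1.0,
    "intercept": 20.0,
}


@pytest.fixture(scope="module")
def random_features():
    target = simulate_target_premrna(2000, seed=5)
    panel = tile_asos(target, 50, 50, seed=5)
    return feature_table(panel)


class TestFit:
    def test_noiseless_recovery(self, random_features):
        """A noiseless full-rank linear system is recovered exactly."""
        y = linear_scores(random_features, TRUE)
        res = fit_linear_model(random_features, y)
        for name in PARAM_NAMES:
            assert res.params[name] == pytest.approx(TRUE[name], abs=1e-8)

    def test_constant_scores_give_zero_weights(self, random_features):
        res = fit_linear_model(random_features, np.full(len(random_features), 70.0))
        assert res.params["intercept"] == pytest.approx(70.0, abs=1e-8)
        for name in PARAM_NAMES[:-1]:
            assert res.params[name] == pytest.approx(0.0, abs=1e-8)

    def test_too_few_observations_rejected(self, random_features):
        few = random_features.iloc[:6]
        with pytest.raises(ValueError, match="at least 7"):
            SequenceScoreModel(np.zeros(6), few)

    def test_rank_deficiency_names_columns(self, random_features):
        broken = random_features.copy()
        broken["n_t"] = 2.0 * broken["n_a"]
        with pytest.raises(ValueError, match="n_t"):
            SequenceScoreModel(np.zeros(len(broken)), broken)

    def test_residuals_orthogonal_to_design(self, random_features):
        rng = np.random.default_rng(0)
        y = linear_scores(random_features, TRUE) + rng.normal(0, 25, len(random_features))
        res = fit_linear_model(random_features, y)
        n = len(random_features)
        assert abs(res.resid.sum()) < 1e-6 * n
        for col in ("n_a", "n_t", "n_c", "n_g", "g3"):
            dot = float(res.resid @ random_features[col].to_numpy(dtype=float))
            assert abs(dot) < 1e-6 * n

    def test_inference_fields_well_formed(self, random_features):
        rng = np.random.default_rng(1)
        y = linear_scores(random_features, TRUE) + rng.normal(0, 10, len(random_features))
        res = fit_linear_model(random_features, y)
        assert (res.bse >= 0).all()
        assert ((res.pvalues >= 0) & (res.pvalues <= 1)).all()
        assert res.nobs == len(random_features)
        np.testing.assert_allclose(res.tvalues, res.params / res.bse)

    def test_coefficient_bias_shrinks_with_noise(self, random_features):
        """Mean recovered coefficients approach the generators as noise
        shrinks (Monte-Carlo over noise draws at fixed design)."""
        truth = np.array([TRUE[k] for k in PARAM_NAMES])
        base = linear_scores(random_features, TRUE)
        biases = []
        for sd in (20.0, 2.0):
            rng = np.random.default_rng(42)
            est = np.mean(
                [
                    fit_linear_model(
                        random_features, base + rng.normal(0, sd, len(base))
                    ).params.to_numpy()
                    for _ in range(40)
                ],
                axis=0,
            )
            biases.append(np.abs(est - truth).max())
        assert biases[1] < biases[0]

    def test_cap_clips_scores_before_fit(self, random_features):
        y = linear_scores(random_features, TRUE)
        y[0] = 500.0
        capped = fit_linear_model(random_features, y, cap=200.0)
        raw = fit_linear_model(random_features, y)
        assert not np.allclose(capped.params, raw.params)


class TestCalculateScore:
    def test_direct_substitution(self):
        fv = FeatureVector(
            n_a=1, n_t=0, n_c=1, n_g=0, g3=2, g5=2, length=2, n_lna=0,
            gap_length=2,
        )
        params = {k: 1.0 for k in PARAM_NAMES[:-1]} | {"intercept": 0.0}
        assert calculate_score(params, fv) == pytest.approx(4.0)

    def test_intercept_only(self, reference_panel):
        params = {k: 0.0 for k in PARAM_NAMES[:-1]} | {"intercept": 70.0}
        fv = FeatureVector.from_aso(reference_panel[0])
        assert calculate_score(params, fv) == pytest.approx(70.0)

    def test_linearity_in_features(self):
        rng = np.random.default_rng(2)
        params = dict(zip(PARAM_NAMES, rng.normal(size=6)))
        I = params["intercept"]

        def fv(n_a, n_t, n_c, n_g, g3):
            return FeatureVector(
                n_a=n_a, n_t=n_t, n_c=n_c, n_g=n_g, g3=g3, g5=g3,
                length=n_a + n_t + n_c + n_g, n_lna=0,
                gap_length=n_a + n_t + n_c + n_g,
            )

        a, b = fv(3, 2, 1, 4, 2), fv(1, 5, 2, 2, 7)
        s = fv(4, 7, 3, 6, 9)
        assert calculate_score(params, s) - I == pytest.approx(
            (calculate_score(params, a) - I) + (calculate_score(params, b) - I)
        )

    def test_score_panel_rounding(self, reference_panel):
        params = {k: 0.0 for k in PARAM_NAMES[:-1]} | {"intercept": 70.4}
        res = SequenceScoreResults(model=None)
        res.params = pd.Series(params).reindex(PARAM_NAMES)
        rounded = res.score_panel(reference_panel, round_scores=True)
        assert (rounded == 70).all()


class TestPersistence:
    def test_json_round_trip(self, tmp_path, random_features):
        rng = np.random.default_rng(3)
        y = linear_scores(random_features, TRUE) + rng.normal(0, 5, len(random_features))
        res = fit_linear_model(random_features, y)
        path = tmp_path / "model.json"
        res.to_json(path)
        back = SequenceScoreResults.from_json(path)
        pd.testing.assert_series_equal(back.params, res.params)
        pd.testing.assert_series_equal(back.bse, res.bse)
        assert back.nobs == res.nobs
        np.testing.assert_allclose(
            back.predict(random_features), res.predict(random_features)
        )


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman_test([1, 2, 3], [10, 20, 30])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_test([1, 2, 3], [3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_test([1, 1, 1], [1, 2, 3])

    def test_matches_ranks_then_pearson_oracle(self):
        """With ties, rho equals Pearson correlation of average ranks and p
        follows the t-approximation on n-2 df."""
        import scipy.stats

        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            x = rng.integers(0, 5, size=n).astype(float)  # forces ties
            y = rng.integers(0, 5, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = spearman_test(x, y)
            rx = scipy.stats.rankdata(x)
            ry = scipy.stats.rankdata(y)
            rho_oracle = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(rho_oracle, abs=1e-12)
            if abs(rho_oracle) < 1:
                t = rho_oracle * np.sqrt((n - 2) / (1 - rho_oracle**2))
                p_oracle = 2 * scipy.stats.t.sf(abs(t), n - 2)
                assert p == pytest.approx(p_oracle, abs=1e-12)


class TestFeatureCorrelations:
    def test_negative_g_weight_gives_negative_rho(self, random_features):
        y = linear_scores(random_features, TRUE)
        table = feature_score_correlations(random_features, y)
        assert table.loc["n_g", "rho"] < 0
        assert table.loc["n_a", "rho"] > 0

    def test_null_simulation_p_values_roughly_uniform(self, random_features):
        """Pure-noise scores: p-values across replicates are not
        concentrated at small values."""
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(100):
            y = rng.normal(100, 25, len(random_features))
            table = feature_score_correlations(random_features, y, columns=["n_g"])
            pvals.append(table.loc["n_g", "p_value"])
        assert np.mean(np.array(pvals) < 0.05) < 0.15
        assert 0.2 < np.median(pvals) < 0.8

    def test_constant_column_excluded_with_warning(self, random_features):
        feats = random_features.copy()
        feats["n_g"] = 0
        with pytest.warns(UserWarning, match="n_g"):
            table = feature_score_correlations(
                feats, np.arange(len(feats), dtype=float)
            )
        assert "n_g" not in table.index

    def test_median_by_count(self, random_features):
        y = linear_scores(random_features, TRUE)
        med = median_score_by_count(random_features, y, "n_g")
        assert set(med.index) <= set(random_features["n_g"])
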
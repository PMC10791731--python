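import numpy as np
import pandas as pd
import pytest

from oracles import svd_pls1

from gyflux.pls import (
    BLM_TIMEPOINTS,
    BatchLevelPLS,
    coefficient_sum_ranking,
    fit_pls,
    unfold_batch_level,
    vip_scores,
)
from gyflux.qc import detect_outliers, filter_outliers
from gyflux.synth import default_conditions, plant_titer_correlation, simulate_study


def random_matrix_model(n, p, seed, n_components=2):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, p)),
        columns=pd.MultiIndex.from_tuples(
            [(f"v{j}", float(d)) for j, d in zip(range(p), np.arange(p))],
            names=["variable", "day"],
        ),
        index=pd.Index([f"b{i}" for i in range(n)], name="batch_id"),
    )
    beta = rng.normal(size=p)
    y = pd.Series(X.to_numpy() @ beta + 0.1 * rng.normal(size=n), index=X.index)
    model = BatchLevelPLS(X, y)
    return model, model.fit(n_components=n_components)


class TestUnfold:
    def test_shape_is_batches_by_variable_times_timepoint(self, study_batches):
        m = unfold_batch_level(study_batches)
        n_vars = 3 + len(study_batches[0].conc)  # VCD, viability, titer + mets
        expected_cols = n_vars * len(BLM_TIMEPOINTS) - len(m.dropped_columns)
        assert m.X.shape == (len(study_batches), expected_cols)

    def test_max_titer_batch_normalized_to_one(self, study_batches):
        m = unfold_batch_level(study_batches)
        assert m.y.max() == pytest.approx(1.0)
        best = m.y.idxmax()
        titers = {b.batch_id: b.titer[-1] for b in study_batches}
        assert best == max(titers, key=titers.get)

    def test_constant_column_dropped_and_logged(self, study_batches):
        import dataclasses

        doctored = [
            dataclasses.replace(b, conc={**b.conc, "inert": [1.0] * len(b.days)})
            for b in study_batches
        ]
        m = unfold_batch_level(doctored)
        assert all(v != "inert" for v, _ in m.X.columns)
        inert_drops = [d for d in m.dropped_columns if d[0].startswith("inert@")]
        assert len(inert_drops) == len(BLM_TIMEPOINTS)

    def test_missing_timepoint_raises(self, study_batches):
        with pytest.raises(ValueError, match="missing"):
            unfold_batch_level(study_batches, timepoints=[4.0, 9.0])


class TestNipalsAgainstOracles:
    @pytest.mark.parametrize("seed", range(20))
    def test_coefficients_match_svd_oracle(self, seed):
        """NIPALS and an SVD-based PLS1 agree to 1e-6 on random matrices."""
        model, results = random_matrix_model(8, 5, seed=seed, n_components=2)
        Xs, ys = model._scaled_xy()
        _, _, _, _, coef = svd_pls1(Xs, ys, 2)
        assert np.allclose(results.coef.to_numpy(), coef, atol=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_coefficients_match_sklearn(self, seed):
        from sklearn.cross_decomposition import PLSRegression

        model, results = random_matrix_model(12, 7, seed=seed, n_components=3)
        Xs, ys = model._scaled_xy()
        sk = PLSRegression(n_components=3, scale=False).fit(Xs, ys)
        assert np.allclose(results.coef.to_numpy(), sk.coef_.ravel(), atol=1e-6)

    def test_one_component_coef_proportional_to_xty(self):
        model, results = random_matrix_model(10, 6, seed=3, n_components=1)
        Xs, ys = model._scaled_xy()
        direction = Xs.T @ ys
        coef = results.coef.to_numpy()
        cos = coef @ direction / np.linalg.norm(coef) / np.linalg.norm(direction)
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_planted_linear_signal_recovered(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            rng.normal(size=(20, 10)),
            columns=pd.MultiIndex.from_tuples(
                [(f"v{j}", 0.0) for j in range(10)], names=["variable", "day"]
            ),
        )
        beta = rng.normal(size=10)
        y = pd.Series(X.to_numpy() @ beta + 0.05 * rng.normal(size=20), index=X.index)
        res = BatchLevelPLS(X, y).fit(n_components=3)
        pred = res.predict()
        ss_res = float(((pred - y) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        assert 1 - ss_res / ss_tot > 0.9


class TestVip:
    def test_mean_squared_vip_is_one(self):
        for seed in range(5):
            _, results = random_matrix_model(9, 6, seed=seed, n_components=2)
            vip = vip_scores(results)
            assert float((vip**2).mean()) == pytest.approx(1.0, abs=1e-10)

    def test_single_column_vip_is_one(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            rng.normal(size=(8, 1)),
            columns=pd.MultiIndex.from_tuples([("v0", 0.0)], names=["variable", "day"]),
        )
        y = pd.Series(X.iloc[:, 0] * 2 + rng.normal(size=8) * 0.1, index=X.index)
        res = BatchLevelPLS(X, y).fit(n_components=1)
        assert vip_scores(res).iloc[0] == pytest.approx(1.0)

    def test_informative_columns_score_above_noise(self):
        rng = np.random.default_rng(2)
        signal = rng.normal(size=(30, 3))
        noise = rng.normal(size=(30, 9))
        X = pd.DataFrame(
            np.hstack([signal, noise]),
            columns=pd.MultiIndex.from_tuples(
                [(f"s{j}", 0.0) for j in range(3)] + [(f"n{j}", 0.0) for j in range(9)],
                names=["variable", "day"],
            ),
        )
        y = pd.Series(signal.sum(axis=1) + 0.2 * rng.normal(size=30), index=X.index)
        vip = vip_scores(BatchLevelPLS(X, y).fit(n_components=2))
        signal_vip = vip[[c for c in vip.index if c[0].startswith("s")]]
        noise_vip = vip[[c for c in vip.index if c[0].startswith("n")]]
        assert signal_vip.min() > 1.0
        assert (noise_vip < 1.0).mean() > 0.7

    def test_scale_equivariance_of_vip_and_coefficients(self, study_batches):
        m = unfold_batch_level(study_batches)
        res1 = BatchLevelPLS(m.X, m.y).fit(n_components=2)
        X2 = m.X.copy()
        col = X2.columns[5]
        X2[col] = X2[col] * 1000.0  # rescaling a raw column
        res2 = BatchLevelPLS(X2, m.y).fit(n_components=2)
        assert np.allclose(res1.vip.to_numpy(), res2.vip.to_numpy(), atol=1e-8)
        assert np.allclose(res1.coef.to_numpy(), res2.coef.to_numpy(), atol=1e-8)


class TestRanking:
    def test_no_passing_column_gives_empty_ranking(self):
        _, results = random_matrix_model(9, 6, seed=0, n_components=1)
        df = coefficient_sum_ranking(results, vip_threshold=1e9)
        assert df.empty

    def test_planted_negative_nutrient_ranks_first(self):
        conds = plant_titer_correlation(
            default_conditions(seed=12), "glutamate", -1, 2.0
        )
        batches = simulate_study(conds)
        batches = filter_outliers(batches, detect_outliers(batches))
        res = fit_pls(unfold_batch_level(batches))
        ranking = res.rank_nutrients()
        assert ranking.iloc[0]["variable"] == "glutamate"
        assert ranking.iloc[0]["coefficient_sum"] < 0

    def test_opposite_plants_have_opposite_sums(self):
        conds = plant_titer_correlation(default_conditions(seed=5), "leucine", -1, 2.0)
        conds = plant_titer_correlation(conds, "serine", +1, 2.0)
        batches = filter_outliers(*(lambda b: (b, detect_outliers(b)))(simulate_study(conds)))
        ranking = fit_pls(unfold_batch_level(batches)).rank_nutrients()
        r = ranking.set_index("variable")["coefficient_sum"]
        assert r["leucine"] < 0 < r["serine"]

    def test_process_variables_excluded_from_nutrient_ranking(self, study_batches):
        res = fit_pls(unfold_batch_level(study_batches))
        ranking = res.rank_nutrients()
        assert not set(ranking["variable"]) & {"VCD", "viability", "titer"}

    def test_summary_mentions_components_and_top_nutrient(self, study_batches):
        res = fit_pls(unfold_batch_level(study_batches))
        text = res.summary()
        assert "components" in text
        assert "coefficient-sum" in text


class TestComponentSelection:
    def test_selected_rank_within_cap(self, study_batches):
        model = BatchLevelPLS.from_batches(study_batches)
        a, q2 = model.select_components(max_components=5)
        assert 1 <= a <= 5
        assert q2 > 0.5  # the study design is strongly predictive of titer

    def test_too_many_components_rejected(self, study_batches):
        model = BatchLevelPLS.from_batches(study_batches)
        with pytest.raises(ValueError):
            model.fit(n_components=10**6)
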
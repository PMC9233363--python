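"""Weighted indices, the clock, the threshold rule, ROC, and Venn overlap."""

import numpy as np
import pandas as pd
import pytest

from mitomethyl.indices import (
    BrainAreaIndex,
    DrugUseClassifier,
    IndexModel,
    MethylationClock,
    acceleration_contrast,
    age_acceleration,
    build_index,
    du_threshold,
    evaluate_classifier,
    fit_clock,
    roc_auc,
    score_samples,
    venn_overlap,
)
from mitomethyl.stats import SiteTestResult


def _result(pos, effect, kind="log_odds_ratio", p=0.01):
    return SiteTestResult((pos, "H"), effect, p, kind)


def _levels(data, sites):
    return pd.DataFrame(data, columns=pd.MultiIndex.from_tuples(sites), dtype=float)


class TestBuildIndex:
    def test_single_entry_verbatim(self):
        model = build_index([_result(7, 0.7)], "DU")
        assert model.entries == (((7, "H"), 0.7),)

    def test_mixed_test_kinds_rejected(self):
        with pytest.raises(ValueError, match="test_kind"):
            build_index([_result(1, 0.5), _result(2, 0.5, kind="age_slope")], "DU")

    def test_empty_selection_advises_looser_alpha(self):
        with pytest.raises(ValueError, match="looser"):
            build_index([], "BA")

    def test_count_contract(self):
        results = [_result(i, 0.1 * (i + 1), kind="log_fold_change") for i in range(105)]
        assert len(build_index(results, "BA")) == 105

    def test_json_round_trip(self):
        model = build_index([_result(3, -0.4), _result(9, 1.2)], "DU", 0.05, area="NAcc")
        assert IndexModel.from_json(model.to_json()) == model

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            IndexModel("DU", (((1, "H"), 0.0),), 0.05)


class TestScoreSamples:
    def test_single_entry_weights_percent(self):
        model = build_index([_result(1, 1.0)], "DU")
        levels = _levels([[2.0], [4.0]], [(1, "H")])
        assert list(score_samples(model, levels)) == [2.0, 4.0]

    def test_missing_site_error_lists_positions(self):
        model = build_index([_result(99, 1.0)], "DU")
        with pytest.raises(KeyError, match="99"):
            score_samples(model, _levels([[1.0]], [(1, "H")]))

    def test_linearity_in_weights(self, rng):
        sites = [(i, "H") for i in range(1, 6)]
        levels = _levels(rng.uniform(0, 5, size=(4, 5)), sites)
        w1 = rng.normal(size=5)
        w2 = rng.normal(size=5)
        m1 = IndexModel("DU", tuple(zip(sites, w1)), 0.05)
        m2 = IndexModel("DU", tuple(zip(sites, w2)), 0.05)
        msum = IndexModel("DU", tuple(zip(sites, w1 + w2)), 0.05)
        np.testing.assert_allclose(
            score_samples(msum, levels), score_samples(m1, levels) + score_samples(m2, levels)
        )

    def test_identical_levels_give_invariant_scores(self):
        model = build_index([_result(1, 1.0), _result(2, -1.0)], "DU")
        levels = _levels([[3.0, 3.0], [5.0, 5.0]], [(1, "H"), (2, "H")])
        scores = score_samples(model, levels)
        assert scores.iloc[0] == scores.iloc[1] == 0.0


class TestClock:
    def test_exact_linear_scores(self):
        ages = np.linspace(20, 80, 12)
        scores = 0.5 * ages + 3.0
        clock = fit_clock(ages, scores)
        assert clock.r_squared == pytest.approx(1.0)
        np.testing.assert_allclose(clock.predict(scores), ages, atol=1e-9)

    def test_training_residuals_zero_mean(self, rng):
        ages = rng.uniform(20, 80, size=30)
        scores = 0.3 * ages + rng.normal(0, 5, size=30)
        clock = fit_clock(ages, scores)
        residuals = clock.predict(scores) - ages
        assert abs(residuals.mean()) < 1e-9

    def test_r_squared_is_squared_pearson(self, rng):
        ages = rng.uniform(20, 80, size=25)
        scores = ages + rng.normal(0, 20, size=25)
        clock = fit_clock(ages, scores)
        assert clock.r_squared == pytest.approx(np.corrcoef(ages, scores)[0, 1] ** 2)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_clock(np.arange(20.0, 40.0), np.full(20, 1.0))

    def test_acceleration_is_predicted_minus_chronological(self, rng):
        ages = rng.uniform(20, 80, size=20)
        scores = pd.Series(0.3 * ages + rng.normal(0, 5, 20),
                           index=[f"S{i}" for i in range(20)])
        clock = fit_clock(ages, scores)
        accel = age_acceleration(clock, scores, ages)
        np.testing.assert_allclose(accel.to_numpy(), clock.predict(scores) - ages)
        assert abs(accel.mean()) < 1e-9  # OLS residual property on the training set

    def test_recovered_r_squared_band_at_moderate_age_signal(self):
        # Parameter-recovery harness: a small site universe with a weak planted
        # age signal keeps the in-sample clock fit in a moderate band (the raw
        # P<0.05 selection inflates in-sample R^2, so the band sits above what
        # the planted signal alone would explain).
        from mitomethyl.core import build_matrix
        from mitomethyl.simulate import SimulationConfig, simulate_dataset

        r2s = []
        for seed in range(1, 11):
            config = SimulationConfig(
                genome_length=1200, n_ba_sites=0, n_du_sites=0, n_age_sites=15,
                age_slope=0.012, individual_sd=0.4, seed=seed,
            )
            _, cohort, _, calls = simulate_dataset(config)
            meta = cohort.set_index("id")
            m = build_matrix({p: d for (p, a), d in calls.items() if a == "NAcc"}, 30)
            ctrl = [i for i in m.levels.index if meta.loc[i, "group"] == "control"]
            cov = meta.loc[ctrl, ["batch", "collector", "alcohol", "pmi_class"]]
            clock = MethylationClock().fit(
                m.levels.loc[ctrl], meta.loc[ctrl, "age"].astype(float), covariates=cov
            )
            r2s.append(clock.r_squared_)
        assert 0.2 <= float(np.median(r2s)) <= 0.6

    def test_heroin_users_excluded_from_contrast(self, rng):
        ids = [f"S{i}" for i in range(20)]
        accel = pd.Series(rng.normal(size=20), index=ids)
        groups = pd.Series(["control"] * 12 + ["drug"] * 8, index=ids)
        heroin = pd.Series([False] * 14 + [True, True] + [False] * 4, index=ids)
        out = acceleration_contrast(accel, groups, heroin)
        assert out["n_drug"] == 6  # two heroin-positive individuals dropped
        assert out["n_control"] == 12


class TestThresholdRule:
    def test_degenerate_zero_scores(self):
        assert du_threshold([0.0] * 10) == 0.0

    def test_arithmetic(self):
        scores = np.array([8.0, 10.0, 12.0])
        expected = 10.0 + 1.96 * np.std(scores, ddof=1)
        assert du_threshold(scores) == pytest.approx(expected)

    def test_needs_two_scores(self):
        with pytest.raises(ValueError):
            du_threshold([1.0])

    def test_null_specificity_monte_carlo(self, rng):
        train = rng.normal(0, 1, size=10_000)
        threshold = du_threshold(train)
        fresh = rng.normal(0, 1, size=10_000)
        specificity = np.mean(fresh <= threshold)
        assert specificity == pytest.approx(0.975, abs=0.01)


class TestEvaluateClassifier:
    def test_perfect_separation(self):
        scores = [1, 2, 3, 10, 11, 12]
        labels = ["control"] * 3 + ["drug"] * 3
        ev = evaluate_classifier(scores, labels, threshold=5.0)
        assert ev.sensitivity == ev.specificity == ev.ppv == ev.npv == 1.0

    def test_all_below_threshold_ppv_undefined(self):
        ev = evaluate_classifier([1, 2, 3, 4], ["control", "control", "drug", "drug"], 10.0)
        assert ev.sensitivity == 0.0 and ev.specificity == 1.0
        assert ev.ppv is None

    def test_tie_at_threshold_is_negative_call(self):
        ev = evaluate_classifier([5.0, 5.0], ["control", "drug"], 5.0)
        assert ev.tn == 1 and ev.fn == 1 and ev.tp == 0

    def test_confusion_counts_match_brute_force(self, rng):
        scores = rng.normal(size=60)
        labels = rng.choice(["control", "drug"], size=60)
        while len(set(labels)) < 2:
            labels = rng.choice(["control", "drug"], size=60)
        thr = float(np.median(scores))
        ev = evaluate_classifier(scores, labels, thr)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for s, l in zip(scores, labels):
            call = s > thr
            truth = l == "drug"
            key = ("t" if call == truth else "f") + ("p" if call else "n")
            tally[key] += 1
        assert (ev.tp, ev.fp, ev.tn, ev.fn) == (
            tally["tp"], tally["fp"], tally["tn"], tally["fn"],
        )


class TestRocAuc:
    def test_perfect_separation_auc_one(self):
        _, auc = roc_auc([1, 2, 9, 10], ["control", "control", "drug", "drug"])
        assert auc == 1.0

    def test_null_scores_near_half(self, rng):
        scores = rng.normal(size=1000)
        labels = ["drug"] * 500 + ["control"] * 500
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.04)

    def test_equals_tie_adjusted_u_including_ties(self, rng):
        from mitomethyl.stats import mann_whitney

        scores = rng.integers(0, 6, size=80).astype(float)  # heavy ties
        labels = np.array(["drug"] * 30 + ["control"] * 50)
        _, auc = roc_auc(scores, labels)
        u, _ = mann_whitney(scores[labels == "drug"], scores[labels == "control"])
        assert auc == pytest.approx(u / (30 * 50), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=50)
        labels = rng.choice(["control", "drug"], size=50)
        while len(set(labels)) < 2:
            labels = rng.choice(["control", "drug"], size=50)
        _, auc1 = roc_auc(scores, labels)
        _, auc2 = roc_auc(np.exp(3 * scores), labels)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_roc_points_monotone_from_origin_to_corner(self, rng):
        scores = rng.normal(size=40)
        labels = ["drug"] * 15 + ["control"] * 25
        points, _ = roc_auc(scores, labels)
        assert points["fpr"].is_monotonic_increasing
        assert points["tpr"].is_monotonic_increasing
        assert (points["fpr"].iloc[0], points["tpr"].iloc[0]) == (0.0, 0.0)
        assert (points["fpr"].iloc[-1], points["tpr"].iloc[-1]) == (1.0, 1.0)


class TestVennOverlap:
    def _model(self, positions):
        return IndexModel("DU", tuple(((p, "H"), 1.0) for p in positions), 0.05)

    def test_identical_models_full_overlap(self):
        m = self._model([1, 2, 3])
        cells = venn_overlap({"a": m, "b": m})
        assert cells["a&b"] == 3
        assert cells["shared_by_2_or_more"] == 3

    def test_disjoint_models(self):
        cells = venn_overlap({"a": self._model([1, 2]), "b": self._model([3])})
        assert cells == {"a": 2, "b": 1, "shared_by_2_or_more": 0}

    def test_matches_set_algebra_oracle(self, rng):
        sets = {
            name: set(rng.choice(50, size=rng.integers(5, 20), replace=False))
            for name in ("x", "y", "z")
        }
        cells = venn_overlap({k: self._model(v) for k, v in sets.items()})
        only_x = sets["x"] - sets["y"] - sets["z"]
        xyz = sets["x"] & sets["y"] & sets["z"]
        if only_x:
            assert cells["x"] == len(only_x)
        if xyz:
            assert cells["x&y&z"] == len(xyz)


@pytest.fixture(scope="module")
def fitted(small_matrices):
    cohort, matrices = small_matrices
    meta = cohort.set_index("id")
    from mitomethyl.core import overlap_sites

    shared = overlap_sites(matrices["NAcc"], matrices["PFC"])
    ctrl = [i for i in meta.index[meta["group"] == "control"]
            if i in matrices["NAcc"].levels.index and i in matrices["PFC"].levels.index]
    a = matrices["NAcc"].levels.loc[ctrl, shared]
    b = matrices["PFC"].levels.loc[ctrl, shared]
    return cohort, matrices, BrainAreaIndex(alpha=0.05).fit(a, b), a, b


class TestEstimatorsOnSyntheticData:
    """Estimator behavior on the shared small synthetic study."""

    def test_ba_index_scores_separate_areas(self, fitted):
        from mitomethyl.stats import paired_wilcoxon

        _, _, model, a, b = fitted
        res = paired_wilcoxon(model.transform(a), model.transform(b))
        assert res.p_value < 0.01
        assert np.median(model.transform(a).to_numpy() - model.transform(b).to_numpy()) > 0

    def test_sklearn_param_interface(self, fitted):
        _, _, model, _, _ = fitted
        assert model.get_params() == {"alpha": 0.05, "pseudocount": 0.01}
        clone = BrainAreaIndex().set_params(alpha=0.005)
        assert clone.alpha == 0.005

    def test_drug_classifier_fit_predict(self, small_matrices):
        cohort, matrices = small_matrices
        meta = cohort.set_index("id")
        m = matrices["NAcc"]
        y = meta.loc[m.levels.index, "group"].to_numpy()
        cov = meta.loc[m.levels.index, ["age", "batch", "collector", "alcohol", "pmi_class"]]
        clf = DrugUseClassifier(alpha=0.05).fit(m.levels, y, covariates=cov)
        predictions = clf.predict(m.levels)
        assert set(predictions) <= {"control", "drug"}
        ev = clf.evaluate(m.levels, y)
        assert ev.auc > 0.7  # strong planted effects separate the groups
        assert ev.specificity >= 0.8

    def test_clock_trained_on_controls_scores_drug_group(self, small_matrices):
        cohort, matrices = small_matrices
        meta = cohort.set_index("id")
        m = matrices["NAcc"]
        ctrl = [i for i in m.levels.index if meta.loc[i, "group"] == "control"]
        cov = meta.loc[ctrl, ["batch", "collector", "alcohol", "pmi_class"]]
        clock = MethylationClock(alpha=0.05).fit(
            m.levels.loc[ctrl], meta.loc[ctrl, "age"].astype(float), covariates=cov
        )
        assert 0 <= clock.r_squared_ <= 1
        accel = clock.acceleration(m.levels, meta.loc[m.levels.index, "age"].astype(float))
        # training controls: residuals average to zero by OLS construction
        assert abs(accel[ctrl].mean()) < 1e-8
        assert set(accel.index) == set(m.levels.index)
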
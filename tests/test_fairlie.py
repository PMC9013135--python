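"""Fairlie-type decomposition: fitting, matching, sequential substitution,
randomised averaging, and the exact telescoping/order-invariance identities."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import wealthgap as wg
from wealthgap.exceptions import EstimationError, SeparationError, ValidationError
from wealthgap.fairlie import (
    LogitModel,
    fit_pooled_logit,
    match_samples,
    sequential_contributions,
)


def toy_model(coeffs, blocks=None):
    params = pd.Series({"const": coeffs.get("const", 0.0), **{k: v for k, v in coeffs.items() if k != "const"}})
    if blocks is None:
        blocks = {k: [k] for k in coeffs if k != "const"}
    return LogitModel(params=params, blocks=blocks)


class TestFitPooledLogit:
    def test_intercept_only_closed_form(self):
        X = pd.DataFrame(index=range(8))
        y = [1, 1, 0, 0, 0, 0, 0, 0]
        m = fit_pooled_logit(X, y)
        assert m.intercept == pytest.approx(float(logit(0.25)), rel=1e-6)

    def test_saturated_binary_closed_form(self):
        # group death rates 0.2 / 0.8: slope = logit(0.8) - logit(0.2) = 2.7726
        x = [0] * 10 + [1] * 10
        y = [1] * 2 + [0] * 8 + [1] * 8 + [0] * 2
        m = fit_pooled_logit(pd.DataFrame({"x": x}), y)
        assert m.params["x"] == pytest.approx(float(logit(0.8) - logit(0.2)), rel=1e-6)

    def test_frequency_weight_expansion_oracle(self):
        # integer weights equal an unweighted fit on row-expanded data
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.normal(size=8), "z": rng.integers(0, 2, 8).astype(float)})
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0])
        w = np.array([1, 3, 2, 1, 4, 2, 1, 3])
        weighted = fit_pooled_logit(X, y, w)
        idx = np.repeat(np.arange(8), w)
        expanded = fit_pooled_logit(X.iloc[idx].reset_index(drop=True), y[idx])
        assert np.allclose(weighted.params, expanded.params, rtol=1e-6)

    def test_one_outcome_class_errors(self):
        with pytest.raises(EstimationError):
            fit_pooled_logit(pd.DataFrame({"x": [0.0, 1.0]}), [0, 0])

    def test_separation_names_column(self):
        X = pd.DataFrame({"fine": [0, 1, 0, 1, 0, 1, 0, 1.0], "sep": [0, 0, 0, 0, 1, 1, 1, 1.0]})
        with pytest.raises(SeparationError, match="sep"):
            fit_pooled_logit(X, [0, 0, 0, 0, 1, 1, 1, 1])


class TestMatchSamples:
    def test_identical_equal_groups(self):
        X = pd.DataFrame({"x": [0.1, 0.5, 0.9, 0.3]})
        model = toy_model({"x": 1.0})
        Xp, Xn = match_samples(X, X.copy(), model, seed=0)
        pd.testing.assert_frame_equal(Xp, Xn)

    def test_subsample_size_contract(self, rng):
        Xp = pd.DataFrame({"x": rng.normal(size=100)})
        Xn = pd.DataFrame({"x": rng.normal(size=60)})
        model = toy_model({"x": 1.0})
        A, B = match_samples(Xp, Xn, model, seed=1)
        assert len(A) == len(B) == 60

    def test_sort_and_zip_oracle(self):
        # 5 vs 5 distinct predicted probabilities: matching is rank sorting
        Xp = pd.DataFrame({"x": [3.0, 1.0, 5.0, 2.0, 4.0]})
        Xn = pd.DataFrame({"x": [0.4, 0.1, 0.5, 0.2, 0.3]})
        model = toy_model({"x": 1.0})
        A, B = match_samples(Xp, Xn, model, seed=0)
        assert A["x"].tolist() == sorted(Xp["x"])
        assert B["x"].tolist() == sorted(Xn["x"])

    def test_deterministic_given_seed(self, rng):
        Xp = pd.DataFrame({"x": rng.normal(size=50)})
        Xn = pd.DataFrame({"x": rng.normal(size=30)})
        model = toy_model({"x": 1.0})
        a = match_samples(Xp, Xn, model, seed=7)
        b = match_samples(Xp, Xn, model, seed=7)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_empty_group(self):
        model = toy_model({"x": 1.0})
        with pytest.raises(ValidationError):
            match_samples(pd.DataFrame({"x": []}), pd.DataFrame({"x": [1.0]}), model, 0)


class TestSequentialContributions:
    def test_hand_logistic_example(self):
        # 4 pairs, alpha*=0, beta*=1, poor x=(1,1,1,0), non-poor x=(0,0,1,0):
        # contribution = 1/4 * 2 * (F(1) - F(0)) = 0.11553
        model = toy_model({"x": 1.0})
        Xp = pd.DataFrame({"x": [1.0, 1.0, 1.0, 0.0]})
        Xn = pd.DataFrame({"x": [0.0, 0.0, 1.0, 0.0]})
        contrib, explained = sequential_contributions(Xp, Xn, model, ["x"])
        expected = 0.25 * 2 * (expit(1.0) - expit(0.0))
        assert contrib["x"] == pytest.approx(expected, abs=1e-12)
        assert contrib["x"] == pytest.approx(0.11553, abs=5e-6)
        assert explained == contrib["x"]

    def test_identical_pairs_zero(self):
        model = toy_model({"a": 0.5, "b": -1.0})
        X = pd.DataFrame({"a": [0.0, 1.0, 1.0], "b": [1.0, 0.0, 1.0]})
        contrib, explained = sequential_contributions(X, X.copy(), model, ["b", "a"])
        assert contrib == {"b": 0.0, "a": 0.0}
        assert explained == 0.0

    def test_orderings_share_explained_exactly(self, rng):
        model = toy_model({"a": 0.8, "b": -0.4, "c": 0.3})
        Xp = pd.DataFrame(rng.integers(0, 2, (40, 3)).astype(float), columns=["a", "b", "c"])
        Xn = pd.DataFrame(rng.integers(0, 2, (40, 3)).astype(float), columns=["a", "b", "c"])
        explained = set()
        for ordering in itertools.permutations(["a", "b", "c"]):
            contrib, expl = sequential_contributions(Xp, Xn, model, list(ordering))
            assert sum(contrib.values()) == pytest.approx(expl, abs=1e-14)
            explained.add(expl)
        assert len(explained) == 1  # exactly order-invariant

    def test_symmetry_negates_gap(self, rng):
        model = toy_model({"a": 0.8, "b": -0.4})
        Xp = pd.DataFrame(rng.integers(0, 2, (30, 2)).astype(float), columns=["a", "b"])
        Xn = pd.DataFrame(rng.integers(0, 2, (30, 2)).astype(float), columns=["a", "b"])
        _, forward = sequential_contributions(Xp, Xn, model, ["a", "b"])
        _, backward = sequential_contributions(Xn, Xp, model, ["a", "b"])
        assert backward == pytest.approx(-forward, abs=1e-14)

    def test_zero_coefficients_zero_contributions(self, rng):
        model = toy_model({"const": -1.2, "a": 0.0, "b": 0.0})
        Xp = pd.DataFrame(rng.integers(0, 2, (20, 2)).astype(float), columns=["a", "b"])
        Xn = pd.DataFrame(rng.integers(0, 2, (20, 2)).astype(float), columns=["a", "b"])
        contrib, explained = sequential_contributions(Xp, Xn, model, ["a", "b"])
        assert contrib == {"a": 0.0, "b": 0.0}
        assert explained == 0.0

    def test_invalid_ordering(self):
        model = toy_model({"a": 1.0, "b": 1.0})
        X = pd.DataFrame({"a": [0.0], "b": [1.0]})
        with pytest.raises(ValidationError):
            sequential_contributions(X, X, model, ["a", "a"])


def two_covariate_frame(n_poor=60, n_non=40, seed=5):
    """Small frame with compositional differences on both covariates."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, p_edu, p_res in (("poor", n_poor, 0.7, 0.6), ("non", n_non, 0.3, 0.4)):
        for _ in range(n):
            edu = rng.random() < p_edu
            res = rng.random() < p_res
            eta = -1.0 + 0.9 * edu + 0.5 * res + 0.2 * (group == "poor")
            rows.append(
                {
                    "country_id": "T",
                    "cluster_id": "T-0",
                    "weight": 1.0,
                    "wealth_quintile": 1 if group == "poor" else 5,
                    "died": int(rng.random() < expit(eta)),
                    "edu": "low" if edu else "high",
                    "res": "rural" if res else "urban",
                }
            )
    return pd.DataFrame(rows)


class TestFairlieDecompose:
    def test_pure_group_effect_explained_near_zero(self):
        # identical covariate distributions, beta_poor != 0: explained ~ 0
        cfg = wg.PopulationConfig(
            n_countries=1,
            clusters_per_country=100,
            births_per_cluster=100,
            covariates=(
                wg.CovariateSpec("x", ("a", "b"), p_poor=(0.5, 0.5), p_non_poor=(0.5, 0.5)),
            ),
            outcome=wg.OutcomeModel(
                intercept=float(logit(0.05)), poor_effect=0.7, covariate_effects={"x": {"a": 0.5}}
            ),
        )
        df = wg.generate_survey(cfg, 0, 3)
        frame = wg.build_analysis_frame(df, ses_indicators=False)
        res = wg.fairlie_decompose(frame, n_orderings=10, n_subsamples=3, seed=1)
        assert res.total_gap > 0.01  # the group effect creates a real gap
        assert abs(res.explained) < 0.2 * res.total_gap

    def test_exhaustive_enumeration_oracle(self):
        # brute force over all equal-size subsets x orderings on a tiny frame
        df = two_covariate_frame(n_poor=6, n_non=4, seed=11)
        frame = wg.build_analysis_frame(df, ses_indicators=False, vif_threshold=1e9)
        model_res = wg.fairlie_decompose(
            frame, n_orderings=2, n_subsamples=4000, seed=2, keep_replications=True
        )

        # oracle: same fitted model, explicit enumeration
        from wealthgap.fairlie import GROUP_COLUMN
        from wealthgap.harmonize import dummy_design

        data = frame.data
        design, blocks = dummy_design(data, frame.covariates)
        design[GROUP_COLUMN] = (data["wealth_quintile"] <= 2).astype(float)
        model = fit_pooled_logit(
            design, data["died"], data["weight"], blocks=blocks, group_col=GROUP_COLUMN
        )
        X = design.drop(columns=[GROUP_COLUMN])
        poor_mask = design[GROUP_COLUMN] == 1
        Xp_all, Xn = X[poor_mask], X[~poor_mask]
        m = len(Xn)
        totals = {c: [] for c in frame.covariates}
        for subset in itertools.combinations(range(len(Xp_all)), m):
            Xp = Xp_all.iloc[list(subset)]
            op = np.argsort(model.predict_prob(Xp), kind="stable")
            on = np.argsort(model.predict_prob(Xn), kind="stable")
            A = Xp.iloc[op].reset_index(drop=True)
            B = Xn.iloc[on].reset_index(drop=True)
            for ordering in itertools.permutations(frame.covariates):
                contrib, _ = sequential_contributions(A, B, model, list(ordering))
                for c, v in contrib.items():
                    totals[c].append(v)
        for c in frame.covariates:
            oracle = np.mean(totals[c])
            mc_se = np.std(totals[c]) / np.sqrt(model_res.n_replications / 4)
            assert model_res.contributions[c] == pytest.approx(
                oracle, abs=max(4 * mc_se, 1e-4)
            )

    def test_telescoping_every_replication(self):
        df = two_covariate_frame(n_poor=80, n_non=50, seed=7)
        frame = wg.build_analysis_frame(df, ses_indicators=False, vif_threshold=1e9)
        res = wg.fairlie_decompose(frame, n_orderings=8, n_subsamples=4, seed=3)
        gap = np.abs(res.replications.sum(axis=1) - res.explained_reps)
        assert gap.max() <= 1e-10 * max(1.0, np.abs(res.explained_reps).max())

    def test_reproducible_given_seed(self):
        df = two_covariate_frame(seed=9)
        frame = wg.build_analysis_frame(df, ses_indicators=False, vif_threshold=1e9)
        a = wg.fairlie_decompose(frame, n_orderings=5, n_subsamples=2, seed=42)
        b = wg.fairlie_decompose(frame, n_orderings=5, n_subsamples=2, seed=42)
        assert a.contributions == b.contributions
        assert a.explained == b.explained

    def test_replication_count(self):
        df = two_covariate_frame(seed=9)
        frame = wg.build_analysis_frame(df, ses_indicators=False, vif_threshold=1e9)
        res = wg.fairlie_decompose(frame, n_orderings=5, n_subsamples=3, seed=0)
        assert res.n_replications == 15
        assert res.replications.shape == (15, len(frame.covariates))

    def test_invalid_replication_args(self, default_frame):
        with pytest.raises(ValidationError):
            wg.fairlie_decompose(default_frame, n_orderings=0, seed=1)


class TestContributionTable:
    def _result(self, contributions, total_gap, seed=0):
        explained = sum(contributions.values())
        return wg.DecompositionResult(
            total_gap=total_gap,
            explained=explained,
            explained_sd=0.0,
            contributions=contributions,
            contribution_sd={k: 0.0 for k in contributions},
            percent_of_gap={
                k: (100 * v / total_gap if total_gap else float("nan"))
                for k, v in contributions.items()
            },
            percent_of_explained={
                k: (100 * v / explained if explained else float("nan"))
                for k, v in contributions.items()
            },
            n_replications=1,
            seed=seed,
            covariates=list(contributions),
        )

    def test_single_covariate_full_share(self):
        res = self._result({"edu": 0.02}, total_gap=0.04)
        wide, long = wg.contribution_table({"A": res})
        assert wide.loc["A", "edu"] == pytest.approx(50.0)
        assert res.percent_of_explained["edu"] == pytest.approx(100.0)

    def test_zero_gap_flagged_nan(self):
        res = self._result({"edu": 0.01}, total_gap=0.0)
        wide, long = wg.contribution_table({"A": res})
        assert np.isnan(wide.loc["A", "edu"])
        assert long.loc[0, "contribution"] == pytest.approx(0.01)

    def test_three_country_reshape_oracle(self):
        results = {
            c: self._result({"edu": v, "res": -v / 2}, total_gap=0.05)
            for c, v in (("A", 0.01), ("B", 0.02), ("C", 0.03))
        }
        wide, long = wg.contribution_table(results)
        assert wide.shape == (3, 2)
        for c in results:
            for cov in ("edu", "res"):
                assert wide.loc[c, cov] == pytest.approx(results[c].percent_of_gap[cov])
        assert len(long) == 6

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            wg.contribution_table({})
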
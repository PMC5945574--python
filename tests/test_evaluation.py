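"""Cross-validation machinery, predictability ANOVA, Tukey letters,
subsampling experiments and broad-sense heritability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridgs import evaluation, simdata
from hybridgs.evaluation import (
    CVResult,
    cross_validate,
    estimate_broad_sense_H,
    kfold_partition,
    predictability,
    predictability_anova,
    subsample_experiment,
    tukey_groups,
)


class TestFolds:
    def test_balanced_partition_covers_all(self):
        f = kfold_partition(10, 5, seed=1)
        sizes = [len(f.test_indices(k)) for k in range(1, 6)]
        assert sizes == [2] * 5
        assert sorted(np.concatenate([f.test_indices(k) for k in range(1, 6)])) == list(range(10))

    def test_575_samples_five_folds_of_115(self):
        f = kfold_partition(575, 5, seed=3)
        assert all(len(f.test_indices(k)) == 115 for k in range(1, 6))

    def test_deterministic_given_seed(self):
        a = kfold_partition(50, 5, seed=9)
        b = kfold_partition(50, 5, seed=9)
        np.testing.assert_array_equal(a.fold_of, b.fold_of)

    def test_unbalanced_sizes_differ_by_at_most_one(self):
        f = kfold_partition(13, 5, seed=0)
        sizes = sorted(len(f.test_indices(k)) for k in range(1, 6))
        assert max(sizes) - min(sizes) <= 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            kfold_partition(3, 5, seed=0)


class TestPredictability:
    def test_perfect_and_inverted_agreement(self):
        v = np.array([1.0, 2.0, 5.0, 3.0])
        assert predictability(v, v) == pytest.approx(1.0)
        assert predictability(v, -v) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        assert predictability([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            predictability([1, 1, 1], [1, 2, 3])


class _OracleModel:
    """Test hook: 'learner' that returns a fixed lookup of true values."""

    def __init__(self, table):
        self.table = table

    def predict(self, M):
        return np.array([self.table[tuple(row)] for row in M])


def oracle_factory(truth_by_genotype):
    def fit(M, y):
        return _OracleModel(truth_by_genotype)

    fit.__name__ = "oracle"
    return fit


class TestCrossValidate:
    def test_oracle_method_attains_near_one_at_high_heritability(self, tiny_bundle):
        hybrids = tiny_bundle.hybrids
        truth = tiny_bundle.truth["HI"]
        g = truth["mu"] + truth["g"]
        table = {tuple(row): g[i] for i, row in enumerate(hybrids.calls)}
        y = tiny_bundle.hybrid_means["HI"].to_numpy()
        cv = cross_validate(oracle_factory(table), hybrids, y, replicates=3, seed=1)
        # r is bounded by sqrt(H) ~ 0.92 at H = 0.85; the oracle should sit
        # near that ceiling (sampling noise at n=60 pulls it down a little)
        assert cv.records["r"].mean() > 0.8

    def test_every_sample_predicted_once_per_replicate(self, tiny_bundle):
        """The pooled out-of-fold vector covers each sample exactly once."""
        n = tiny_bundle.hybrids.n_samples
        f = kfold_partition(n, 5, seed=4)
        seen = np.concatenate([f.test_indices(k) for k in range(1, 6)])
        assert len(seen) == n and len(set(seen)) == n

    def test_high_heritability_trait_beats_low_in_paired_replicates(self, tiny_bundle):
        hybrids = tiny_bundle.hybrids
        reps = 6
        hi = cross_validate(
            "gblup", hybrids, tiny_bundle.hybrid_means["HI"].to_numpy(),
            replicates=reps, seed=2, trait="HI",
        ).records["r"]
        lo = cross_validate(
            "gblup", hybrids, tiny_bundle.hybrid_means["LO"].to_numpy(),
            replicates=reps, seed=2, trait="LO",
        ).records["r"]
        wins = int((hi.to_numpy() > lo.to_numpy()).sum())
        assert wins >= reps - 1


def synthetic_cv_records(a=8, b=6, reps=20, seed=0, effects=True):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(a):
        for j in range(b):
            mu = 0.5 + (0.04 * i if effects else 0.0) + (0.01 * j if effects else 0.0)
            for rep in range(1, reps + 1):
                rows.append((f"T{i}", f"M{j}", rep, mu + rng.normal(0, 0.01)))
    return CVResult(pd.DataFrame(rows, columns=["trait", "method", "replicate", "r"]))


class TestAnova:
    def test_factorial_degrees_of_freedom(self):
        table = predictability_anova(synthetic_cv_records(8, 6, 20))
        assert table["df"].tolist() == [7, 5, 35, 912]

    def test_all_equal_records_give_zero_ss(self):
        cv = synthetic_cv_records(3, 2, 4, effects=False)
        cv.records["r"] = 0.7
        table = predictability_anova(cv)
        assert np.allclose(table["SS"], 0.0)

    def test_toy_table_matches_mean_decomposition_oracle(self):
        """Brute-force sums-of-squares decomposition on a 2x2x3 table."""
        cv = synthetic_cv_records(2, 2, 3, seed=5)
        table = predictability_anova(cv)
        df = cv.records
        grand = df["r"].mean()
        ss_total = ((df["r"] - grand) ** 2).sum()
        assert table["SS"].sum() == pytest.approx(ss_total, abs=1e-10)
        # trait SS by direct enumeration
        ss_trait = sum(
            len(sub) * (sub["r"].mean() - grand) ** 2 for _, sub in df.groupby("trait")
        )
        assert table.loc[0, "SS"] == pytest.approx(ss_trait, abs=1e-10)

    def test_unbalanced_records_rejected(self):
        cv = synthetic_cv_records(2, 2, 3)
        cv.records.drop(index=[0], inplace=True)
        with pytest.raises(ValueError):
            predictability_anova(cv)


class TestTukey:
    def test_identical_levels_share_a_letter(self):
        cv = synthetic_cv_records(2, 2, 10, effects=False)
        letters = tukey_groups(cv, "trait")
        assert letters["T0"] == letters["T1"]

    def test_widely_separated_levels_get_distinct_letters(self):
        cv = synthetic_cv_records(2, 2, 10, effects=False)
        cv.records.loc[cv.records["trait"] == "T1", "r"] += 1.0
        letters = tukey_groups(cv, "trait")
        assert set(letters["T0"]) & set(letters["T1"]) == set()
        assert letters["T1"] == "A"  # higher mean gets the first letter

    def test_pairwise_calls_match_studentized_range_oracle(self):
        """4-level toy: significance of each pair against a direct
        studentized-range computation."""
        cv = synthetic_cv_records(4, 1, 10, seed=8)
        letters = tukey_groups(cv, "trait")
        anova = predictability_anova_single(cv)
        ms, dfr = anova
        means = cv.records.groupby("trait")["r"].mean()
        n_per = 10
        qcrit = stats.studentized_range.ppf(0.95, 4, dfr)
        for a in means.index:
            for b in means.index:
                if a >= b:
                    continue
                signif = abs(means[a] - means[b]) > qcrit * np.sqrt(ms / n_per)
                share = bool(set(letters[a]) & set(letters[b]))
                assert share != signif


def predictability_anova_single(cv):
    """Residual MS and df for a one-factor-times-method layout used above."""
    table = predictability_anova(cv)
    resid = table[table["source"] == "residual"].iloc[0]
    return float(resid["MS"]), int(resid["df"])


class TestSubsample:
    def test_full_size_matches_plain_cv_within_noise(self, tiny_bundle):
        hybrids = tiny_bundle.hybrids
        y = tiny_bundle.hybrid_means["HI"].to_numpy()
        full = cross_validate("gblup", hybrids, y, replicates=5, seed=0)
        tab = subsample_experiment(
            "individuals", [hybrids.n_samples], "gblup", hybrids, y,
            selections_per_size=5, seed=0,
        )
        pooled_sd = np.sqrt(full.records["r"].std() ** 2 + tab["sd"].iloc[0] ** 2)
        assert abs(tab["mean"].iloc[0] - full.records["r"].mean()) < 2 * pooled_sd + 1e-6

    def test_size_exceeding_axis_rejected(self, tiny_bundle):
        with pytest.raises(ValueError):
            subsample_experiment(
                "markers", [10**6], "gblup", tiny_bundle.hybrids,
                tiny_bundle.hybrid_means["HI"].to_numpy(), selections_per_size=1,
            )


class TestHeritability:
    @staticmethod
    def simulate_layout(n_g, s2_g, s2_ge, s2_eps, e=2, r=2, seed=0, mu=10.0):
        rng = np.random.default_rng(seed)
        g = rng.normal(0, np.sqrt(s2_g), n_g)
        rows = []
        for i in range(n_g):
            for j in range(e):
                ge = rng.normal(0, np.sqrt(s2_ge)) if s2_ge else 0.0
                for l in range(r):
                    eps = rng.normal(0, np.sqrt(s2_eps)) if s2_eps else 0.0
                    rows.append((f"h{i}", f"E{j}", l + 1, mu + g[i] + ge + eps))
        return pd.DataFrame(rows, columns=["hybrid_id", "environment", "replicate", "value"])

    def test_no_noise_gives_heritability_near_one(self):
        df = self.simulate_layout(500, 1.0, 0.0, 0.0)
        vc = estimate_broad_sense_H(df)
        assert vc.H > 0.99

    def test_recovers_two_thirds_closed_form(self):
        """(s2_g, s2_ge, s2_eps) = (1, 0.5, 1) with e=r=2 gives H = 2/3."""
        hs = [
            estimate_broad_sense_H(self.simulate_layout(200, 1.0, 0.5, 1.0, seed=s)).H
            for s in range(40)
        ]
        assert np.mean(hs) == pytest.approx(2 / 3, abs=0.03)

    def test_signal_destroyed_by_permutation(self):
        df = self.simulate_layout(300, 1.0, 0.2, 0.5, seed=2)
        rng = np.random.default_rng(0)
        for env, sub in df.groupby("environment"):
            perm = rng.permutation(sub["value"].to_numpy())
            df.loc[sub.index, "value"] = perm
        vc = estimate_broad_sense_H(df)
        assert vc.H < 0.1

    def test_scale_and_shift_invariance(self):
        df = self.simulate_layout(100, 1.0, 0.5, 1.0, seed=3)
        h0 = estimate_broad_sense_H(df).H
        df2 = df.assign(value=3.0 * df["value"] + 100.0)
        assert estimate_broad_sense_H(df2).H == pytest.approx(h0, abs=1e-12)

    def test_single_environment_rejected(self):
        df = self.simulate_layout(20, 1, 0.5, 1.0, e=1)
        with pytest.raises(ValueError):
            estimate_broad_sense_H(df)

    def test_estimates_simulated_bundle_heritability(self, tiny_bundle):
        vc = estimate_broad_sense_H(tiny_bundle.phenotypes, trait="HI")
        assert vc.H == pytest.approx(0.85, abs=0.08)
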
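import itertools

import numpy as np
import pandas as pd
import pytest

from shmctm import (
    Cohort,
    differential_abundance,
    dichotomize,
    gene_set_score,
    protein_score,
    qc_and_impute,
)


def make_cohort(values: pd.DataFrame, group=None) -> Cohort:
    n = len(values)
    samples = pd.DataFrame(
        {
            "group": group if group is not None else ["case"] * n,
            "survival_time": 100.0,
            "event": 0,
            "sex": "female",
            "age_at_diagnosis": 60.0,
            "cancer_type": "c1",
            "sampling_lag": 0.0,
        },
        index=values.index,
    )
    return Cohort(values, samples)


class TestQcAndImpute:
    def test_no_missing_values_is_identity(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(
            rng.normal(size=(12, 5)),
            index=[f"s{i}" for i in range(12)],
            columns=list("abcde"),
        )
        out = qc_and_impute(make_cohort(vals))
        pd.testing.assert_frame_equal(out.values, vals)

    def test_feature_above_threshold_dropped_at_boundary(self):
        vals = pd.DataFrame(
            np.ones((100, 3)),
            index=[f"s{i}" for i in range(100)],
            columns=["keep20", "drop21", "full"],
        )
        vals.iloc[:20, 0] = np.nan  # exactly 20% missing: kept
        vals.iloc[:21, 1] = np.nan  # 21% missing: dropped
        out = qc_and_impute(make_cohort(vals))
        assert list(out.values.columns) == ["keep20", "full"]

    def test_constant_neighbors_impute_the_shared_value(self):
        vals = pd.DataFrame(
            np.full((11, 4), 7.0),
            index=[f"s{i}" for i in range(11)],
            columns=list("abcd"),
        )
        vals.iloc[0, 0] = np.nan
        out = qc_and_impute(make_cohort(vals), k=10)
        assert out.values.iloc[0, 0] == pytest.approx(7.0)

    def test_observed_values_untouched(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(
            rng.normal(size=(30, 4)),
            index=[f"s{i}" for i in range(30)],
            columns=list("abcd"),
        )
        vals.iloc[0, 0] = np.nan
        out = qc_and_impute(make_cohort(vals), k=5)
        observed = ~vals.isna()
        assert np.allclose(out.values.to_numpy()[observed], vals.to_numpy()[observed])

    def test_all_missing_sample_is_an_error(self):
        vals = pd.DataFrame(
            [[np.nan, np.nan], [1.0, 2.0], [1.0, 2.0]],
            index=["s0", "s1", "s2"],
            columns=["a", "b"],
        )
        with pytest.raises(ValueError, match="all features missing"):
            qc_and_impute(make_cohort(vals))


def gsva_oracle(values: pd.DataFrame, signature: set[str]) -> pd.Series:
    """Independent step-by-step random-walk scorer (loops, no vectorization)."""
    n = len(values)
    # midrank empirical CDF (matches average ranks under ties)
    ecdf = {g: {} for g in values.columns}
    for g in values.columns:
        col = values[g]
        for s in values.index:
            less = sum(col[t] < col[s] for t in values.index)
            equal = sum(col[t] == col[s] for t in values.index)
            ecdf[g][s] = (less + (equal + 1) / 2) / n
    scores = {}
    for s in values.index:
        order = sorted(values.columns, key=lambda g: (-ecdf[g][s], g))
        hit_total = sum(ecdf[g][s] for g in order if g in signature)
        n_miss = sum(1 for g in order if g not in signature)
        walk, pos, neg = 0.0, 0.0, 0.0
        for g in order:
            if g in signature:
                walk += ecdf[g][s] / hit_total
            else:
                walk -= 1.0 / n_miss
            pos = max(pos, walk)
            neg = min(neg, walk)
        scores[s] = pos + neg
    return pd.Series(scores)


class TestGeneSetScore:
    def toy(self, seed=0, n=6, p=9):
        rng = np.random.default_rng(seed)
        vals = pd.DataFrame(
            rng.normal(size=(n, p)),
            index=[f"s{i}" for i in range(n)],
            columns=[f"g{i}" for i in range(p)],
        )
        return make_cohort(vals)

    def test_monotone_separation(self):
        # signature genes top-ranked in s0, bottom-ranked in s1
        vals = pd.DataFrame(
            {
                "sig1": [5.0, -5.0, 0.1],
                "sig2": [4.0, -4.0, 0.2],
                "bg1": [0.0, 0.0, 0.0],
                "bg2": [0.1, 0.1, 0.3],
                "bg3": [-0.1, -0.1, 0.2],
            },
            index=["s0", "s1", "s2"],
        )
        sv = gene_set_score(make_cohort(vals), ["sig1", "sig2"])
        assert sv.scores["s0"] > sv.scores["s1"]

    def test_scores_bounded_in_unit_interval(self):
        cohort = self.toy(seed=3, n=10, p=15)
        sv = gene_set_score(cohort, ["g0", "g1", "g2", "g3"])
        assert sv.scores.between(-1, 1).all()

    def test_invariant_to_monotone_per_feature_transforms(self):
        cohort = self.toy(seed=4)
        sig = ["g0", "g1", "g2"]
        base = gene_set_score(cohort, sig).scores
        transformed = cohort.values.copy()
        transformed["g0"] = np.exp(transformed["g0"])
        transformed["g3"] = transformed["g3"] ** 3
        transformed["g5"] = 10 * transformed["g5"] + 4
        again = gene_set_score(make_cohort(transformed), sig).scores
        pd.testing.assert_series_equal(base, again)

    def test_equivariant_under_sample_permutation(self):
        cohort = self.toy(seed=5)
        sig = ["g1", "g4"]
        base = gene_set_score(cohort, sig).scores
        perm = cohort.values.sample(frac=1, random_state=2)
        permuted = gene_set_score(make_cohort(perm), sig).scores
        pd.testing.assert_series_equal(base.sort_index(), permuted.sort_index())

    def test_matches_step_by_step_oracle_on_toy(self):
        cohort = self.toy(seed=6, n=5, p=10)
        sig = ["g0", "g3", "g7"]
        sv = gene_set_score(cohort, sig)
        oracle = gsva_oracle(cohort.values, set(sig))
        pd.testing.assert_series_equal(
            sv.scores, oracle, check_names=False, atol=1e-12, rtol=0
        )

    def test_missing_signature_genes_reported(self):
        cohort = self.toy()
        with pytest.raises(ValueError, match="gX"):
            gene_set_score(cohort, ["g0", "gX", "gY"])


class TestProteinScore:
    def cohort(self):
        vals = pd.DataFrame(
            {
                "p1": [1.0, 2.0, 3.0],
                "p2": [1.0, np.nan, 5.0],
                "bg": [9.0, 9.0, 9.0],
            },
            index=["s0", "s1", "s2"],
        )
        return make_cohort(vals)

    def test_mean_of_observed_signature_proteins(self):
        sv = protein_score(self.cohort(), ["p1", "p2"])
        assert sv.scores["s0"] == pytest.approx(1.0)
        assert sv.scores["s1"] == pytest.approx(2.0)  # p2 missing: mean of observed
        assert sv.scores["s2"] == pytest.approx(4.0)

    def test_single_protein_score_is_its_value(self):
        sv = protein_score(self.cohort(), ["p1"])
        assert sv.scores.tolist() == [1.0, 2.0, 3.0]

    def test_no_signature_proteins_is_an_error(self):
        with pytest.raises(ValueError):
            protein_score(self.cohort(), ["absent"])

    def test_linearity_in_the_data(self):
        cohort = self.cohort()
        base = protein_score(cohort, ["p1", "p2"]).scores
        shifted = cohort.values.copy()
        shifted[["p1", "p2"]] += 2.5
        again = protein_score(make_cohort(shifted), ["p1", "p2"]).scores
        assert np.allclose(again, base + 2.5)


class TestDichotomize:
    def test_level_is_high_iff_above_mean(self):
        sv = dichotomize(pd.Series([1.0, 2.0, 3.0, 10.0], index=list("abcd")))
        assert sv.cutoff == pytest.approx(4.0)
        assert sv.levels.tolist() == ["low", "low", "low", "high"]
        # reproducible from the stored cutoff
        assert ((sv.scores > sv.cutoff) == (sv.levels == "high")).all()


def ranksum_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[: len(x)].sum()
    n = len(pooled)
    stats = [
        ranks[list(idx)].sum() for idx in itertools.combinations(range(n), len(x))
    ]
    stats = np.array(stats)
    mean = stats.mean()
    extreme = np.abs(stats - mean) >= abs(obs - mean) - 1e-9
    return extreme.mean()


class TestDifferentialAbundance:
    def two_group(self, case_vals, ctrl_vals, feature="f"):
        vals = pd.DataFrame(
            {feature: list(case_vals) + list(ctrl_vals)},
            index=[f"s{i}" for i in range(len(case_vals) + len(ctrl_vals))],
        )
        vals["pad"] = 0.0
        groups = ["case"] * len(case_vals) + ["control"] * len(ctrl_vals)
        return make_cohort(vals, group=groups)

    def test_identical_distributions_give_unit_p(self):
        cohort = self.two_group([1, 2, 3, 4], [4, 3, 2, 1])
        out = differential_abundance(cohort, features=["f"])
        assert out.loc[0, "p"] == pytest.approx(1.0)
        assert out.loc[0, "log2fc"] == pytest.approx(0.0)

    def test_constant_shift_appears_as_log2fc(self):
        case = np.array([1.0, 2.0, 3.0, 4.5])
        cohort = self.two_group(case + 1.0, case)
        out = differential_abundance(cohort, features=["f"])
        assert out.loc[0, "log2fc"] == pytest.approx(1.0)

    def test_matches_exact_enumeration_oracle_six_v_six(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=6)
        y = rng.normal(loc=1.0, size=6)
        cohort = self.two_group(x, y)
        out = differential_abundance(cohort, features=["f"])
        assert out.loc[0, "p"] == pytest.approx(ranksum_oracle(x, y))

    def test_empty_group_is_an_error(self):
        cohort = self.two_group([1.0, 2.0], [3.0, 4.0])
        cohort.samples["group"] = "case"
        with pytest.raises(ValueError, match="nonempty"):
            differential_abundance(cohort, features=["f"])

    def test_bh_adjustment_across_features(self):
        rng = np.random.default_rng(11)
        vals = pd.DataFrame(
            rng.normal(size=(20, 6)),
            index=[f"s{i}" for i in range(20)],
            columns=[f"g{i}" for i in range(6)],
        )
        cohort = make_cohort(vals, group=["case"] * 10 + ["control"] * 10)
        out = differential_abundance(cohort)
        assert (out.sort_values("p")["adj_p"]).is_monotonic_increasing
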
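"""Wilks Λ, Rao F, diagnostics, Mahalanobis, LDA — oracles and identities."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from seedmorph import (
    SeedDiscriminantAnalysis,
    canonical_scores,
    f_to_remove,
    fit_discriminant,
    lda_classify,
    mahalanobis_matrix,
    rao_f_approx,
    sample_trait_table,
    summarize_classification,
    variable_diagnostics,
    wilks_lambda,
)
from seedmorph.exceptions import SingularScatterError, TraitTableError


def _toy_table(rng_seed=0, shift=(0.0, 0.0, 3.0)):
    """Three tiny groups on two traits with known arithmetic."""
    rng = np.random.default_rng(rng_seed)
    rows = []
    for g, dx in zip("ABC", shift):
        for _ in range(4):
            rows.append(
                {
                    "species": g,
                    "surface_um2": dx + rng.normal(),
                    "profile_um": -dx + rng.normal(),
                }
            )
    return pd.DataFrame(rows)


class TestWilksLambda:
    def test_identical_group_means_give_lambda_one(self):
        base = _toy_table(shift=(0, 0, 0))
        one = base[base["species"] == "A"]
        dup = pd.concat([one, one.assign(species="A2")], ignore_index=True)
        lam = wilks_lambda(dup, traits=["surface_um2", "profile_um"])
        assert lam == pytest.approx(1.0, abs=1e-9)

    def test_two_groups_one_trait_matches_t_statistic(self):
        """Λ = 1/(1 + t²/(N−2)) for the two-sample pooled t statistic."""
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([4.0, 5.0, 7.0])
        table = pd.DataFrame(
            {"species": ["A"] * 3 + ["B"] * 3, "surface_um2": np.concatenate([a, b])}
        )
        lam = wilks_lambda(table, traits=["surface_um2"])
        t = stats.ttest_ind(a, b, equal_var=True).statistic
        assert lam == pytest.approx(1.0 / (1.0 + t**2 / 4.0), rel=1e-12)

    def test_eigenvalue_product_identity(self, trait_table):
        """Λ equals the product of 1/(1+λ_i) over canonical eigenvalues."""
        model = fit_discriminant(trait_table, "species")
        prod = np.prod(1.0 / (1.0 + model.eigenvalues_))
        assert model.wilks_lambda_ == pytest.approx(prod, rel=1e-8)

    def test_synthetic_species_strongly_separated(self, trait_table):
        assert wilks_lambda(trait_table, "species") < 0.05

    def test_singular_scatter_advises_trait_removal(self, trait_table):
        dup = trait_table.assign(copy_trait=trait_table["surface_um2"])
        with pytest.raises(SingularScatterError, match="tolerance"):
            wilks_lambda(
                dup, traits=["surface_um2", "copy_trait", "angle_deg"]
            )


class TestRaoApproximation:
    def test_printed_degrees_of_freedom(self):
        assert (rao_f_approx(0.5, 6, 28, 1260).df1,
                rao_f_approx(0.5, 6, 28, 1260).df2) == (162, 7217)
        assert (rao_f_approx(0.5, 6, 10, 1260).df1,
                rao_f_approx(0.5, 6, 10, 1260).df2) == (54, 6352)

    def test_single_trait_reduces_to_anova_f(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, 1.0, size=12) for m in (0.0, 0.5, 1.5, 2.0)]
        table = pd.DataFrame(
            {
                "species": np.repeat(list("ABCD"), 12),
                "surface_um2": np.concatenate(groups),
            }
        )
        lam = wilks_lambda(table, traits=["surface_um2"])
        rep = rao_f_approx(lam, p=1, g=4, N=48)
        f_ref = stats.f_oneway(*groups)
        assert (rep.df1, rep.df2) == (3, 44)
        assert rep.F == pytest.approx(f_ref.statistic, rel=1e-9)
        assert rep.p_value == pytest.approx(f_ref.pvalue, rel=1e-6)

    def test_domain_violations(self):
        with pytest.raises(ValueError):
            rao_f_approx(0.0, 6, 10, 1260)
        with pytest.raises(ValueError):
            rao_f_approx(0.5, 6, 1, 1260)


class TestVariableDiagnostics:
    def test_f_to_remove_closed_form(self, trait_table):
        diag = variable_diagnostics(trait_table, "species")
        N, g, p = len(trait_table), 10, 6
        for _, row in diag.iterrows():
            expected = (
                (1 - row["partial_lambda"]) / row["partial_lambda"]
                * ((N - g - p + 1) / (g - 1))
            )
            assert row["F_to_remove"] == pytest.approx(expected, rel=1e-10)
            assert (row["df1"], row["df2"]) == (g - 1, N - g - p + 1)

    def test_tolerance_plus_r_squared_is_one(self, trait_table):
        diag = variable_diagnostics(trait_table, "species")
        assert np.allclose(diag["tolerance"] + diag["r_squared"], 1.0, atol=1e-9)

    def test_pits_and_angle_among_top_discriminators(self, cards):
        """The most informative traits on card-sampled data are the coat and
        curvature descriptors, across seeded replicates."""
        hits = 0
        for seed in range(20):
            tab = sample_trait_table(cards, n_per_species=50, rng_seed=seed)
            diag = variable_diagnostics(tab, "species")
            top3 = set(diag["F_to_remove"].nlargest(3).index)
            hits += {"pits", "angle_deg"} <= top3
        assert hits >= 18

    def test_single_trait_has_no_diagnostics(self, trait_table):
        with pytest.raises(ValueError, match="two traits"):
            variable_diagnostics(trait_table, "species", traits=["pits"])


class TestMahalanobis:
    def test_hand_computed_toy_matrix(self):
        table = _toy_table()
        d2 = mahalanobis_matrix(table, traits=["surface_um2", "profile_um"])
        # independent brute-force arithmetic
        X = table[["surface_um2", "profile_um"]].to_numpy()
        y = table["species"].to_numpy()
        means = {g: X[y == g].mean(axis=0) for g in "ABC"}
        W = sum(
            (X[y == g] - means[g]).T @ (X[y == g] - means[g]) for g in "ABC"
        )
        S = W / (len(X) - 3)
        Si = np.linalg.inv(S)
        for i in "ABC":
            for j in "ABC":
                d = means[i] - means[j]
                assert d2.loc[i, j] == pytest.approx(d @ Si @ d, abs=1e-10)

    def test_whitened_data_reduces_to_euclidean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 2))
        y = np.repeat(list("ABC"), 100)
        X[100:200] += [5.0, 0.0]
        X[200:] += [0.0, 7.0]
        table = pd.DataFrame(
            {"species": y, "surface_um2": X[:, 0], "profile_um": X[:, 1]}
        )
        d2 = mahalanobis_matrix(table, traits=["surface_um2", "profile_um"])
        means = {g: X[y == g].mean(axis=0) for g in "ABC"}
        # pooled covariance ~ identity, so D² ~ squared Euclidean distance
        eu = np.sum((means["A"] - means["B"]) ** 2)
        assert d2.loc["A", "B"] == pytest.approx(eu, rel=0.1)
        assert np.allclose(np.diag(d2), 0.0)


class TestClassification:
    def test_well_separated_groups_fully_recovered(self):
        table = _toy_table(shift=(0.0, 30.0, 60.0))
        res = lda_classify(table, traits=["surface_um2", "profile_um"])
        assert np.trace(res.counts.to_numpy()) == len(table)
        assert res.summary.overall_percent == 100

    def test_row_sums_equal_group_sizes(self, trait_table):
        res = lda_classify(trait_table, "species")
        sizes = trait_table.groupby("species").size()
        assert (res.counts.sum(axis=1) == sizes).all()

    def test_agreement_with_sklearn_lda(self, trait_table):
        model = fit_discriminant(trait_table, "species")
        X = trait_table[list(model.feature_names_in_)]
        ours = model.predict(X)
        ref = (
            LinearDiscriminantAnalysis(priors=[0.1] * 10)
            .fit(X, trait_table["species"])
            .predict(X)
        )
        assert (ours == ref).mean() >= 0.99

    def test_summary_identity_matrix(self):
        counts = pd.DataFrame(np.eye(3, dtype=int) * 5, index=list("ABC"),
                              columns=list("ABC"))
        s = summarize_classification(counts)
        assert (s.percent_correct == 100).all()
        assert s.overall_percent == 100
        assert (s.correct_minus_classified == 0).all()

    def test_summary_zero_row_rejected(self):
        counts = pd.DataFrame(
            [[0, 0], [1, 3]], index=list("AB"), columns=list("AB")
        )
        with pytest.raises(ValueError, match="no classified rows"):
            summarize_classification(counts)

    def test_proportional_priors_available(self, trait_table):
        res = lda_classify(trait_table, "species", priors="proportional")
        assert res.counts.to_numpy().sum() == len(trait_table)


class TestCanonicalScores:
    def test_unit_pooled_within_variance(self, trait_table):
        scores = canonical_scores(trait_table, "species")
        resid = scores.groupby("species").transform(lambda s: s - s.mean())
        n, g = len(trait_table), trait_table["species"].nunique()
        pooled_var = (resid**2).sum() / (n - g)
        assert np.allclose(pooled_var.iloc[:4], 1.0, atol=1e-8)

    def test_two_group_mean_separation_is_mahalanobis_distance(self):
        table = _toy_table(shift=(0.0, 4.0, 0.0))
        table = table[table["species"].isin(["A", "B"])]
        traits = ["surface_um2", "profile_um"]
        scores = canonical_scores(table, traits=traits)
        gap = abs(scores.groupby("species")["can1"].mean().diff().iloc[-1])
        d = np.sqrt(mahalanobis_matrix(table, traits=traits).loc["A", "B"])
        assert gap == pytest.approx(d, rel=1e-8)

    def test_eigenvalue_sum_relates_to_lambda(self, trait_table):
        model = fit_discriminant(trait_table, "species")
        # Π 1/(1+λ) = Λ implies Σ log(1+λ) = −log Λ
        assert np.sum(np.log1p(model.eigenvalues_)) == pytest.approx(
            -np.log(model.wilks_lambda_), rel=1e-8
        )


class TestEstimatorProtocol:
    def test_get_set_params_and_clone(self):
        est = SeedDiscriminantAnalysis(priors="proportional", n_components=2)
        assert est.get_params() == {"priors": "proportional", "n_components": 2}
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_transform_shape_and_nan_rejection(self, trait_table):
        model = fit_discriminant(trait_table, "species")
        Z = model.transform(trait_table[list(model.feature_names_in_)])
        assert Z.shape == (len(trait_table), min(6, 10 - 1))
        bad = trait_table.copy()
        bad.loc[bad.index[0], "pits"] = np.nan
        with pytest.raises(TraitTableError):
            fit_discriminant(bad, "species")
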
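"""Gene-class statistics: enumeration, closed-form and null oracles."""

import numpy as np
import pandas as pd
import pytest

from sexconflict.stats import (
    covariate_regression,
    flag_top_quantile,
    permutation_enrichment,
    polynomial_sexbias_fit,
    relative_tajimas_d,
    wilcoxon_contrast,
    z_subsampling_test,
)


class TestRelativeD:
    def test_difference_of_medians(self):
        assert relative_tajimas_d([-0.5], [0.3]) == pytest.approx(-0.8)

    def test_identical_sets_give_zero(self):
        vals = [0.1, -0.2, 0.5]
        assert relative_tajimas_d(vals, vals) == 0.0

    def test_median_oracle(self):
        assert relative_tajimas_d([1, 2, 9], [0, 0, 4]) == pytest.approx(2.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            relative_tajimas_d([], [1.0])


class TestWilcoxon:
    def test_identical_samples_not_significant(self):
        _, p = wilcoxon_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_exact_enumeration_small_samples(self):
        # all ranks separated: one-tailed 1/C(6,3) = 1/20 -> two-sided 0.1
        _, p = wilcoxon_contrast([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_large_shift_is_overwhelming(self, rng):
        a = rng.normal(1.0, 1.0, 200)
        b = rng.normal(0.0, 1.0, 200)
        _, p = wilcoxon_contrast(a, b)
        assert p < 1e-6


def _gene_frame(rng, n=120, beta_gonad=0.0):
    tissue = rng.choice(
        ["gonad-biased", "spleen-biased", "non-tissue-biased"], size=n, p=[0.3, 0.2, 0.5]
    )
    tw = rng.gamma(3.0, 1.0, n) + 0.1
    length = rng.integers(500, 5000, n).astype(float)
    gc = rng.beta(5, 5, n)
    expr = rng.gamma(2.0, 40.0, n) + 1
    d = (
        0.5 * np.log(tw)
        - 0.2 * np.log(length)
        + beta_gonad * (tissue == "gonad-biased")
        + rng.normal(0, 0.3, n)
    )
    return pd.DataFrame(
        {
            "tajimas_d": d,
            "tissue_class": tissue,
            "theta_w": tw,
            "length_bp": length,
            "gc_fraction": gc,
            "mean_expr": expr,
        }
    )


class TestCovariateRegression:
    def test_noiseless_planted_model_recovered_exactly(self, rng):
        df = _gene_frame(rng, n=80)
        df["tajimas_d"] = (
            1.5
            + 0.5 * np.log(df["theta_w"])
            - 0.2 * np.log(df["length_bp"])
            + 0.7 * (df["tissue_class"] == "gonad-biased")
        )
        out = covariate_regression(df).set_index("term")
        assert out.loc["log_theta_w", "estimate"] == pytest.approx(0.5, abs=1e-8)
        assert out.loc["log_length_bp", "estimate"] == pytest.approx(-0.2, abs=1e-8)
        assert out.loc["tissue_class[gonad-biased]", "estimate"] == pytest.approx(0.7, abs=1e-8)

    def test_constant_tissue_class_rejected(self, rng):
        df = _gene_frame(rng)
        df["tissue_class"] = "non-tissue-biased"
        with pytest.raises(ValueError, match="tissue_class"):
            covariate_regression(df)

    def test_matches_normal_equations_oracle(self, rng):
        df = _gene_frame(rng, n=50, beta_gonad=0.4)
        out = covariate_regression(df).set_index("term")
        # independent closed-form (X'X)^-1 X'y with explicit dummies
        x = np.column_stack(
            [
                np.ones(len(df)),
                (df["tissue_class"] == "gonad-biased").astype(float),
                (df["tissue_class"] == "spleen-biased").astype(float),
                np.log(df["theta_w"]),
                np.log(df["length_bp"]),
                np.log(df["gc_fraction"]),
                np.log(df["mean_expr"]),
            ]
        )
        beta = np.linalg.solve(x.T @ x, x.T @ df["tajimas_d"].to_numpy())
        assert out.loc["tissue_class[gonad-biased]", "estimate"] == pytest.approx(beta[1])
        assert out.loc["log_theta_w", "estimate"] == pytest.approx(beta[3])

    def test_planted_tissue_effect_stays_significant(self, rng):
        hits = 0
        for rep in range(50):
            r = np.random.default_rng(rep)
            df = _gene_frame(r, n=150, beta_gonad=0.5)
            out = covariate_regression(df).set_index("term")
            hits += out.loc["tissue_class[gonad-biased]", "p"] < 0.05
        assert hits >= 45


class TestPolynomialFit:
    def test_exact_quadratic_has_unit_r2(self):
        x = np.linspace(-3, 3, 30)
        d = 0.5 - 0.3 * x + 0.1 * x**2
        coef, r2 = polynomial_sexbias_fit(d, x, degree=2)
        assert r2 == pytest.approx(1.0)
        np.testing.assert_allclose(coef, [0.5, -0.3, 0.1], atol=1e-10)

    def test_independent_data_has_near_zero_r2(self):
        r2s = []
        for rep in range(10):
            r = np.random.default_rng(rep)
            _, r2 = polynomial_sexbias_fit(r.normal(size=1000), r.normal(size=1000), 2)
            r2s.append(r2)
        assert np.median(r2s) < 0.02

    def test_noisy_quadratic_coefficients_within_2se(self, rng):
        x = rng.normal(0, 2, 400)
        d = 0.2 + 0.15 * x - 0.05 * x**2 + rng.normal(0, 0.3, 400)
        coef, _ = polynomial_sexbias_fit(d, x, degree=2)
        # rough SE scale for this n and noise
        assert coef[1] == pytest.approx(0.15, abs=0.05)
        assert coef[2] == pytest.approx(-0.05, abs=0.03)


class TestTopQuantile:
    def test_ten_distinct_values_flag_exactly_one(self, rng):
        d = pd.DataFrame({"sp1": rng.permutation(10).astype(float)})
        flags = flag_top_quantile(d, 0.1)
        assert flags["sp1"].sum() == 1

    def test_all_equal_values_all_flagged(self):
        d = pd.DataFrame({"sp1": np.full(10, 1.3)})
        assert flag_top_quantile(d, 0.1)["sp1"].all()

    def test_matches_independent_quantile_oracle(self, rng):
        vals = rng.normal(size=100)
        d = pd.DataFrame({"sp1": vals})
        flags = flag_top_quantile(d, 0.1)
        assert (flags["sp1"].to_numpy() == (vals >= np.quantile(vals, 0.9))).all()

    def test_universal_requires_all_species(self, rng):
        d = pd.DataFrame({"sp1": rng.normal(size=50), "sp2": rng.normal(size=50)})
        flags = flag_top_quantile(d, 0.2)
        assert (flags["universal"] == (flags["sp1"] & flags["sp2"])).all()


class TestPermutationEnrichment:
    def test_class_equal_to_universe_is_degenerate(self):
        universal = np.array([True, True] + [False] * 8)
        member = np.ones(10, dtype=bool)
        res = permutation_enrichment(universal, member, n_perm=200, seed=1)
        assert res.observed == 2
        assert res.empirical_p == pytest.approx(1.0)

    def test_no_universal_genes(self):
        res = permutation_enrichment(
            np.zeros(20, dtype=bool), np.arange(20) < 5, n_perm=200, seed=1
        )
        assert res.observed == 0
        assert res.empirical_p == pytest.approx(1.0)

    def test_matches_hypergeometric_tail(self):
        """10 genes, 2 universal, class of 5 holding both: one-sided
        P(X >= 2) = C(8,3)/C(10,5) = 56/252."""
        universal = np.zeros(10, dtype=bool)
        universal[:2] = True
        member = np.zeros(10, dtype=bool)
        member[:5] = True
        res = permutation_enrichment(universal, member, n_perm=10_000, seed=3)
        p_true = 56 / 252
        tail = np.mean(res.null_counts >= 2)
        se = np.sqrt(p_true * (1 - p_true) / 10_000)
        assert abs(tail - p_true) < 3 * se

    def test_reproducible_given_seed(self):
        universal = np.arange(30) % 3 == 0
        member = np.arange(30) < 12
        a = permutation_enrichment(universal, member, n_perm=300, seed=7)
        b = permutation_enrichment(universal, member, n_perm=300, seed=7)
        assert a.empirical_p == b.empirical_p
        np.testing.assert_array_equal(a.null_counts, b.null_counts)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            permutation_enrichment(np.ones(5, bool), np.zeros(5, bool))


def _species_table(rng, species, n_focal=30, n_bg=60, shift=0.0, chrom="A"):
    rows = []
    shifts = np.broadcast_to(np.atleast_1d(shift), (len(species),))
    for sp, sh in zip(species, shifts):
        for _ in range(n_focal):
            rows.append({"species": sp, "tissue_class": "gonad-biased",
                         "tajimas_d": rng.normal(sh, 0.5)})
        for _ in range(n_bg):
            rows.append({"species": sp, "tissue_class": "non-tissue-biased",
                         "tajimas_d": rng.normal(0, 0.5)})
    return pd.DataFrame(rows)


class TestZSubsampling:
    def test_constant_trait_rejected(self, rng):
        species = ["a", "b", "c"]
        auto = _species_table(rng, species)
        z = _species_table(rng, species, n_focal=5, n_bg=10)
        traits = pd.DataFrame({"species": species, "dichromatism_score": 1.0})
        with pytest.raises(ValueError, match="constant"):
            z_subsampling_test(auto, z, traits)

    def test_z_equal_to_autosomes_gives_p_one(self, rng):
        species = ["a", "b", "c", "d"]
        auto = _species_table(rng, species, n_focal=8, n_bg=20)
        traits = pd.DataFrame(
            {"species": species, "dichromatism_score": [0.0, 1.0, 2.0, 3.0]}
        )
        res = z_subsampling_test(auto, auto, traits, n_rep=100, seed=2)
        # every replicate uses the full focal set -> identical to observed
        assert res["p_r"] == pytest.approx(1.0)
        assert res["p_slope"] == pytest.approx(1.0)

    def test_noise_z_vs_planted_autosomal_correlation(self):
        """When autosomal focal D tracks the trait but Z genes are pure
        noise, the Z correlation is usually below the subsampled null."""
        small_p = 0
        for rep in range(10):
            r = np.random.default_rng(100 + rep)
            species = list("abcdef")
            trait_vals = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.5])
            auto = _species_table(r, species, n_focal=40, n_bg=60, shift=trait_vals)
            z = _species_table(r, species, n_focal=6, n_bg=12, shift=0.0)
            traits = pd.DataFrame({"species": species, "dichromatism_score": trait_vals})
            res = z_subsampling_test(auto, z, traits, n_rep=300, seed=rep)
            small_p += res["p_r"] < 0.5
        assert small_p >= 8
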
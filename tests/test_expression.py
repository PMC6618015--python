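"""Expression module: arithmetic oracles, filters, classification, RBH."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from sexconflict.expression import (
    classify_sex_bias,
    classify_tissue_bias,
    cpm,
    exclude_flagged_genes,
    filter_low_expression,
    fpkm,
    select_reciprocal_best_hits,
    tmm_factors,
)


class TestFpkm:
    def test_unit_case(self):
        counts = pd.DataFrame({"s1": [10]}, index=["g1"])
        out = fpkm(counts, pd.Series({"g1": 1000}), pd.Series({"s1": 1e6}))
        assert out.loc["g1", "s1"] == pytest.approx(10.0)

    def test_zero_count_is_zero(self):
        counts = pd.DataFrame({"s1": [0]}, index=["g1"])
        out = fpkm(counts, pd.Series({"g1": 500}), pd.Series({"s1": 2e6}))
        assert out.loc["g1", "s1"] == 0.0

    def test_arithmetic(self):
        counts = pd.DataFrame({"s1": [7]}, index=["g1"])
        out = fpkm(counts, pd.Series({"g1": 2500}), pd.Series({"s1": 3e6}))
        assert out.loc["g1", "s1"] == pytest.approx(7 / (2.5 * 3))

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g1"])
        with pytest.raises(ValueError):
            fpkm(counts, pd.Series({"g1": 100}), pd.Series({"s1": 0}))


def reference_tmm(counts: np.ndarray) -> np.ndarray:
    """Independent step-by-step evaluation of the TMM recipe."""
    lib = counts.sum(axis=0)
    scaled = counts / lib
    uq = np.quantile(scaled, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(counts.shape[1])
    for k in range(counts.shape[1]):
        if k == ref:
            continue
        use = (counts[:, k] > 0) & (counts[:, ref] > 0)
        m = np.log2((counts[use, k] / lib[k]) / (counts[use, ref] / lib[ref]))
        a = 0.5 * np.log2((counts[use, k] / lib[k]) * (counts[use, ref] / lib[ref]))
        if np.max(np.abs(m)) < 1e-10:
            continue
        n = use.sum()
        lo_m, lo_a = np.floor(n * 0.30) + 1, np.floor(n * 0.05) + 1
        rm = pd.Series(m).rank().to_numpy()
        ra = pd.Series(a).rank().to_numpy()
        keep = (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
        w = (lib[k] - counts[use, k]) / (lib[k] * counts[use, k]) + (
            lib[ref] - counts[use, ref]
        ) / (lib[ref] * counts[use, ref])
        factors[k] = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame(np.tile([[10], [60], [200]], (1, 3)), columns=list("abc"))
        np.testing.assert_allclose(tmm_factors(counts), 1.0)

    def test_depth_invariance(self):
        base = np.array([10, 50, 200, 1000, 40])
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        np.testing.assert_allclose(tmm_factors(counts), 1.0, atol=1e-12)

    def test_matches_reference_recipe_on_inflated_gene_toy(self, rng):
        counts = rng.poisson(60, size=(200, 4)).astype(int)
        counts[0, 0] = 50000  # composition-distorting gene in one sample
        df = pd.DataFrame(counts, columns=list("abcd"))
        np.testing.assert_allclose(
            tmm_factors(df).to_numpy(), reference_tmm(counts.astype(float)), rtol=1e-10
        )

    def test_matches_edger(self, rng, tmp_path):
        """Cross-check against edgeR::calcNormFactors on a dense toy matrix."""
        counts = rng.poisson(80, size=(300, 4)) + 1  # no zeros
        counts[: 30, 0] *= 6  # composition shift
        df = pd.DataFrame(counts, columns=list("abcd"))
        csv = tmp_path / "counts.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.csv("{csv}"))
            f <- calcNormFactors(x, method="TMM")
            cat(sprintf("%.10f", f), sep="\\n")
            """
        )
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert res.returncode == 0, res.stderr
        expected = np.array([float(v) for v in res.stdout.split()])
        np.testing.assert_allclose(tmm_factors(df).to_numpy(), expected, rtol=1e-6)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            tmm_factors(counts)


class TestLowExpressionFilter:
    def _sheet(self, n=5):
        rows = []
        for i in range(n):
            for t in ("gonad", "spleen"):
                rows.append(
                    {"sample": f"i{i}_{t}", "species": "sp", "individual": f"i{i}",
                     "sex": "male", "tissue": t}
                )
        return pd.DataFrame(rows)

    def test_low_in_three_of_five_gonads_removed(self):
        sheet = self._sheet()
        fp = pd.DataFrame(10.0, index=["g1"], columns=sheet["sample"])
        fp.loc["g1", ["i0_gonad", "i1_gonad", "i2_gonad"]] = 1.9
        assert "g1" not in filter_low_expression(fp, sheet)

    def test_exactly_two_fpkm_everywhere_retained(self):
        sheet = self._sheet()
        fp = pd.DataFrame(2.0, index=["g1"], columns=sheet["sample"])
        assert "g1" in filter_low_expression(fp, sheet)

    def test_two_below_in_each_tissue_retained(self):
        sheet = self._sheet()
        fp = pd.DataFrame(10.0, index=["g1"], columns=sheet["sample"])
        fp.loc["g1", ["i0_gonad", "i1_gonad", "i0_spleen", "i1_spleen"]] = 0.5
        assert "g1" in filter_low_expression(fp, sheet)  # 2 < ceil(5/2)


class TestBiasClassification:
    def test_tissue_fold_change_threshold(self, toy_sample_sheet):
        sheet = toy_sample_sheet[toy_sample_sheet["sex"] == "male"]
        expr = pd.DataFrame(
            0.0, index=["g1", "g2", "g3"], columns=toy_sample_sheet["sample"]
        )
        gonad = sheet.loc[sheet["tissue"] == "gonad", "sample"]
        spleen = sheet.loc[sheet["tissue"] == "spleen", "sample"]
        expr.loc["g1", gonad], expr.loc["g1", spleen] = 8.0, 2.0   # lfc = 2 at c=0
        expr.loc["g2", gonad], expr.loc["g2", spleen] = 4.0, 2.0   # lfc = 1
        expr.loc["g3", gonad], expr.loc["g3", spleen] = 1.0, 9.0   # lfc(c=1) = -2.32
        out = classify_tissue_bias(expr, toy_sample_sheet, "male", pseudo=0.0)
        assert out.loc["g1", "tissue_class"] == "gonad-biased"
        assert out.loc["g1", "log2fc_tissue"] == pytest.approx(2.0)
        assert out.loc["g2", "tissue_class"] == "non-tissue-biased"
        out_c1 = classify_tissue_bias(expr, toy_sample_sheet, "male", pseudo=1.0)
        assert out_c1.loc["g3", "log2fc_tissue"] == pytest.approx(np.log2(2 / 10))
        assert out_c1.loc["g3", "tissue_class"] == "spleen-biased"

    def test_sex_fold_change_threshold(self, toy_sample_sheet):
        gonad = toy_sample_sheet[toy_sample_sheet["tissue"] == "gonad"]
        expr = pd.DataFrame(0.0, index=["g1", "g2", "g3"], columns=toy_sample_sheet["sample"])
        male = gonad.loc[gonad["sex"] == "male", "sample"]
        female = gonad.loc[gonad["sex"] == "female", "sample"]
        expr.loc["g1", male], expr.loc["g1", female] = 4.0, 2.0    # lfc = 1
        expr.loc["g2", male], expr.loc["g2", female] = 3.0, 3.0    # equal
        expr.loc["g3", male], expr.loc["g3", female] = 0.0, 12.0   # sex-limited
        out0 = classify_sex_bias(expr, toy_sample_sheet, "gonad", pseudo=0.0)
        assert out0.loc["g1", "sex_class"] == "male-biased"
        assert out0.loc["g2", "sex_class"] == "unbiased"
        assert out0.loc["g2", "log2fc_sex"] == 0.0
        out1 = classify_sex_bias(expr, toy_sample_sheet, "gonad", pseudo=1.0)
        assert out1.loc["g3", "log2fc_sex"] == pytest.approx(np.log2(1 / 13))
        assert out1.loc["g3", "sex_class"] == "female-biased"

    def test_classification_invariant_to_global_rescaling(self, toy_sample_sheet, rng):
        expr = pd.DataFrame(
            rng.gamma(2.0, 50.0, size=(40, len(toy_sample_sheet))),
            index=[f"g{i}" for i in range(40)],
            columns=toy_sample_sheet["sample"],
        )
        a = classify_tissue_bias(expr, toy_sample_sheet, "male")
        b = classify_tissue_bias(expr * 7.5, toy_sample_sheet, "male")
        # ratios survive a common scale only asymptotically under the pseudo
        # count, so compare after scaling pseudo too
        b2 = classify_tissue_bias(expr * 7.5, toy_sample_sheet, "male", pseudo=7.5)
        assert (a["tissue_class"] == b2["tissue_class"]).all()
        np.testing.assert_allclose(a["log2fc_tissue"], b2["log2fc_tissue"], rtol=1e-10)
        assert b is not None


class TestReciprocalBestHits:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["query", "subject", "pident", "evalue", "bitscore"])

    def test_mutual_best_hit_pair_retained(self):
        ab = self._table([("a", "x", 80.0, 1e-50, 200.0)])
        ba = self._table([("x", "a", 80.0, 1e-50, 200.0)])
        pairs = select_reciprocal_best_hits(ab, ba)
        assert pairs.to_records(index=False).tolist() == [("a", "x")]

    def test_bitscore_tie_broken_by_identity(self):
        ab = self._table(
            [("a", "x", 80.0, 1e-50, 200.0), ("a", "y", 90.0, 1e-50, 200.0)]
        )
        ba = self._table([("y", "a", 90.0, 1e-50, 200.0)])
        pairs = select_reciprocal_best_hits(ab, ba)
        assert pairs["gene_b"].tolist() == ["y"]

    def test_full_tie_discards_query(self):
        ab = self._table(
            [("a", "x", 90.0, 1e-50, 200.0), ("a", "y", 90.0, 1e-50, 200.0)]
        )
        ba = self._table([("x", "a", 90.0, 1e-50, 200.0)])
        assert select_reciprocal_best_hits(ab, ba).empty

    def test_filters_on_evalue_and_identity(self):
        ab = self._table(
            [("a", "x", 80.0, 1e-5, 500.0), ("a", "y", 25.0, 1e-50, 400.0),
             ("a", "z", 45.0, 1e-20, 100.0)]
        )
        ba = self._table([("z", "a", 45.0, 1e-20, 100.0)])
        pairs = select_reciprocal_best_hits(ab, ba)
        assert pairs["gene_b"].tolist() == ["z"]


class TestExcludeFlagged:
    def _ann(self, flags):
        return pd.DataFrame(
            {"gene": [f"g{i}" for i in range(len(flags))], "immune_flag": flags}
        )

    def test_no_flags_is_identity(self):
        genes = pd.Index([f"g{i}" for i in range(4)])
        out = exclude_flagged_genes(genes, self._ann([False] * 4))
        assert list(out) == list(genes)

    def test_all_flagged_empty(self):
        genes = pd.Index(["g0", "g1"])
        assert len(exclude_flagged_genes(genes, self._ann([True, True]))) == 0

    def test_partial_flagging_counts(self):
        genes = pd.Index([f"g{i}" for i in range(10)])
        flags = [i < 3 for i in range(10)]
        assert len(exclude_flagged_genes(genes, self._ann(flags))) == 7


class TestSexBiasRecovery:
    def test_planted_sex_bias_recovered_with_low_dispersion(self):
        """Strong planted sex bias (3 log2) is recovered nearly perfectly
        and null genes are rarely called, over 20 replicates."""
        from sexconflict.config import SimulationConfig
        from sexconflict.simulate import simulate_dataset

        tpr, fpr = [], []
        for rep in range(20):
            cfg = SimulationConfig(
                n_species=2,
                n_genes=120,
                sex_bias_lfc=3.0,
                nb_dispersion=0.01,
                tissue_bias_lfc=3.0,
                seed=1000 + rep,
            )
            ds = simulate_dataset(cfg)
            sp = next(iter(ds.species))
            d = ds.species[sp]
            counts = d["counts"]
            factors = tmm_factors(counts)
            norm = cpm(counts, factors)
            out = classify_sex_bias(norm, d["samples"], "gonad")
            truth = ds.genes.set_index("gene")["true_sex_class"].reindex(out.index)
            biased = truth != "unbiased"
            tpr.append(np.mean(out.loc[biased, "sex_class"] == truth[biased]))
            fpr.append(np.mean(out.loc[~biased, "sex_class"] != "unbiased"))
        assert np.mean(tpr) >= 0.95
        assert np.mean(fpr) <= 0.05
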
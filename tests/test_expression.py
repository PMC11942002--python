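"""Expression core: I/O, FPKM, detectability, normalization, BH, tiers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from dermsig.expression import (
    ExpressionMatrix,
    bh_adjust,
    classify_degs,
    compute_fpkm,
    de_test,
    detectability_filter,
    detectable_mask,
    normalize_libsizes,
    poisson_lower_ci,
    read_expression,
    standardize_expression,
    write_expression,
)

from conftest import make_matrix


class TestIO:
    def test_round_trip_identity(self, toy_matrix, tmp_path):
        write_expression(toy_matrix, tmp_path / "c.tsv", tmp_path / "d.tsv")
        back = read_expression(tmp_path / "c.tsv", tmp_path / "d.tsv")
        pd.testing.assert_frame_equal(back.counts, toy_matrix.counts, check_names=False)
        pd.testing.assert_series_equal(back.design, toy_matrix.design)
        assert (back.gene_lengths == toy_matrix.gene_lengths).all()

    def test_missing_sample_in_design_names_it(self, toy_matrix, tmp_path):
        write_expression(toy_matrix, tmp_path / "c.tsv", tmp_path / "d.tsv")
        design = pd.read_csv(tmp_path / "d.tsv", sep="\t")
        design[design["sample"] != "S6"].to_csv(tmp_path / "d.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="S6"):
            read_expression(tmp_path / "c.tsv", tmp_path / "d.tsv")

    def test_non_integer_count_rejected(self):
        with pytest.raises(ValueError, match="non-integer"):
            make_matrix(np.array([[1.5, 2.0], [1.0, 1.0]]))

    def test_duplicate_gene_ids_rejected(self):
        counts = pd.DataFrame([[1, 2], [3, 4]], index=["g", "g"], columns=["S1", "S2"])
        with pytest.raises(ValueError, match="duplicate"):
            ExpressionMatrix(
                counts=counts,
                gene_lengths=pd.Series([100.0, 100.0], index=["g", "g"]),
                design=pd.Series(["A", "B"], index=["S1", "S2"]),
            )


class TestFPKM:
    def test_closed_form(self):
        m = make_matrix(np.array([[100, 0]]), lengths=[1000.0], library_sizes=[1e7, 1e7])
        fpkm = compute_fpkm(m)
        assert fpkm.iloc[0, 0] == pytest.approx(10.0)
        assert fpkm.iloc[0, 1] == 0.0

    def test_depth_scale_invariance(self):
        a = make_matrix(np.array([[10, 20], [30, 40]]), library_sizes=[1e6, 2e6])
        b = make_matrix(2 * np.array([[10, 20], [30, 40]]), library_sizes=[2e6, 4e6])
        pd.testing.assert_frame_equal(compute_fpkm(a), compute_fpkm(b))


class TestDetectability:
    def test_garwood_lower_bound_for_count_one(self):
        assert poisson_lower_ci([1])[0] == pytest.approx(0.0253, abs=1e-4)
        assert poisson_lower_ci([0])[0] == 0.0

    def test_filter_rules(self, toy_matrix):
        universe = detectability_filter(toy_matrix, "A", "B")
        assert "G001" not in universe  # all-zero gene
        assert "G002" in universe  # single read in exactly 2 of 6
        assert "G003" not in universe  # detected in only 1 of 6
        assert "G004" in universe and "G005" in universe

    def test_mask_matches_count_rule(self, toy_matrix):
        mask = detectable_mask(toy_matrix)
        assert (mask.to_numpy() == (toy_matrix.counts.to_numpy() >= 1)).all()

    def test_empty_group_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="no samples"):
            detectability_filter(toy_matrix, "A", "Z")

    def test_universes_are_comparison_specific(self):
        # a gene detectable only in group C changes the universe of any
        # comparison involving C
        counts = np.array([[0, 0, 0, 0, 2, 3], [9, 9, 9, 9, 9, 9]])
        m = make_matrix(counts, groups=["A", "A", "B", "B", "C", "C"])
        assert len(detectability_filter(m, "A", "B")) == 1
        assert len(detectability_filter(m, "A", "C")) == 2


class TestNormalization:
    def test_identical_columns_give_unit_factors(self):
        m = make_matrix(np.tile([[10], [20], [30]], (1, 3)))
        assert np.allclose(normalize_libsizes(m), 1.0)

    def test_doubled_column_factors(self):
        m = make_matrix(np.array([[10, 20], [30, 60], [5, 10]]))
        factors = normalize_libsizes(m)
        assert factors["S2"] == pytest.approx(np.sqrt(2))
        assert factors["S1"] == pytest.approx(1 / np.sqrt(2))

    def test_permutation_equivariance(self):
        counts = np.array([[10, 25, 40], [3, 9, 2], [70, 10, 30]])
        m = make_matrix(counts, groups=["A", "B", "B"])
        f = normalize_libsizes(m)
        perm = m.counts[["S3", "S1", "S2"]]
        f_perm = normalize_libsizes(perm)
        assert f_perm["S1"] == pytest.approx(f["S1"])
        assert f_perm["S3"] == pytest.approx(f["S3"])

    def test_fallback_warns_when_no_common_gene(self):
        m = make_matrix(np.array([[5, 0], [0, 5]]))
        with pytest.warns(UserWarning, match="library-size"):
            factors = normalize_libsizes(m)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.011, 0.02, 0.04], [0.02, 0.022, 0.02 * 4 / 3, 0.04]),
        ],
    )
    def test_hand_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_matches_independent_implementation(self, p):
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)


class TestDETest:
    def test_identical_groups_give_unit_fc(self):
        block = np.array([[10, 20, 30], [5, 0, 9], [100, 110, 90]])
        m = make_matrix(np.hstack([block, block]), groups=["A"] * 3 + ["B"] * 3)
        de = de_test(m, "B", "A", compute_pvalues=False)
        assert np.allclose(de["fc"], 1.0)

    def test_single_replicate_group_rejected(self):
        m = make_matrix(np.array([[5, 5, 5]]), groups=["A", "A", "B"])
        with pytest.raises(ValueError, match="replicates"):
            de_test(m, "B", "A")

    def test_planted_effect_recovered(self):
        from conftest import simulate_two_group

        # a minority of planted genes: median-of-ratios normalization
        # assumes most genes are unchanged
        m, _ = simulate_two_group(3, n_genes=800, planted=[(slice(0, 40), 2.0)], mean_range=(80, 120))
        de = de_test(m, "TRT", "CTL")
        assert abs(de["log2fc"][:40].median() - 2.0) < 0.3
        # planted genes should dominate the small-p tail
        assert de["p"][:40].median() < de["p"][40:].median()

    def test_fdr_controlled_among_stringent_calls(self):
        """With a planted 10% non-null fraction, the realized false-discovery
        proportion among stringent (FDR < 0.10) calls stays below 0.15
        pooled over 50 seeded simulations."""
        from conftest import simulate_two_group

        false_calls = total_calls = 0
        for seed in range(50):
            m, _ = simulate_two_group(
                seed,
                n_genes=1000,
                planted=[(slice(0, 50), 2.0), (slice(50, 100), -2.0)],
                mean_range=(20, 2000),
            )
            de = de_test(m, "TRT", "CTL")
            calls = classify_degs(de).stringent
            truly_null = set(de.index[100:])
            false_calls += len(calls & truly_null)
            total_calls += len(calls)
        assert total_calls > 0
        assert false_calls / total_calls <= 0.15

    def test_untested_genes_flagged(self, toy_matrix):
        de = de_test(toy_matrix, "B", "A")
        assert not de.loc["G001", "tested"]
        assert np.isnan(de.loc["G001", "p"])
        assert de.loc["G004", "tested"]
        assert np.isfinite(de.loc["G004", "p"])


class TestClassifyDEGs:
    def test_gene_meeting_both_tiers(self):
        de = pd.DataFrame(
            {"fc": [1.6], "p": [0.01], "fdr": [0.05], "tested": [True]},
            index=["g1"],
        )
        tiers = classify_degs(de)
        assert "g1" in tiers.stringent_up and "g1" in tiers.permissive_up

    def test_fc_bound_excludes_significant_gene(self):
        de = pd.DataFrame(
            {"fc": [1.2], "p": [0.001], "fdr": [0.001], "tested": [True]},
            index=["g1"],
        )
        tiers = classify_degs(de)
        assert not tiers.stringent and not tiers.permissive

    def test_empty_table(self):
        tiers = classify_degs(pd.DataFrame())
        assert not tiers.stringent and not tiers.permissive

    @given(st.integers(0, 2**31 - 1))
    def test_stringent_nested_in_permissive(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        de = pd.DataFrame(
            {
                "fc": rng.lognormal(0, 1, n),
                "p": rng.uniform(0, 1, n),
                "fdr": rng.uniform(0, 1, n),
                "tested": rng.random(n) > 0.2,
            },
            index=[f"g{i}" for i in range(n)],
        )
        tiers = classify_degs(de)
        assert tiers.stringent <= tiers.permissive


class TestStandardize:
    def test_constant_gene_zero_in_both_modes(self):
        values = pd.DataFrame([[3.0, 3.0, 3.0, 3.0]], index=["g"], columns=list("abcd"))
        design = pd.Series(["R", "R", "T", "T"], index=list("abcd"))
        for mode in ("center", "zscore"):
            out = standardize_expression(values, design, "R", mode=mode)
            assert np.allclose(out, 0.0)

    def test_reference_mean_exactly_zero(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.random((5, 6)), columns=list("abcdef"))
        design = pd.Series(["R"] * 3 + ["T"] * 3, index=list("abcdef"))
        out = standardize_expression(values, design, "R")
        assert np.allclose(out[["a", "b", "c"]].mean(axis=1), 0.0)

    def test_centering_arithmetic(self):
        values = pd.DataFrame([[1.0, 2, 3, 4, 5, 6]], columns=list("abcdef"))
        design = pd.Series(["R"] * 3 + ["T"] * 3, index=list("abcdef"))
        out = standardize_expression(values, design, "R")
        assert np.allclose(out.iloc[0], [-1, 0, 1, 2, 3, 4])

    def test_zero_sd_gene_flagged(self):
        values = pd.DataFrame(
            [[1.0, 1, 1, 1], [1.0, 2, 3, 4]], index=["flat", "var"], columns=list("abcd")
        )
        design = pd.Series(["R", "R", "T", "T"], index=list("abcd"))
        out = standardize_expression(values, design, "R", mode="zscore")
        assert out.attrs["zero_sd_genes"] == ["flat"]
        assert np.allclose(out.loc["flat"], 0.0)
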
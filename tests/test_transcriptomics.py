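import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from conftest import bh_step_up_oracle
from synspread import synthetic_data as sd
from synspread import transcriptomics as tx


def toy_matrix(counts, groups):
    counts = pd.DataFrame(counts)
    return tx.CountMatrix(counts=counts,
                          groups=pd.Series(groups, index=counts.columns))


class TestCpm:
    def test_definition_on_single_count(self):
        cm = toy_matrix({"s1": [10, 10 ** 6 - 10]}, ["LPS"])
        assert tx.cpm(cm).iloc[0, 0] == pytest.approx(10.0)

    def test_raw_cpm_columns_sum_to_a_million(self):
        cm, _ = sd.make_count_matrix(sd.CountSimConfig(seed=1, n_genes=100))
        assert np.allclose(tx.cpm(cm).sum(axis=0), 1e6)

    def test_log2cpm_prior_formula_at_zero_count(self):
        lib = 2 * 10 ** 6
        cm = toy_matrix({"s1": [0, lib]}, ["LPS"])
        prior = 2.0
        expect = math.log2(prior / (lib + 2 * prior) * 1e6)
        assert tx.log2cpm(cm).iloc[0, 0] == pytest.approx(expect)

    def test_zero_library_rejected(self):
        cm = toy_matrix({"s1": [1], "s2": [0]}, ["LPS", "IL4"])
        with pytest.raises(ValueError):
            tx.cpm(cm)


class TestFilterMinCpm:
    def test_toy_rule_application(self):
        # libraries of 5e6: a single count is 0.2 CPM (> 0.1); gene A clears
        # the >0.1-CPM-in-3-samples rule, gene B does not
        lib = 5 * 10 ** 6
        counts = {f"s{j}": [ab[0], ab[1], lib - ab[0] - ab[1]]
                  for j, ab in enumerate([(1, 1), (1, 1), (1, 0), (0, 0)])}
        cm = toy_matrix(counts, ["PBS", "LPS", "LPS", "IL4"])
        cm.counts.index = ["A", "B", "filler"]
        kept = tx.filter_min_cpm(cm, threshold=0.1, min_samples=3)
        assert "A" in kept.counts.index and "B" not in kept.counts.index

    def test_zero_thresholds_are_identity(self):
        cm, _ = sd.make_count_matrix(sd.CountSimConfig(seed=2, n_genes=50))
        kept = tx.filter_min_cpm(cm, threshold=0.0, min_samples=0)
        assert kept.counts.shape == cm.counts.shape


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = np.random.default_rng(0).poisson(50, 500)
        cm = toy_matrix({"a": col, "b": col, "c": col}, ["PBS", "LPS", "IL4"])
        assert np.allclose(tx.tmm_norm_factors(cm), 1.0)

    def test_factors_have_geometric_mean_one(self):
        cm, _ = sd.make_count_matrix(sd.CountSimConfig(seed=3, n_genes=400,
                                                       de_fraction=0.2))
        f = tx.tmm_norm_factors(cm)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_two_sample_factor_matches_brute_force_trimmed_mean(self):
        # independent evaluation of the doubly trimmed weighted mean of
        # M-values, written longhand against sorted copies
        rng = np.random.default_rng(4)
        base = rng.poisson(100, 200) + 1
        spiked = base.copy()
        spiked[:20] *= 6
        cm = toy_matrix({"ref": base, "obs": spiked}, ["IL4", "LPS"])
        f = tx.tmm_norm_factors(cm, ref_column="ref")

        n_o, n_r = spiked.sum(), base.sum()
        m = np.log2((spiked / n_o) / (base / n_r))
        a = 0.5 * np.log2((spiked / n_o) * (base / n_r))
        w = (n_o - spiked) / (n_o * spiked) + (n_r - base) / (n_r * base)
        n = len(m)
        lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        from scipy.stats import rankdata
        keep = ((rankdata(m) >= lo_m) & (rankdata(m) <= hi_m)
                & (rankdata(a) >= lo_a) & (rankdata(a) <= hi_a))
        log_f_obs = np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep])
        expected = 2.0 ** np.array([0.0, log_f_obs])
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(f.to_numpy(), expected, rtol=1e-10)

    def test_factors_match_edger_reference_values(self):
        # frozen output of edgeR::calcNormFactors (TMM) on this exact
        # simulated matrix, computed once with the reference implementation
        cm, _ = sd.make_count_matrix(sd.CountSimConfig(
            seed=42, n_genes=500, group_sizes=(0, 5, 8),
            de_fraction=0.1, de_log2fc=2.0))
        edger = [0.96632, 0.97336, 1.02557, 0.99697, 0.96132, 0.96822,
                 1.01460, 0.99572, 1.00536, 0.97323, 1.06256, 1.02848,
                 1.03419]
        assert np.allclose(tx.tmm_norm_factors(cm).to_numpy(), edger,
                           atol=5e-6)

    def test_all_zero_column_rejected(self):
        cm = toy_matrix({"a": [1, 2], "b": [0, 0]}, ["LPS", "IL4"])
        with pytest.raises(ValueError):
            tx.tmm_norm_factors(cm)


class TestFilterGroupMean:
    def test_either_group_semantics(self):
        lcpm = pd.DataFrame([[0.5, 0.5, -2.0, -2.0],
                             [-1.0, -1.0, -3.0, -3.0]],
                            index=["kept", "dropped"],
                            columns=["l1", "l2", "i1", "i2"])
        groups = pd.Series(["LPS", "LPS", "IL4", "IL4"], index=lcpm.columns)
        kept = tx.filter_group_mean(lcpm, groups)
        assert list(kept) == ["kept"]

    def test_unknown_group_rejected(self):
        lcpm = pd.DataFrame([[1.0]], columns=["s"])
        with pytest.raises(ValueError):
            tx.filter_group_mean(lcpm, pd.Series(["LPS"], index=["s"]),
                                 which=("LPS", "TGF"))


class TestDeTest:
    def test_swapping_groups_negates_every_log2fc(self):
        cm, _ = sd.make_count_matrix(sd.CountSimConfig(seed=5, n_genes=300,
                                                       de_fraction=0.1))
        fwd = tx.de_test(cm, "LPS", "IL4")
        rev = tx.de_test(cm, "IL4", "LPS")
        assert np.allclose(fwd.log2fc, -rev.log2fc)
        assert np.allclose(fwd.p, rev.p)

    def test_log2fc_matches_limma_voom_reference(self):
        # frozen limma-voom logFC values for the first genes of this matrix
        # (reference run: edgeR TMM + voom + lmFit + eBayes)
        cm, _ = sd.make_count_matrix(sd.CountSimConfig(
            seed=42, n_genes=500, group_sizes=(0, 5, 8),
            de_fraction=0.1, de_log2fc=2.0))
        det = tx.de_test(cm)
        limma = [0.354281, 0.306731, 0.265680, 0.014805, 0.255074]
        assert np.allclose(det.log2fc.to_numpy()[:5], limma, atol=5e-4)

    def test_too_few_replicates_rejected(self):
        cm, _ = sd.make_count_matrix(sd.CountSimConfig(
            seed=6, n_genes=50, group_sizes=(0, 1, 3)))
        with pytest.raises(ValueError):
            tx.de_test(cm)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert tx.bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_worked_vector_matches_step_up_oracle(self):
        p = np.array([0.005, 0.01, 0.03, 0.04])
        assert np.allclose(tx.bh_adjust(p), bh_step_up_oracle(p))

    def test_ties_all_equal(self):
        p = np.full(5, 0.2)
        assert np.allclose(tx.bh_adjust(p), 0.2)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(p=hst.lists(hst.floats(0, 1), min_size=1, max_size=10))
    def test_agrees_with_brute_force_on_any_short_vector(self, p):
        p = np.array(p)
        assert np.allclose(tx.bh_adjust(p), bh_step_up_oracle(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tx.bh_adjust(np.array([-0.1]))


class TestDeThresholds:
    def test_fdr_without_fold_change_is_significant_only(self):
        det = pd.DataFrame({"fdr": [0.04], "log2fc": [0.5]}, index=["g"])
        sig, high = tx.apply_de_thresholds(det)
        assert list(sig) == ["g"] and list(high) == []

    def test_both_filters_required_for_high_magnitude(self):
        det = pd.DataFrame({"fdr": [0.01, 0.01, 0.5],
                            "log2fc": [2.0, 0.2, 3.0]},
                           index=["a", "b", "c"])
        sig, high = tx.apply_de_thresholds(det)
        assert set(sig) == {"a", "b"} and set(high) == {"a"}


class TestZscore:
    def test_reference_columns_standardized(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(5, 2, (20, 6)),
                            columns=[f"s{i}" for i in range(6)])
        groups = pd.Series(["LPS"] * 2 + ["IL4"] * 4, index=expr.columns)
        z = tx.zscore_vs_reference(expr, groups)
        ref = z[groups[groups == "IL4"].index]
        assert np.allclose(ref.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(ref.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_shift_propagates_per_formula(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 10.0]],
                            columns=["i1", "i2", "i3", "l1"])
        groups = pd.Series(["IL4"] * 3 + ["LPS"], index=expr.columns)
        z0 = tx.zscore_vs_reference(expr, groups).loc[0, "l1"]
        z1 = tx.zscore_vs_reference(expr + 5.0, groups).loc[0, "l1"]
        assert z0 == pytest.approx(z1)

    def test_constant_reference_row_flagged_missing(self):
        expr = pd.DataFrame([[2.0, 2.0, 5.0]], columns=["i1", "i2", "l1"])
        groups = pd.Series(["IL4", "IL4", "LPS"], index=expr.columns)
        z = tx.zscore_vs_reference(expr, groups)
        assert z.isna().all(axis=None)


class TestFpkm:
    def test_length_scaling(self):
        cm = toy_matrix({"s1": [10, 10, 10 ** 6 - 20]}, ["LPS"])
        cm.counts.index = ["two_kb", "one_kb", "filler"]
        lengths = pd.Series([2.0, 1.0, 1.0], index=cm.counts.index)
        out = tx.fpkm(cm, lengths)
        raw_cpm = tx.cpm(cm)
        assert out.loc["two_kb", "s1"] == pytest.approx(
            raw_cpm.loc["two_kb", "s1"] / 2.0)
        assert out.loc["one_kb", "s1"] == pytest.approx(
            raw_cpm.loc["one_kb", "s1"])

    def test_random_matrix_matches_definition(self):
        cm, _ = sd.make_count_matrix(sd.CountSimConfig(seed=8, n_genes=30))
        lengths = pd.Series(np.random.default_rng(1).uniform(0.5, 8, 30),
                            index=cm.counts.index)
        assert np.allclose(tx.fpkm(cm, lengths),
                           tx.cpm(cm).div(lengths, axis=0))

    def test_missing_length_rejected(self):
        cm, _ = sd.make_count_matrix(sd.CountSimConfig(seed=8, n_genes=3))
        with pytest.raises(ValueError):
            tx.fpkm(cm, pd.Series([1.0], index=cm.counts.index[:1]))


class TestMds:
    def test_duplicate_samples_land_on_identical_coordinates(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.normal(0, 1, (200, 3)), columns=list("abc"))
        x["d"] = x["a"]
        coords = tx.mds_coordinates(x, top_n=200)
        assert np.allclose(coords.loc["a"], coords.loc["d"], atol=1e-8)

    def test_three_samples_embed_distances_exactly(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.normal(5, 2, (300, 3)), columns=list("abc"))
        coords = tx.mds_coordinates(x, top_n=300)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            emb = np.linalg.norm(coords.iloc[i] - coords.iloc[j])
            true = np.sqrt(((x.iloc[:, i] - x.iloc[:, j]) ** 2).mean())
            assert emb == pytest.approx(true, rel=1e-9)

    def test_planted_groups_separate(self):
        cm, _ = sd.make_count_matrix(sd.CountSimConfig(
            seed=9, n_genes=800, de_fraction=0.3, de_log2fc=4.0))
        coords = tx.mds_coordinates(tx.log2cpm(cm))
        groups = cm.groups
        lps = coords.loc[groups[groups == "LPS"].index].to_numpy()
        il4 = coords.loc[groups[groups == "IL4"].index].to_numpy()
        within = max(np.linalg.norm(lps - lps.mean(0), axis=1).max(),
                     np.linalg.norm(il4 - il4.mean(0), axis=1).max())
        between = np.linalg.norm(lps.mean(0) - il4.mean(0))
        assert between > within

    def test_fewer_than_three_samples_rejected(self):
        x = pd.DataFrame(np.ones((10, 2)), columns=["a", "b"])
        with pytest.raises(ValueError):
            tx.mds_coordinates(x)


class TestSignatureOverlap:
    def test_ratio_arithmetic(self):
        sig = {f"ct": {f"g{i}" for i in range(50)}}
        universe = {f"g{i}" for i in range(100)}
        de = {f"g{i}" for i in range(10)}
        assert tx.signature_overlap_ratio(de, sig, universe)["ct"] == pytest.approx(0.2)

    def test_de_equals_universe_gives_ratio_one(self):
        universe = {f"g{i}" for i in range(30)}
        sigs = {"a": {f"g{i}" for i in range(5)}, "b": {f"g{i}" for i in range(9, 20)}}
        out = tx.signature_overlap_ratio(universe, sigs, universe)
        assert np.allclose(out, 1.0)

    def test_disjoint_signature_is_zero_and_empty_is_missing(self):
        universe = {"a", "b"}
        out = tx.signature_overlap_ratio({"a"}, {"dj": {"b"}, "out": {"zz"}},
                                         universe)
        assert out["dj"] == 0.0 and np.isnan(out["out"])


class TestHcluster:
    def test_hand_upgma_on_three_points(self):
        # 1-D points at 0, 1, -2: pairwise distances 1, 2, 3
        m = pd.DataFrame([[0.0], [1.0], [-2.0]])
        z = tx.hcluster(m)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}
        assert z[0, 2] == pytest.approx(1.0)
        assert z[1, 2] == pytest.approx(2.5)

    def test_duplicate_rows_merge_first_at_zero_height(self):
        m = pd.DataFrame([[1.0, 2.0], [5.0, 5.0], [1.0, 2.0]])
        z = tx.hcluster(m)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 2}
        assert z[0, 2] == 0.0

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(4)
        z = tx.hcluster(pd.DataFrame(rng.normal(0, 1, (12, 6))))
        assert np.all(np.diff(z[:, 2]) >= -1e-12)

    def test_nan_rows_rejected(self):
        with pytest.raises(ValueError):
            tx.hcluster(pd.DataFrame([[1.0, np.nan], [0.0, 1.0]]))


class TestEnrichment:
    def test_p_matches_exact_enumeration(self):
        background = {f"g{i}" for i in range(20)}
        category = {f"g{i}" for i in range(5)}
        query = {"g0", "g1", "g2", "g10"}
        out = tx.enrich_hypergeometric(query, {"cat": category}, background)
        expect = sum(math.comb(5, k) * math.comb(15, 4 - k)
                     for k in (3, 4)) / math.comb(20, 4)
        assert out.p[0] == pytest.approx(expect, rel=1e-12)

    def test_zero_overlap_with_tiny_category_near_one(self):
        background = {f"g{i}" for i in range(100)}
        out = tx.enrich_hypergeometric({"g99"}, {"cat": {"g0"}}, background)
        assert out.p[0] == pytest.approx(1.0, abs=0.02)

    def test_category_equal_to_background_gives_p_one(self):
        background = {f"g{i}" for i in range(10)}
        out = tx.enrich_hypergeometric({"g1", "g2"}, {"all": background},
                                       background)
        assert out.p[0] == pytest.approx(1.0)

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            tx.enrich_hypergeometric({"zz"}, {"c": {"a"}}, {"a", "b"})

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("setA\tdesc\tg1\tg2\ng3\nsetB\tdesc\tg3\n")
        sets = tx.read_gmt(path)
        assert sets["setA"] == {"g1", "g2"} and sets["setB"] == {"g3"}
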
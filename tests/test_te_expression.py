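import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from naivebench.core import CountMatrix, Thresholds
from naivebench.te_expression import (bh_adjust, differential_expression,
                                      normalize, pca, polarization_summary,
                                      top_n_composition, top_sd_cluster)


def _cm(arr, prefix="f"):
    arr = np.asarray(arr)
    return CountMatrix([f"{prefix}{i}" for i in range(arr.shape[0])],
                       [f"s{j}" for j in range(arr.shape[1])], arr)


class TestNormalize:
    def test_identical_samples_unit_factors(self):
        cm = _cm(np.tile([[10], [20], [30]], (1, 4)))
        _, factors = normalize(cm)
        np.testing.assert_allclose(factors, 1.0)

    def test_doubled_sample_factor_two(self):
        base = np.array([[10, 10, 20], [20, 20, 40], [5, 5, 10]])
        _, factors = normalize(_cm(base))
        np.testing.assert_allclose(factors, [1 / 2**(1/3), 1 / 2**(1/3), 2 / 2**(1/3)],
                                   rtol=1e-12)
        # ratio between samples is what matters: third is double the others
        assert factors[2] / factors[0] == pytest.approx(2.0)

    def test_matches_hand_computed_median_of_ratios(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(50, size=(40, 5)) + 1
        _, factors = normalize(_cm(counts))
        # independent reimplementation: per-sample median of count/geomean
        geomean = np.exp(np.mean(np.log(counts), axis=1))
        expected = np.median(counts / geomean[:, None], axis=0)
        np.testing.assert_allclose(factors, expected, rtol=1e-12)

    def test_fallback_library_size(self):
        counts = np.array([[0, 5], [5, 0]])
        with pytest.warns(UserWarning, match="library-size"):
            _, factors = normalize(_cm(counts))
        np.testing.assert_allclose(factors, [1.0, 1.0])


class TestBH:
    def test_simple_case(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(bh_adjust(p), [0.02, 0.04, 0.04, 0.02])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_agrees_with_brute_force_definition(self, p_list):
        p = np.array(p_list)
        got = bh_adjust(p)
        m = p.size
        order = np.argsort(p, kind="stable")
        # brute force: padj_(i) = min_{k >= i} p_(k) * m / k, capped at 1
        expected = np.empty(m)
        for rank_i, idx in enumerate(order, start=1):
            vals = [p[order[k - 1]] * m / k for k in range(rank_i, m + 1)]
            expected[idx] = min(1.0, min(vals))
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_monotone_and_geq_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestDifferentialExpression:
    def test_identical_groups_no_calls(self):
        block = np.array([[10, 12, 11], [100, 90, 110], [5, 6, 4]])
        cm = _cm(np.hstack([block, block]))
        de = differential_expression(cm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        np.testing.assert_allclose(de["log2fc"], 0.0, atol=1e-12)
        assert (de["call"] == "no_change").all()

    def test_group_swap_antisymmetry(self):
        rng = np.random.default_rng(11)
        cm = _cm(rng.poisson(80, size=(30, 6)))
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        de_ab = differential_expression(cm, a, b, labels=("A", "B"))
        de_ba = differential_expression(cm, b, a, labels=("B", "A"))
        np.testing.assert_allclose(de_ab["log2fc"], -de_ba["log2fc"], atol=1e-12)
        np.testing.assert_allclose(de_ab["p"], de_ba["p"], atol=1e-12)
        mirror = {"up_in_A": "up_in_A", "up_in_B": "up_in_B", "no_change": "no_change"}
        assert list(de_ab["call"].map(mirror)) == list(de_ba["call"])

    def test_small_group_rejected(self, small_counts):
        with pytest.raises(ValueError, match=">= 2 samples"):
            differential_expression(small_counts, ["primed_r1"],
                                    ["naive_5iLA_r1", "naive_5iLA_r2"])

    def test_matches_step_by_step_welch_bh_oracle(self):
        rng = np.random.default_rng(23)
        counts = rng.poisson(60, size=(20, 6))
        cm = _cm(counts)
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        de = differential_expression(cm, a, b)
        # oracle: explicit median-of-ratios, per-feature Welch t, manual BH
        geomean = np.exp(np.mean(np.log(np.maximum(counts, 1)), axis=1))
        pos = (counts > 0).all(axis=1)
        factors = np.median(counts[pos] / np.exp(
            np.mean(np.log(counts[pos]), axis=1))[:, None], axis=0)
        norm = counts / factors
        logm = np.log2(norm + 1)
        detected = (norm[:, :3].mean(1) >= 1) | (norm[:, 3:].mean(1) >= 1)
        p_oracle = np.full(20, np.nan)
        for i in range(20):
            if not detected[i]:
                continue
            p_oracle[i] = stats.ttest_ind(logm[i, 3:], logm[i, :3],
                                          equal_var=False).pvalue
        np.testing.assert_allclose(de["p"], p_oracle, rtol=1e-10)
        det_idx = np.where(detected)[0]
        padj_oracle = np.full(20, np.nan)
        padj_oracle[det_idx] = bh_adjust(p_oracle[det_idx])
        np.testing.assert_allclose(de["padj"], padj_oracle, rtol=1e-10)

    def test_true_null_type_one_control(self):
        rng = np.random.default_rng(99)
        cm = _cm(rng.poisson(100, size=(2000, 6)))
        de = differential_expression(cm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        raw_rate = (de["p"] < 0.05).mean()
        assert 0.02 < raw_rate < 0.09  # ~5% raw positives
        assert (de["call"] != "no_change").mean() < 0.005  # BH+fold gate kills them

    def test_undetected_features_never_called(self):
        counts = np.vstack([np.zeros((3, 6), dtype=int),
                            np.full((3, 6), 50, dtype=int)])
        de = differential_expression(_cm(counts), ["s0", "s1", "s2"],
                                     ["s3", "s4", "s5"])
        assert (~de.loc[~de["detected"], "call"].ne("no_change")).all()
        assert de.loc[~de["detected"], "p"].isna().all()


class TestPolarization:
    def _de_frame(self, family_counts):
        """family -> (n_detected, n_up_naive, n_up_primed)"""
        rows = []
        for fam, (n_det, n_naive, n_primed) in family_counts.items():
            for i in range(n_det):
                call = ("up_in_naive" if i < n_naive
                        else "up_in_primed" if i < n_naive + n_primed
                        else "no_change")
                rows.append({"feature_id": f"{fam}_{i}", "base_mean": 10.0,
                             "log2fc": 2.0 if call != "no_change" else 0.0,
                             "p": 0.001, "padj": 0.01, "call": call,
                             "detected": True})
        de = pd.DataFrame(rows)
        fams = {r["feature_id"]: r["feature_id"].rsplit("_", 1)[0] for r in rows}
        return de, fams

    def test_hervh_worked_example(self):
        de, fams = self._de_frame({"HERVH-int": (847, 64, 546)})
        (s,) = polarization_summary(de, fams)
        assert s.n_de == 610
        assert s.pct_de == 72.0
        assert s.pct_up_primed_of_de == 89.5

    def test_sva_d_worked_example(self):
        de, fams = self._de_frame({"SVA_D": (539, 530, 0)})
        (s,) = polarization_summary(de, fams)
        assert s.pct_de == 98.3
        assert s.pct_up_naive_of_de == 100.0

    def test_percent_split_sums_to_100(self):
        de, fams = self._de_frame({"SVA": (100, 33, 34)})
        (s,) = polarization_summary(de, fams)
        assert s.pct_up_naive_of_de + s.pct_up_primed_of_de == pytest.approx(100.0, abs=0.11)

    def test_missing_family_label_rejected(self):
        de, _ = self._de_frame({"SVA": (3, 1, 0)})
        with pytest.raises(ValueError, match="without family"):
            polarization_summary(de, {})


class TestTopN:
    def _de(self, lfcs):
        return pd.DataFrame({
            "feature_id": [f"f{i}" for i in range(len(lfcs))],
            "base_mean": 10.0, "log2fc": lfcs, "p": 0.001, "padj": 0.01,
            "call": ["up_in_B" if x > 0 else "up_in_A" for x in lfcs],
            "detected": True,
        })

    def test_single_family(self):
        de = self._de([3.0, 2.0, 1.5])
        tally, n = top_n_composition(de, 2, {f"f{i}": "SVA_D" for i in range(3)})
        assert tally == {"SVA_D": 2} and n == 2

    def test_n_too_large_errors(self):
        de = self._de([3.0])
        with pytest.raises(ValueError, match="exceeds"):
            top_n_composition(de, 5, {"f0": "SVA_D"})

    def test_ties_included(self):
        de = self._de([3.0, 2.0, 2.0, 1.0])
        subs = {f"f{i}": s for i, s in enumerate(["a", "b", "c", "d"])}
        tally, n = top_n_composition(de, 2, subs)
        assert n == 3 and tally == {"a": 1, "b": 1, "c": 1}

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(5)
        lfcs = rng.normal(0, 2, 50)
        lfcs[lfcs == 0] = 0.1
        de = self._de(list(lfcs))
        subs = {f"f{i}": f"sub{i % 4}" for i in range(50)}
        tally, n = top_n_composition(de, 10, subs)
        order = sorted(range(50), key=lambda i: -abs(lfcs[i]))
        oracle = {}
        for i in order[:10]:
            oracle[subs[f"f{i}"]] = oracle.get(subs[f"f{i}"], 0) + 1
        assert n == 10 and tally == oracle


class TestTopSdCluster:
    def test_constant_matrix_errors(self):
        cm = _cm(np.full((5, 4), 7, dtype=int))
        with pytest.raises(ValueError, match="zero variance"):
            top_sd_cluster(cm, 3)

    def test_zero_variance_features_never_selected(self):
        rng = np.random.default_rng(1)
        var_block = rng.poisson(100, size=(5, 4))
        const_block = np.full((5, 4), 50, dtype=int)
        cm = _cm(np.vstack([const_block, var_block]))
        selected, _, _ = top_sd_cluster(cm, 5)
        assert set(selected) <= {f"f{i}" for i in range(5, 10)}

    def test_selection_equals_sd_sort_oracle(self):
        rng = np.random.default_rng(2)
        cm = _cm(rng.poisson(100, size=(30, 5)))
        selected, _, _ = top_sd_cluster(cm, 10)
        norm, _ = normalize(cm)
        sd = np.log2(norm + 1).std(axis=1, ddof=1)
        oracle = set(np.array(cm.feature_ids)[np.argsort(-sd)[:10]])
        assert set(selected) == oracle

    def test_n_top_too_large(self, small_counts):
        with pytest.raises(ValueError, match="exceeds"):
            top_sd_cluster(small_counts, 100)


class TestPCA:
    def test_duplicated_sample_identical_coords(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(100, size=(40, 3))
        counts = np.hstack([base, base[:, [0]]])
        coords, _ = pca(_cm(counts))
        np.testing.assert_allclose(coords[0], coords[3], atol=1e-8)

    def test_variance_explained_bounded(self):
        rng = np.random.default_rng(6)
        _, var = pca(_cm(rng.poisson(60, size=(30, 8))))
        assert 0 <= var.sum() <= 1 + 1e-12

    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(8)
        lo = rng.poisson(50, size=(50, 4))
        hi = rng.poisson(200, size=(50, 4))
        counts = np.hstack([np.vstack([lo, hi]), np.vstack([hi, lo])])
        coords, var = pca(_cm(counts))
        g1, g2 = coords[:4, 0], coords[4:, 0]
        assert max(g1) < min(g2) or max(g2) < min(g1)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match=">= 3 samples"):
            pca(_cm(np.ones((5, 2), dtype=int)))
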
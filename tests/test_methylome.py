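import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from naivebench.core import SampleSheet, Thresholds
from naivebench.methylome import (classify_imprinted_dmrs, global_level,
                                  overexpressed_te_methylation, region_levels,
                                  xlinked_cgi_methylation)


def _calls(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                       "meth_reads", "total_reads"])


def _levels(mapping, n_sites=20):
    """dmr_id -> level; builds a region_levels-style frame."""
    return pd.DataFrame({
        "weighted_level": pd.Series(mapping, dtype=float),
        "n_sites": n_sites,
    })


class TestGlobalLevel:
    def test_all_unmethylated(self):
        calls = _calls([("chrS1", p, "+", "CpG", 0, 10) for p in (1, 5, 9)])
        assert global_level(calls, "CpG") == 0.0

    def test_all_methylated(self):
        calls = _calls([("chrS1", p, "+", "CpG", 10, 10) for p in (1, 5)])
        assert global_level(calls, "CpG") == 1.0

    def test_two_site_arithmetic(self):
        calls = _calls([("chrS1", 1, "+", "CpG", 3, 10),
                        ("chrS1", 5, "+", "CpG", 7, 10)])
        assert global_level(calls, "CpG") == 0.5

    def test_weighting_by_coverage(self):
        calls = _calls([("chrS1", 1, "+", "CpG", 0, 30),
                        ("chrS1", 5, "+", "CpG", 10, 10)])
        assert global_level(calls, "CpG") == pytest.approx(0.25)

    def test_no_sites_null_with_warning(self):
        calls = _calls([("chrS1", 1, "+", "CpG", 1, 5)])
        with pytest.warns(UserWarning, match="no covered sites"):
            assert global_level(calls, "CH") is None


class TestRegionLevels:
    def test_region_covering_two_sites(self):
        calls = _calls([("chrS1", 1, "+", "CpG", 3, 10),
                        ("chrS1", 5, "+", "CpG", 7, 10)])
        regions = pd.DataFrame({"chrom": ["chrS1"], "start": [0], "end": [10],
                                "name": ["r1"], "score": [0], "strand": ["."]})
        out = region_levels(calls, regions, "CpG")
        assert out.loc["r1", "weighted_level"] == 0.5
        assert out.loc["r1", "n_sites"] == 2

    def test_disjoint_region_null(self):
        calls = _calls([("chrS1", 1, "+", "CpG", 3, 10)])
        regions = pd.DataFrame({"chrom": ["chrS1"], "start": [100], "end": [200],
                                "name": ["r1"], "score": [0], "strand": ["."]})
        out = region_levels(calls, regions, "CpG")
        assert np.isnan(out.loc["r1", "weighted_level"])

    def test_half_open_membership_on_pos_minus_one(self):
        # BED [10, 20): 1-based positions 11..20 inside, 10 and 21 outside
        calls = _calls([("chrS1", 10, "+", "CpG", 10, 10),
                        ("chrS1", 11, "+", "CpG", 0, 10),
                        ("chrS1", 20, "+", "CpG", 0, 10),
                        ("chrS1", 21, "+", "CpG", 10, 10)])
        regions = pd.DataFrame({"chrom": ["chrS1"], "start": [10], "end": [20],
                                "name": ["r"], "score": [0], "strand": ["."]})
        out = region_levels(calls, regions, "CpG")
        assert out.loc["r", "n_sites"] == 2
        assert out.loc["r", "weighted_level"] == 0.0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(12)
        chroms = rng.choice(["chrA", "chrB"], 500)
        pos = rng.integers(1, 10_000, 500)
        total = rng.integers(1, 40, 500)
        meth = rng.binomial(total, 0.4)
        calls = pd.DataFrame({"chrom": chroms, "pos": pos, "strand": "+",
                              "context": "CpG", "meth_reads": meth,
                              "total_reads": total})
        starts = rng.integers(0, 9_000, 100)
        regions = pd.DataFrame({
            "chrom": rng.choice(["chrA", "chrB"], 100), "start": starts,
            "end": starts + rng.integers(50, 2_000, 100),
            "name": [f"r{i}" for i in range(100)], "score": 0, "strand": ".",
        })
        out = region_levels(calls, regions, "CpG")
        for reg in regions.itertuples(index=False):
            hit = calls[(calls["chrom"] == reg.chrom)
                        & (calls["pos"] - 1 >= reg.start)
                        & (calls["pos"] - 1 < reg.end)]
            tot = hit["total_reads"].sum()
            if tot == 0:
                assert np.isnan(out.loc[reg.name, "weighted_level"])
            else:
                assert out.loc[reg.name, "weighted_level"] == \
                    pytest.approx(hit["meth_reads"].sum() / tot)

    def test_global_equals_one_whole_genome_region(self):
        rng = np.random.default_rng(3)
        total = rng.integers(1, 30, 200)
        calls = pd.DataFrame({"chrom": "chrS1", "pos": np.arange(1, 201),
                              "strand": "+", "context": "CpG",
                              "meth_reads": rng.binomial(total, 0.3),
                              "total_reads": total})
        regions = pd.DataFrame({"chrom": ["chrS1"], "start": [0], "end": [10_000],
                                "name": ["all"], "score": [0], "strand": ["."]})
        assert region_levels(calls, regions, "CpG").loc["all", "weighted_level"] == \
            pytest.approx(global_level(calls, "CpG"))


class TestOverexpressedTeMethylation:
    def test_identical_distributions(self):
        levels = pd.Series(np.tile([0.2, 0.5, 0.8], 4),
                           index=[f"t{i}" for i in range(12)])
        over = [f"t{i}" for i in range(6)]
        back = [f"t{i}" for i in range(6, 12)]
        m_over, m_back, p = overexpressed_te_methylation(levels, over, back)
        assert m_over == m_back
        assert p > 0.9

    def test_hypomethylated_set_detected(self):
        rng = np.random.default_rng(5)
        over = {f"o{i}": v for i, v in enumerate(np.clip(rng.normal(0.2, 0.1, 50), 0, 1))}
        back = {f"b{i}": v for i, v in enumerate(np.clip(rng.normal(0.4, 0.1, 200), 0, 1))}
        levels = pd.Series({**over, **back})
        m_over, m_back, p = overexpressed_te_methylation(levels, list(over), list(back))
        assert m_over < m_back
        assert p < 0.05

    def test_u_statistic_matches_exhaustive_pairwise_count(self):
        # exact permutation-null p from the brute-force U on small n
        from scipy import stats
        rng = np.random.default_rng(9)
        a = rng.random(6)
        b = rng.random(7)
        levels = pd.Series(np.concatenate([a, b]),
                           index=[f"x{i}" for i in range(13)])
        _, _, p = overexpressed_te_methylation(
            levels, [f"x{i}" for i in range(6)], [f"x{i}" for i in range(6, 13)])
        u_obs = sum(1 for x in a for y in b if x > y)
        pooled = np.concatenate([a, b])
        mean_u = len(a) * len(b) / 2
        count = total = 0
        for combo in itertools.combinations(range(13), 6):
            rest = [i for i in range(13) if i not in combo]
            u = sum(1 for i in combo for j in rest if pooled[i] > pooled[j])
            if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
                count += 1
            total += 1
        assert p == pytest.approx(count / total, abs=1e-9)

    def test_small_set_p_null(self):
        levels = pd.Series({"a": 0.1, "b": 0.2, "c": 0.5, "d": 0.6})
        m_over, m_back, p = overexpressed_te_methylation(levels, ["a", "b"],
                                                         ["c", "d"])
        assert p is None and m_over == pytest.approx(0.15)


class TestClassifyImprintedDmrs:
    @pytest.mark.parametrize("primed,naive,reprimed,verdict", [
        (0.5, 0.1, 0.1, "erased"),
        (0.5, 0.1, 0.5, "retained"),
        (0.5, 0.5, 0.1, "retained"),
        (0.2, 0.1, 0.1, "ineligible"),
        (0.8, 0.1, 0.1, "ineligible"),
        (0.30, 0.1, 0.1, "erased"),     # band closed at 0.30
        (0.70, 0.1, 0.1, "erased"),     # band closed at 0.70
        (0.5, 0.30, 0.1, "retained"),   # erase cutoff strict
    ])
    def test_trajectory_rule(self, primed, naive, reprimed, verdict):
        calls, _ = classify_imprinted_dmrs(
            _levels({"d": primed}), _levels({"d": naive}), _levels({"d": reprimed}))
        assert calls[0].verdict == verdict

    def test_missing_level_ineligible(self):
        calls, _ = classify_imprinted_dmrs(
            _levels({"d": np.nan}), _levels({"d": 0.1}), _levels({"d": 0.1}))
        assert calls[0].verdict == "ineligible"
        assert "missing" in calls[0].reason

    def test_low_coverage_ineligible(self):
        calls, _ = classify_imprinted_dmrs(
            _levels({"d": 0.5}, n_sites=3), _levels({"d": 0.1}), _levels({"d": 0.1}))
        assert calls[0].verdict == "ineligible"

    def test_fraction_denominators(self):
        primed = _levels({"a": 0.5, "b": 0.5, "c": 0.1})
        naive = _levels({"a": 0.1, "b": 0.1, "c": 0.1})
        reprimed = _levels({"a": 0.1, "b": 0.6, "c": 0.1})
        _, frac_eligible = classify_imprinted_dmrs(primed, naive, reprimed)
        _, frac_all = classify_imprinted_dmrs(primed, naive, reprimed,
                                              denominator="all")
        assert frac_eligible == pytest.approx(1 / 2)
        assert frac_all == pytest.approx(1 / 3)

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError, match="must match"):
            classify_imprinted_dmrs(_levels({"a": 0.5}), _levels({"b": 0.1}),
                                    _levels({"a": 0.1}))

    @settings(max_examples=60, deadline=None)
    @given(
        primed=st.floats(0.3, 0.7),
        naive=st.floats(0.0, 1.0),
        reprimed=st.floats(0.0, 1.0),
        delta=st.floats(0.0, 0.5),
    )
    def test_erasure_monotone_in_naive_and_reprimed(self, primed, naive,
                                                    reprimed, delta):
        # lowering naive or reprimed never flips erased -> retained
        def verdict(n, r):
            calls, _ = classify_imprinted_dmrs(
                _levels({"d": primed}), _levels({"d": n}), _levels({"d": r}))
            return calls[0].verdict
        base = verdict(naive, reprimed)
        if base == "erased":
            assert verdict(max(naive - delta, 0), reprimed) == "erased"
            assert verdict(naive, max(reprimed - delta, 0)) == "erased"


class TestXlinkedCgi:
    def _sheet(self):
        return SampleSheet.from_records([
            {"sample_id": "pf", "state": "primed", "sex": "female", "replicate": 1},
            {"sample_id": "nm", "state": "naive_5iLA", "sex": "male", "replicate": 1},
        ])

    def test_female_primed_flagged_intermediate(self):
        rng = np.random.default_rng(2)
        per_sample = {
            "pf": pd.Series(np.clip(rng.normal(0.5, 0.05, 100), 0, 1)),
            "nm": pd.Series(np.clip(rng.normal(0.08, 0.03, 100), 0, 1)),
        }
        out = xlinked_cgi_methylation(per_sample, self._sheet()).set_index("sample_id")
        assert bool(out.loc["pf", "intermediate"])
        assert not bool(out.loc["nm", "intermediate"])
        assert out.loc["nm", "median"] < 0.3

    def test_all_null_regions_error(self):
        per_sample = {"pf": pd.Series([np.nan, np.nan]),
                      "nm": pd.Series([0.1, 0.1])}
        with pytest.raises(ValueError, match="all region levels null"):
            xlinked_cgi_methylation(per_sample, self._sheet())
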
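"""Time-point consolidation, multi-cohort pooling, synchronization, region queries."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from patternmap import (
    CohortTable,
    DimensionError,
    DiscretizationRule,
    RegionQuery,
    combine,
    consolidate_timepoints,
    pattern_key,
    pooled_pattern_groups,
    region_counts,
    synchronized_genes,
)

from conftest import make_profile

FC_ONLY = DiscretizationRule(p_threshold=None)


def table(cohort_id, rows, T=3, pvals=False):
    """rows: {gene: fc tuple (log2)}; optional uniform p-values."""
    profiles = [
        make_profile(g, fc, (0.01,) * len(fc) if pvals else None)
        for g, fc in rows.items()
    ]
    return CohortTable(cohort_id, tuple(f"T{i+1}" for i in range(T)), profiles)


class TestConsolidation:
    def test_mean_of_log2_fold_changes(self):
        t = table("c1", {"g": (1.0, 2.0, 0.5)})
        out = consolidate_timepoints(t, [[0, 1], [2]])
        assert out.profiles[0].fc == (1.5, 0.5)
        assert out.timepoints == ("T1+T2", "T3")

    def test_identity_grouping_is_a_noop(self):
        t = table("c1", {"g": (1.0, -2.0, 0.5)})
        out = consolidate_timepoints(t, [[0], [1], [2]])
        assert out.timepoints == t.timepoints
        assert out.profiles[0].fc == t.profiles[0].fc

    def test_group_pvalue_is_conservative_max(self):
        t = CohortTable("c1", ("T1", "T2", "T3"),
                        [make_profile("g", (1.0, 1.0, 0.0), (0.01, 0.03, 0.5))])
        out = consolidate_timepoints(t, [[0, 1], [2]])
        assert out.profiles[0].pvalue == (0.03, 0.5)

    def test_fisher_combination_option(self):
        t = CohortTable("c1", ("T1", "T2", "T3"),
                        [make_profile("g", (1.0, 1.0, 0.0), (0.01, 0.03, 0.5))])
        out = consolidate_timepoints(t, [[0, 1], [2]], p_combine="fisher")
        assert 0 < out.profiles[0].pvalue[0] < 0.01  # Fisher reinforces agreement
        assert out.profiles[0].pvalue[1] == 0.5  # singleton groups pass through

    @pytest.mark.parametrize("grouping", [[[0, 1]], [[0, 0], [1, 2]], [[1, 0], [2]], [[0], [2]]])
    def test_non_covering_overlapping_or_disordered_grouping_rejected(self, grouping):
        t = table("c1", {"g": (1.0, 2.0, 3.0)})
        with pytest.raises(ValueError):
            consolidate_timepoints(t, grouping)


class TestCombine:
    def test_shared_gene_contributes_once_per_cohort(self):
        a = table("a", {"G": (1.5, 0.0, 0.0)})
        b = table("b", {"G": (1.5, 0.0, 0.0)})
        combined = combine([a, b], FC_ONLY)
        pooled = pooled_pattern_groups(combined)
        (group,) = pooled.groups
        assert group.key == "+00" and group.count == 2

    def test_disjoint_cohorts_pool_to_union(self):
        a = table("a", {"g1": (1.5, 0, 0), "g2": (0, -1.5, 0)})
        b = table("b", {"g3": (1.5, 0, 0)})
        pooled = pooled_pattern_groups(combine([a, b], FC_ONLY))
        assert {g.key: g.count for g in pooled.groups} == {"+00": 2, "0-0": 1}

    def test_unequal_timepoints_is_a_dimension_error(self):
        a = table("a", {"g": (1.5, 0, 0)})
        b = CohortTable("b", ("T1", "T2"), [make_profile("g", (1.5, 0))])
        with pytest.raises(DimensionError, match="consolidate"):
            combine([a, b], FC_ONLY)

    def test_single_cohort_rejected(self):
        with pytest.raises(ValueError, match="master-panel"):
            combine([table("a", {"g": (1.5, 0, 0)})], FC_ONLY)

    @given(
        st.dictionaries(
            st.sampled_from([f"g{i}" for i in range(8)]),
            st.lists(st.sampled_from([-1.5, 0.0, 1.5]), min_size=3, max_size=3),
            max_size=8,
        ),
        st.dictionaries(
            st.sampled_from([f"g{i}" for i in range(8)]),
            st.lists(st.sampled_from([-1.5, 0.0, 1.5]), min_size=3, max_size=3),
            max_size=8,
        ),
    )
    def test_pooled_counts_equal_sum_of_per_cohort_counts(self, rows_a, rows_b):
        from patternmap import group_by_pattern

        a, b = table("a", rows_a), table("b", rows_b)
        pooled = pooled_pattern_groups(combine([a, b], FC_ONLY))
        per_cohort: dict[str, int] = {}
        for t in (a, b):
            for g in group_by_pattern(t, FC_ONLY).groups:
                per_cohort[g.key] = per_cohort.get(g.key, 0) + g.count
        assert {g.key: g.count for g in pooled.groups} == per_cohort


class TestSynchronizedGenes:
    def test_identical_key_in_both_cohorts(self):
        a = table("a", {"G": (1.5, 0, -1.5)})
        b = table("b", {"G": (1.5, 0, -1.5)})
        sync = synchronized_genes(combine([a, b], FC_ONLY))
        assert sync == {"+0-": ["G"]}

    def test_differing_keys_excluded_in_all_cohorts_scope(self):
        a = table("a", {"G": (1.5, 0, -1.5)})
        b = table("b", {"G": (1.5, 0, 0)})
        assert synchronized_genes(combine([a, b], FC_ONLY)) == {}

    def test_gene_absent_from_one_cohort_excluded(self):
        a = table("a", {"G": (1.5, 0, 0), "H": (1.5, 0, 0)})
        b = table("b", {"G": (1.5, 0, 0)})
        assert synchronized_genes(combine([a, b], FC_ONLY)) == {"+00": ["G"]}

    def test_invariant_under_cohort_reordering(self):
        a = table("a", {"G": (1.5, 0, -1.5), "H": (0, 1.5, 0)})
        b = table("b", {"G": (1.5, 0, -1.5), "H": (0, 1.5, 0)})
        c = table("c", {"G": (1.5, 0, -1.5), "H": (0, -1.5, 0)})
        results = [
            synchronized_genes(combine(list(order), FC_ONLY))
            for order in itertools.permutations([a, b, c])
        ]
        assert all(r == results[0] for r in results)

    def test_at_least_k_against_enumeration_oracle(self):
        """3 cohorts; every configuration of presence/keys for one gene."""
        keys = ["+00", "0+0", None]  # None = gene absent from that cohort
        for combo in itertools.product(keys, repeat=3):
            tables = []
            for i, key in enumerate(combo):
                rows = {"F": (1.5, 1.5, 1.5)}  # filler keeps cohorts non-empty
                if key is not None:
                    fc = tuple(1.5 if s == "+" else 0.0 for s in key)
                    rows["G"] = fc
                tables.append(table(f"c{i}", rows))
            combined = combine(tables, FC_ONLY)
            sync2 = synchronized_genes(combined, scope="at_least_k", k=2)
            # oracle: direct count of identical keys among present cohorts
            counts = {}
            for key in combo:
                if key is not None:
                    counts[key] = counts.get(key, 0) + 1
            expect = {k for k, c in counts.items() if c >= 2}
            got = {k for k, genes in sync2.items() if "G" in genes}
            assert got == expect

    def test_bad_k_rejected(self):
        a = table("a", {"G": (1.5, 0, 0)})
        b = table("b", {"G": (1.5, 0, 0)})
        with pytest.raises(ValueError):
            synchronized_genes(combine([a, b], FC_ONLY), scope="at_least_k", k=3)


class TestRegionQueries:
    def combined_from(self, rows):
        a = table("a", {g: fc for g, fc in rows.items()}, T=5)
        b = table("b", {"filler": (1.5, 0, 0, 0, 0)}, T=5)
        return combine([a, b], FC_ONLY)

    def test_any_significant_on_selected_columns(self):
        combined = self.combined_from({"g": (1.5, -1.5, 0, 0, -1.5)})  # key +-00-
        query = RegionQuery({0: "*", 1: "*", 4: "*"})
        report = region_counts(combined, query)
        assert [(c, g) for c, g, _ in report.matched] == [("a", "g")]
        assert list(report.strata) == ["+--"]

    def test_all_neutral_key_never_matches(self):
        combined = self.combined_from({"z": (0, 0, 0, 0, 0)})
        report = region_counts(combined, RegionQuery({0: "*", 1: "*", 4: "*"}))
        assert report.count == 0

    def test_exact_mode_excludes_extra_significant_positions(self):
        combined = self.combined_from({"g": (1.5, 1.5, 1.5, 0, 1.5)})  # sig at 0,1,2,4
        q = RegionQuery({0: "*", 1: "*", 4: "*"})
        assert region_counts(combined, q).count == 0
        q_loose = RegionQuery({0: "*", 1: "*", 4: "*"}, mode="at_least")
        assert region_counts(combined, q_loose).count == 1

    def test_three_positions_stratify_into_eight_subkeys(self):
        rows = {
            f"g{i}": tuple(
                {"+": 1.5, "-": -1.5}[s] if t in (0, 1, 4) else 0.0
                for t, s in enumerate(signs[0] + signs[1] + "00" + signs[2])
            )
            for i, signs in enumerate("".join(c) for c in itertools.product("+-", repeat=3))
        }
        combined = self.combined_from(rows)
        report = region_counts(combined, RegionQuery({0: "*", 1: "*", 4: "*"}))
        assert report.count == 8
        assert len(report.strata) == 8
        assert sum(len(v) for v in report.strata.values()) == report.count

    def test_strata_partition_matched_set(self):
        rows = {
            "g1": (1.5, 1.5, 0, 0, 1.5),
            "g2": (1.5, -1.5, 0, 0, 1.5),
            "g3": (1.5, -1.5, 0, 0, 1.5),
            "g4": (0, -1.5, 0, 0, 1.5),  # not significant at position 0
        }
        combined = self.combined_from(rows)
        report = region_counts(combined, RegionQuery({0: "*", 1: "*", 4: "*"}))
        assert report.count == 3
        assert sum(len(v) for v in report.strata.values()) == 3

    @given(
        st.dictionaries(
            st.sampled_from([f"g{i}" for i in range(10)]),
            st.lists(st.sampled_from([-1.5, 0.0, 1.5]), min_size=3, max_size=3),
            max_size=10,
        ),
        st.dictionaries(
            st.sampled_from([f"g{i}" for i in range(10)]),
            st.lists(st.sampled_from([-1.5, 0.0, 1.5]), min_size=3, max_size=3),
            max_size=10,
        ),
    )
    def test_venn_consistency_on_two_cohorts(self, rows_a, rows_b):
        """|A only| + |B only| + |both| equals |A ∪ B| for significant genes."""
        sig = lambda rows: {
            g for g, fc in rows.items()
            if pattern_key(make_profile(g, fc), FC_ONLY) != "000"
        }
        a_sig, b_sig = sig(rows_a), sig(rows_b)
        only_a = a_sig - b_sig
        only_b = b_sig - a_sig
        both = a_sig & b_sig
        assert len(only_a) + len(only_b) + len(both) == len(a_sig | b_sig)
        # and the combined entries agree with the brute-force significant sets
        a, b = table("a", rows_a), table("b", rows_b)
        combined = combine([a, b], FC_ONLY)
        got_a = {g for c, g, _ in combined.entries if c == "a"}
        got_b = {g for c, g, _ in combined.entries if c == "b"}
        assert got_a == a_sig and got_b == b_sig
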
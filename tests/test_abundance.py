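import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metadefense.abundance import (bray_curtis, community_profile,
                                   complete_linkage, contig_coverage,
                                   contig_cpm_table, cpm, enrichment_call,
                                   aggregate_feature_cpm, gc_distribution,
                                   lca_assign, pearson_correlation, percentage,
                                   ratio_2dp)
from metadefense.core_io import (AlignmentHit, DepthTable, SequenceRecord,
                                 Taxonomy, TaxonomyNode)


class TestCoverage:
    def test_uniform(self):
        assert contig_coverage(np.array([2, 2, 2, 2])) == 2.0

    def test_zeros_included(self):
        assert contig_coverage(np.array([10, 0, 0, 0])) == 2.5

    def test_empty_error(self):
        with pytest.raises(ValueError):
            contig_coverage(np.array([]))


class TestCpm:
    def test_zero_coverage(self):
        assert cpm(0.0, 1000) == 0.0

    def test_arithmetic(self):
        assert cpm(20.0, 2_000_000_000) == pytest.approx(0.01)

    def test_nonpositive_total_error(self):
        with pytest.raises(ValueError):
            cpm(1.0, 0)

    def test_conservation_identity(self, rng):
        """sum_c cpm_c * len_c == 1e6 when depth and total agree."""
        for _ in range(5):
            lengths = rng.integers(50, 500, size=8)
            table = DepthTable({f"c{i}": rng.poisson(10, size=n)
                                for i, n in enumerate(lengths)})
            total = table.total_depth()
            cpms = contig_cpm_table(table, total)
            acc = sum(cpms[f"c{i}"] * int(n) for i, n in enumerate(lengths))
            assert acc == pytest.approx(1e6, rel=1e-9)


class TestAggregate:
    def test_additivity(self):
        out = aggregate_feature_cpm([("f", "c1"), ("f", "c2")],
                                    {"c1": 0.1, "c2": 0.2}, "s1")
        assert len(out) == 1
        assert out[0].cpm == pytest.approx(0.3)
        assert out[0].raw_count == 2

    def test_no_instances(self):
        assert aggregate_feature_cpm([], {"c1": 0.1}, "s1") == []

    def test_unknown_contig_error(self):
        with pytest.raises(KeyError, match="featX"):
            aggregate_feature_cpm([("featX", "nope")], {"c1": 0.1}, "s1")


class TestEnrichment:
    def test_sponge_enriched(self):
        call = enrichment_call("f", [2, 2, 2], 1.0)
        assert call.flag == "sponge"

    def test_no_enrichment(self):
        assert enrichment_call("f", [1, 1, 1], 1.0).flag == "none"

    def test_zero_seawater_positive_sponge(self):
        assert enrichment_call("f", [0.5], 0.0).flag == "sponge"

    def test_zero_sponge_positive_seawater(self):
        assert enrichment_call("f", [0.0, 0.0, 0.0], 0.2).flag == "seawater"

    def test_both_zero_none(self):
        assert enrichment_call("f", [0.0], 0.0).flag == "none"

    def test_exactly_factor_not_enriched(self):
        assert enrichment_call("f", [1.5], 1.0, factor=1.5).flag == "none"

    def test_order_invariance(self):
        a = enrichment_call("f", [0.5, 2.0, 1.0], 0.6)
        b = enrichment_call("f", [2.0, 1.0, 0.5], 0.6)
        assert a.flag == b.flag

    def test_empty_sponge_error(self):
        with pytest.raises(ValueError):
            enrichment_call("f", [], 1.0)


class TestBrayCurtis:
    def test_identical_zero(self):
        p = {"a": 0.5, "b": 0.5}
        assert bray_curtis(p, p) == pytest.approx(0.0)

    def test_disjoint_one(self):
        assert bray_curtis({"a": 1.0}, {"b": 1.0}) == pytest.approx(1.0)

    def test_closed_form(self):
        # 1 - 2*(min(.7,.3)+min(.3,.7))/2 = 1 - 0.6 = 0.4
        assert bray_curtis({"x": 0.7, "y": 0.3},
                           {"x": 0.3, "y": 0.7}) == pytest.approx(0.4)

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            bray_curtis({"a": 0.0}, {"b": 0.0})

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6),
           st.lists(st.floats(0, 1), min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_properties(self, xs, ys):
        a = {f"t{i}": v for i, v in enumerate(xs)}
        b = {f"t{i}": v for i, v in enumerate(ys)}
        if sum(a.values()) == 0 and sum(b.values()) == 0:
            return
        d_ab = bray_curtis(a, b)
        assert 0.0 <= d_ab <= 1.0 + 1e-12
        assert d_ab == pytest.approx(bray_curtis(b, a))
        if sum(a.values()) > 0:
            assert bray_curtis(a, a) == pytest.approx(0.0)


class TestCompleteLinkage:
    def test_two_samples(self):
        newick = complete_linkage(np.array([[0, 0.3], [0.3, 0]]), ["A", "B"])
        assert newick == "(A:0.3,B:0.3);"

    def test_three_sample_hand_trace(self):
        d = np.array([[0.0, 0.1, 0.4],
                      [0.1, 0.0, 0.4],
                      [0.4, 0.4, 0.0]])
        newick = complete_linkage(d, ["A", "B", "C"])
        assert newick == "((A:0.1,B:0.1):0.3,C:0.4);"

    def test_duplicate_sample_merges_at_zero(self):
        d = np.array([[0.0, 0.0, 0.5],
                      [0.0, 0.0, 0.5],
                      [0.5, 0.5, 0.0]])
        newick = complete_linkage(d, ["A", "A2", "C"])
        assert newick.startswith("((A:0,A2:0)")

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            complete_linkage(np.array([[0, 0.2], [0.3, 0]]), ["A", "B"])


def six_node_taxonomy():
    return Taxonomy([
        TaxonomyNode(1, 1, "root", "root"),
        TaxonomyNode(2, 1, "domain", "Bacteria"),
        TaxonomyNode(3, 1, "domain", "Archaea"),
        TaxonomyNode(4, 2, "genus", "GenusX"),
        TaxonomyNode(5, 4, "species", "spA"),
        TaxonomyNode(6, 4, "species", "spB"),
    ])


def ahit(taxid, bit=100.0):
    return AlignmentHit("q1", f"s{taxid}", taxid, 99.0, 100, bit, 1e-30)


class TestLca:
    def test_single_species(self):
        tax = six_node_taxonomy()
        assert lca_assign([ahit(5)], tax) == 5

    def test_sister_species_give_genus(self):
        tax = six_node_taxonomy()
        assert lca_assign([ahit(5), ahit(6)], tax) == 4

    def test_two_domains_give_root(self):
        tax = six_node_taxonomy()
        assert lca_assign([ahit(5), ahit(3)], tax) == 1

    def test_no_hits_unassigned(self):
        assert lca_assign([], six_node_taxonomy()) is None

    def test_score_filter_drops_weak_hits(self):
        tax = six_node_taxonomy()
        # weak hit to Archaea is outside the top-10% band: LCA stays species
        assert lca_assign([ahit(5, 100.0), ahit(3, 50.0)], tax) == 5

    def test_unknown_taxid_error(self):
        with pytest.raises(KeyError):
            lca_assign([ahit(99)], six_node_taxonomy())

    def test_result_ancestor_of_all_retained(self):
        tax = six_node_taxonomy()
        hits = [ahit(5), ahit(6), ahit(3, 95.0)]
        result = lca_assign(hits, tax)
        for h in hits:
            if h.bit_score >= 0.9 * 100.0:
                assert result in tax.lineage(h.subject_taxid)

    def test_shrinking_fraction_never_moves_toward_root(self):
        tax = six_node_taxonomy()
        hits = [ahit(5, 100.0), ahit(6, 92.0), ahit(3, 91.0)]
        wide = lca_assign(hits, tax, top_score_fraction=0.1)
        narrow = lca_assign(hits, tax, top_score_fraction=0.05)
        assert wide in tax.lineage(narrow)


class TestCommunityProfile:
    def test_sums_to_one_with_other(self):
        tax = six_node_taxonomy()
        profile = community_profile({"q1": 5, "q2": 6, "q3": None},
                                    tax, rank="genus")
        assert sum(profile.values()) == pytest.approx(1.0)
        assert profile["other"] == pytest.approx(1 / 3)
        assert profile["GenusX"] == pytest.approx(2 / 3)


class TestGc:
    def test_all_gc(self):
        per, _, _ = gc_distribution([SequenceRecord("r", "GGCC")])
        assert per["r"] == 1.0

    def test_no_gc(self):
        per, _, _ = gc_distribution([SequenceRecord("r", "ATAT")])
        assert per["r"] == 0.0

    def test_n_excluded(self):
        per, _, _ = gc_distribution([SequenceRecord("r", "ACGTN")])
        assert per["r"] == 0.5

    def test_all_n_error(self):
        with pytest.raises(ValueError):
            gc_distribution([SequenceRecord("r", "NNNN")])


class TestPercentage:
    def test_examples(self):
        assert percentage(53, 77) == 68.83
        assert percentage(21, 40) == 52.50
        assert percentage(0, 7) == 0.00

    def test_round_half_up(self):
        assert percentage(1, 800) == 0.13  # 0.125 rounds up, not to even

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            percentage(1, 0)

    def test_ratio(self):
        assert ratio_2dp(5, 4) == 1.25
        assert ratio_2dp(1, 3) == 0.33


class TestPearson:
    def test_identical(self):
        r, _ = pearson_correlation([1, 2, 3], [1, 2, 3])
        assert r == pytest.approx(1.0)

    def test_anticorrelated(self):
        r, _ = pearson_correlation([1, 2, 3], [-1, -2, -3])
        assert r == pytest.approx(-1.0)

    def test_direct_formula_oracle(self):
        a, b = [1, 2, 3], [2, 4, 7]
        # direct summation oracle
        ma, mb = sum(a) / 3, sum(b) / 3
        cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
        sa = math.sqrt(sum((x - ma) ** 2 for x in a))
        sb = math.sqrt(sum((y - mb) ** 2 for y in b))
        expected = cov / (sa * sb)
        r, p = pearson_correlation(a, b)
        assert r == pytest.approx(expected, rel=1e-12)
        assert 0 <= p <= 1

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_too_short_error(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [3, 4])
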
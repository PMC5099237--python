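import math

import numpy as np
import pytest
from Bio import Align

from metadefense.alignment import (ScoringScheme, evalue,
                                   karlin_altschul_params, reverse_complement,
                                   seeded_local_align, smith_waterman_score)
from metadefense.core_io import SequenceRecord
from metadefense.spacer_analysis import (categorize_targets, collect_spacers,
                                         match_repeats_to_reference,
                                         search_targets, shared_sequences)
from metadefense.synthetic import random_dna

from conftest import make_array


def biopython_oracle(scheme):
    """Independent exhaustive local aligner under the same gap convention
    (gap of length L costs gap_open + L*gap_extend)."""
    return Align.PairwiseAligner(
        mode="local", match_score=scheme.match, mismatch_score=scheme.mismatch,
        open_gap_score=scheme.gap_open + scheme.gap_extend,
        extend_gap_score=scheme.gap_extend)


class TestCollectSpacers:
    def test_multiplicities(self):
        arr1 = make_array(spacers=("A" * 36, "C" * 36))
        arr2 = make_array(contig_id="c2", spacers=("A" * 36, "G" * 36))
        cat = collect_spacers([arr1, arr2])
        assert cat.total == 4
        assert cat.distinct == 3
        assert cat.counts["A" * 36] == 2
        assert cat.singletons == 2
        assert cat.multi_occurring == 1

    def test_empty(self):
        cat = collect_spacers([])
        assert cat.total == 0 and cat.distinct == 0

    def test_planted_distinct(self, rng):
        arrays = [make_array(contig_id=f"c{i}",
                             spacers=(random_dna(rng, 36), random_dna(rng, 36)))
                  for i in range(5)]
        cat = collect_spacers(arrays)
        assert cat.distinct == 10
        assert cat.singletons == 10

    def test_unvalidated_rejected(self):
        arr = make_array(validated=False)
        with pytest.raises(ValueError):
            collect_spacers([arr])


class TestSharedSequences:
    def test_overlap(self):
        assert shared_sequences({"X", "Y"}, {"Y", "Z"}) == ["Y"]

    def test_disjoint(self):
        assert shared_sequences({"X"}, {"Z"}) == []

    def test_identity(self):
        a = {"AA", "CC", "GG"}
        assert len(shared_sequences(a, a)) == 3

    def test_symmetric(self, rng):
        a = {random_dna(rng, 20) for _ in range(10)}
        b = {random_dna(rng, 20) for _ in range(10)} | set(list(a)[:3])
        assert shared_sequences(a, b) == shared_sequences(b, a)

    def test_reverse_complement_optional(self):
        a = {"ACGTT"}
        b = {reverse_complement("ACGTT")}
        assert shared_sequences(a, b) == []
        assert shared_sequences(a, b, reverse_complement_match=True) == ["ACGTT"]


class TestSearchTargets:
    def test_verbatim_embedding_scores_length(self, rng):
        spacer = random_dna(rng, 25)
        target = random_dna(rng, 300) + spacer + random_dna(rng, 300)
        hits = search_targets([SequenceRecord("sp1", spacer)],
                              [(SequenceRecord("t1", target), "phage")])
        assert len(hits) == 1
        assert hits[0].score == 25
        assert hits[0].target_category == "phage"

    def test_one_substitution_scores_23(self, rng):
        spacer = random_dna(rng, 25)
        mutated = list(spacer)
        mutated[12] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[12]]
        target = random_dna(rng, 300) + "".join(mutated) + random_dna(rng, 300)
        hits = search_targets([SequenceRecord("sp1", spacer)],
                              [(SequenceRecord("t1", target), "plasmid")])
        assert hits[0].score == 23  # 24 matches - 1 mismatch

    def test_no_shared_word_no_hit(self):
        spacer = "A" * 24
        target = "C" * 200  # reverse complement is all G: no shared 7-mer
        hits = search_targets([SequenceRecord("sp1", spacer)],
                              [(SequenceRecord("t1", target), "virus")])
        assert hits == []

    def test_reverse_strand_found(self, rng):
        spacer = random_dna(rng, 30)
        target = random_dna(rng, 200) + reverse_complement(spacer) \
            + random_dna(rng, 200)
        hits = search_targets([SequenceRecord("sp1", spacer)],
                              [(SequenceRecord("t1", target), "phage")])
        assert hits[0].score == 30
        assert hits[0].strand == "-"

    def test_unlabelled_target_error(self, rng):
        with pytest.raises(ValueError, match="category"):
            search_targets([SequenceRecord("sp1", random_dna(rng, 25))],
                           [(SequenceRecord("t1", random_dna(rng, 100)), "junk")])

    def test_short_spacer_error(self):
        with pytest.raises(ValueError, match="word size"):
            search_targets([SequenceRecord("sp1", "ACGTA")],
                           [(SequenceRecord("t1", "ACGT" * 30), "phage")])

    def test_raising_evalue_max_never_loses_hits(self, rng):
        spacers = [SequenceRecord(f"s{i}", random_dna(rng, 30)) for i in range(5)]
        target_seq = random_dna(rng, 800) + spacers[0].sequence[:20] \
            + random_dna(rng, 200)
        targets = [(SequenceRecord("t1", target_seq), "phage")]
        loose = search_targets(spacers, targets, ScoringScheme(evalue_max=10.0))
        tight = search_targets(spacers, targets, ScoringScheme(evalue_max=0.01))
        assert {(h.spacer_id, h.target_id) for h in tight} <= \
               {(h.spacer_id, h.target_id) for h in loose}

    def test_matches_exhaustive_oracle_per_strand(self, rng):
        """Per-strand scores equal full Smith-Waterman whenever a seed exists."""
        scheme = ScoringScheme()
        oracle = biopython_oracle(scheme)
        checked = 0
        for trial in range(25):
            spacer = random_dna(rng, int(rng.integers(20, 61)))
            target = random_dna(rng, int(rng.integers(300, 1200)))
            if trial % 2 == 0:
                copy = list(spacer)
                for _ in range(int(rng.integers(0, 5))):
                    i = int(rng.integers(0, len(copy)))
                    copy[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[i]]
                pos = int(rng.integers(0, len(target) - len(spacer)))
                target = target[:pos] + "".join(copy) + target[pos + len(spacer):]
            for strand_seq in (target, reverse_complement(target)):
                aln = seeded_local_align(spacer, strand_seq, scheme,
                                         both_strands=False)
                if aln is not None:
                    assert aln.score == oracle.score(strand_seq, spacer)
                    checked += 1
        assert checked >= 10


class TestCategorize:
    def _hit(self, spacer_id, category):
        from metadefense.spacer_analysis import SpacerHit
        return SpacerHit(spacer_id, "t", category, 20, 1e-5, 1, 20, 1, 20, "+")

    def test_no_hit_unknown(self):
        by_spacer, tallies = categorize_targets(["s1"], [])
        assert by_spacer["s1"] == {"unknown"}
        assert tallies["unknown"] == 1

    def test_single_category(self):
        by_spacer, tallies = categorize_targets(["s1"], [self._hit("s1", "plasmid")])
        assert by_spacer["s1"] == {"plasmid"}

    def test_multi_category_double_counted(self):
        hits = [self._hit("s1", "phage"), self._hit("s1", "plasmid")]
        by_spacer, tallies = categorize_targets(["s1", "s2"], hits)
        assert tallies["phage"] == 1
        assert tallies["plasmid"] == 1
        assert tallies["unknown"] == 1
        # category tallies may sum to more than the number of spacers with a target
        assert tallies["phage"] + tallies["plasmid"] > \
            len([s for s, c in by_spacer.items() if c != {"unknown"}])


class TestRepeatReference:
    def test_identical_repeat_known(self, rng):
        rep = random_dna(rng, 32)
        known, unknown = match_repeats_to_reference(
            [SequenceRecord("r1", rep)], [SequenceRecord("ref1", rep)])
        assert known == ["r1"] and unknown == []

    def test_empty_reference_all_unknown(self, rng):
        known, unknown = match_repeats_to_reference(
            [SequenceRecord("r1", random_dna(rng, 32))], [])
        assert known == [] and unknown == ["r1"]

    def test_unrelated_sequences_unknown(self, rng):
        scheme = ScoringScheme(evalue_max=0.01)
        oracle = biopython_oracle(scheme)
        rep = random_dna(rng, 32)
        refs = [SequenceRecord(f"ref{i}", random_dna(rng, 40)) for i in range(5)]
        db_len = sum(len(r) for r in refs)
        # oracle pre-check: no reference alignment reaches the E-value cutoff
        for ref in refs:
            for strand in (ref.sequence, reverse_complement(ref.sequence)):
                s = oracle.score(strand, rep)
                assert evalue(int(s), len(rep), db_len, scheme) > 0.01
        known, unknown = match_repeats_to_reference([SequenceRecord("r1", rep)],
                                                    refs, max_evalue=0.01)
        assert known == []


class TestKarlinAltschul:
    def test_lambda_closed_form(self):
        # 0.25*e^lam + 0.75*e^-lam = 1 has the exact solution lam = ln 3
        lam, K, H = karlin_altschul_params(1, -1)
        assert lam == pytest.approx(math.log(3), rel=1e-9)
        assert 0 < K < 1
        assert H > 0

    def test_evalue_monotone_in_score(self):
        scheme = ScoringScheme()
        evs = [evalue(s, 30, 10000, scheme) for s in range(10, 31)]
        assert all(a > b for a, b in zip(evs, evs[1:]))
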
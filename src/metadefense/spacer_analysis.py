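"""Spacer catalogues, cross-sample sharing, and spacer->target search with
seeded local alignment and E-value filtering."""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .alignment import (LocalAlignment, ScoringScheme, evalue,
                        reverse_complement, seeded_local_align)
from .core_io import SequenceRecord
from .crispr_detect import CrisprArray

TARGET_CATEGORIES = ("phage", "virus", "plasmid")


@dataclass(frozen=True)
class SpacerHit:
    spacer_id: str
    target_id: str
    target_category: str
    score: int
    evalue: float
    spacer_start: int
    spacer_end: int
    target_start: int
    target_end: int
    strand: str


@dataclass
class SpacerCatalogue:
    """Distinct spacer sequences with occurrence counts and sources."""

    counts: Counter = field(default_factory=Counter)
    sources: Dict[str, List[str]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct(self) -> int:
        return len(self.counts)

    @property
    def singletons(self) -> int:
        return sum(1 for c in self.counts.values() if c == 1)

    @property
    def multi_occurring(self) -> int:
        return sum(1 for c in self.counts.values() if c > 1)

    def sequences(self) -> Set[str]:
        return set(self.counts)


def collect_spacers(arrays: Iterable[CrisprArray],
                    id_prefix: str = "") -> SpacerCatalogue:
    """Catalogue spacers by exact string identity across validated arrays."""
    cat = SpacerCatalogue()
    for ai, array in enumerate(arrays):
        if not array.validated:
            raise ValueError(
                f"unvalidated array on contig {array.contig_id!r} passed to collect_spacers")
        for si, (_, _, seq) in enumerate(array.spacers):
            cat.counts[seq] += 1
            label = f"{id_prefix}{array.contig_id}_arr{ai}_sp{si}"
            cat.sources.setdefault(seq, []).append(label)
    return cat


def collect_repeats(arrays: Iterable[CrisprArray]) -> Counter:
    """Consensus repeat sequences with array counts (one per array)."""
    counts: Counter = Counter()
    for array in arrays:
        counts[array.consensus_repeat] += 1
    return counts


def shared_sequences(cat_a: Set[str] | SpacerCatalogue,
                     cat_b: Set[str] | SpacerCatalogue,
                     reverse_complement_match: bool = False) -> List[str]:
    """Exact-match sequences present in both catalogues (each counted once)."""
    a = cat_a.sequences() if isinstance(cat_a, SpacerCatalogue) else set(cat_a)
    b = cat_b.sequences() if isinstance(cat_b, SpacerCatalogue) else set(cat_b)
    shared = a & b
    if reverse_complement_match:
        shared |= {s for s in a if reverse_complement(s) in b}
    return sorted(shared)


def search_targets(spacers: Sequence[SequenceRecord],
                   targets: Sequence[Tuple[SequenceRecord, str]],
                   scheme: Optional[ScoringScheme] = None) -> List[SpacerHit]:
    """Seeded local alignment of each spacer against each labelled target
    (both strands); the best hit per (spacer, target) is reported when its
    E-value is at most ``scheme.evalue_max``."""
    scheme = scheme or ScoringScheme()
    for rec, category in targets:
        if category not in TARGET_CATEGORIES:
            raise ValueError(
                f"target {rec.id!r} has invalid category {category!r}; "
                f"expected one of {TARGET_CATEGORIES}")
    db_len = sum(len(rec) for rec, _ in targets)
    hits: List[SpacerHit] = []
    for spacer in spacers:
        if len(spacer) < scheme.word_size:
            raise ValueError(
                f"spacer {spacer.id!r} shorter than word size {scheme.word_size}")
        for rec, category in targets:
            aln = seeded_local_align(spacer.sequence, rec.sequence, scheme)
            if aln is None:
                continue
            ev = evalue(aln.score, len(spacer), db_len, scheme)
            if ev <= scheme.evalue_max:
                hits.append(SpacerHit(
                    spacer_id=spacer.id, target_id=rec.id, target_category=category,
                    score=aln.score, evalue=ev,
                    spacer_start=aln.query_start, spacer_end=aln.query_end,
                    target_start=aln.target_start, target_end=aln.target_end,
                    strand=aln.strand))
    return hits


def categorize_targets(spacer_ids: Iterable[str],
                       hits: Iterable[SpacerHit]) -> Tuple[Dict[str, Set[str]], Counter]:
    """Per-spacer category sets and the per-category tallies.

    A spacer with no hit is "unknown"; a spacer hitting several categories is
    counted once in each category tally (tallies may exceed the number of
    spacers with a target)."""
    by_spacer: Dict[str, Set[str]] = {s: set() for s in spacer_ids}
    for h in hits:
        if h.spacer_id not in by_spacer:
            raise KeyError(f"hit for unknown spacer {h.spacer_id!r}")
        by_spacer[h.spacer_id].add(h.target_category)
    tallies: Counter = Counter()
    for sid, cats in by_spacer.items():
        if not cats:
            by_spacer[sid] = {"unknown"}
            tallies["unknown"] += 1
        else:
            for c in cats:
                tallies[c] += 1
    return by_spacer, tallies


def match_repeats_to_reference(repeats: Sequence[SequenceRecord],
                               reference: Sequence[SequenceRecord],
                               max_evalue: float = 0.01,
                               scheme: Optional[ScoringScheme] = None,
                               ) -> Tuple[List[str], List[str]]:
    """Partition repeat ids into (known, unknown) by seeded alignment against
    a user-supplied reference repeat FASTA at the given E-value cutoff."""
    scheme = scheme or ScoringScheme(evalue_max=max_evalue)
    known: List[str] = []
    unknown: List[str] = []
    if not reference:
        return [], [r.id for r in repeats]
    db_len = sum(len(r) for r in reference)
    for rep in repeats:
        matched = False
        for ref in reference:
            aln = seeded_local_align(rep.sequence, ref.sequence, scheme)
            if aln is not None and evalue(aln.score, len(rep), db_len, scheme) <= max_evalue:
                matched = True
                break
        (known if matched else unknown).append(rep.id)
    return known, unknown
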
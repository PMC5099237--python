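"""Repeat-spacer array detection and the multi-profile retention protocol.

One seed-and-extend detector is run under several parameter profiles
(default "strict" and "lenient"); an array is retained when found by at
least two profiles, or by one profile on a contig that carries cas genes.
Retained arrays must pass structural validation, including the hard
requirement of at least two spacers.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_left
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .core_io import SequenceRecord


@dataclass(frozen=True)
class DetectionParams:
    seed_k: int = 8
    repeat_len_min: int = 19
    repeat_len_max: int = 48
    spacer_len_min: int = 19
    spacer_len_max: int = 72
    max_repeat_divergence: float = 0.2
    max_spacer_pair_identity: float = 0.6
    min_spacers: int = 2

    def __post_init__(self) -> None:
        if self.repeat_len_min > self.repeat_len_max:
            raise ValueError("repeat_len_min > repeat_len_max")
        if self.spacer_len_min > self.spacer_len_max:
            raise ValueError("spacer_len_min > spacer_len_max")
        for frac in (self.max_repeat_divergence, self.max_spacer_pair_identity):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0,1]")
        if self.seed_k < 1 or self.min_spacers < 1:
            raise ValueError("seed_k and min_spacers must be >= 1")


Segment = Tuple[int, int, str]  # 1-based start, end, sequence


@dataclass(frozen=True)
class CrisprArray:
    contig_id: str
    start: int  # 1-based inclusive
    end: int
    repeats: Tuple[Segment, ...]
    spacers: Tuple[Segment, ...]
    consensus_repeat: str
    profiles_hit: frozenset = frozenset()
    cas_adjacent: bool = False
    validated: bool = False
    crispr_type: Optional[str] = None

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)

    def overlaps(self, other: "CrisprArray") -> bool:
        return (self.contig_id == other.contig_id
                and self.start <= other.end and other.start <= self.end)


def consensus_sequence(copies: Sequence[str]) -> str:
    """Per-column majority vote; ties broken alphabetically."""
    if not copies:
        raise ValueError("no copies to build a consensus from")
    length = len(copies[0])
    if any(len(c) != length for c in copies):
        raise ValueError("repeat copies differ in length")
    out = []
    for col in range(length):
        counts = Counter(c[col] for c in copies)
        top = max(counts.values())
        out.append(min(b for b, n in counts.items() if n == top))
    return "".join(out)


def sequence_identity(a: str, b: str) -> float:
    """Positionwise identity over the longer length (no gaps)."""
    if not a or not b:
        return 0.0
    matches = sum(x == y for x, y in zip(a, b))
    return matches / max(len(a), len(b))


def _kmer_positions(seq: str, k: int) -> Dict[str, List[int]]:
    index: Dict[str, List[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        word = seq[i:i + k]
        if "N" not in word:
            index[word].append(i)
    return index


def _next_occurrence(positions: List[int], lo: int, hi: int) -> Optional[int]:
    """Smallest position p with lo <= p <= hi, or None."""
    i = bisect_left(positions, lo)
    if i < len(positions) and positions[i] <= hi:
        return positions[i]
    return None


def find_candidate_arrays(contig: SequenceRecord,
                          params: DetectionParams) -> List[CrisprArray]:
    """Seed-and-extend scan for candidate repeat-spacer arrays (unvalidated).

    A candidate starts from an exact seed_k-mer recurring at a period
    compatible with one repeat plus one spacer; further copies are chained at
    the same word, then repeat boundaries are extended while *all* copies
    agree and the length constraints still hold.
    """
    seq = contig.sequence
    n = len(seq)
    p = params
    min_period = p.repeat_len_min + p.spacer_len_min
    max_period = p.repeat_len_max + p.spacer_len_max
    if n < 2 * p.repeat_len_min + p.spacer_len_min:
        return []
    index = _kmer_positions(seq, p.seed_k)
    candidates: List[CrisprArray] = []
    claimed_until = -1  # last claimed 0-based position
    i = 0
    while i <= n - p.seed_k:
        if i <= claimed_until:
            i = claimed_until + 1
            continue
        word = seq[i:i + p.seed_k]
        positions = index.get(word)
        if not positions:
            i += 1
            continue
        if _next_occurrence(positions, i + min_period, i + max_period) is None:
            i += 1
            continue
        # A seed straddling the flank/repeat boundary can truncate the chain,
        # so probe every start offset within one word and keep the candidate
        # with the most copies (ties: longest span).
        best: Optional[CrisprArray] = None
        for start in range(i, min(i + p.seed_k, n - p.seed_k + 1)):
            probe_positions = index.get(seq[start:start + p.seed_k])
            if not probe_positions:
                continue
            nxt = _next_occurrence(probe_positions, start + min_period,
                                   start + max_period)
            if nxt is None:
                continue
            copies = [start, nxt]
            while True:
                more = _next_occurrence(probe_positions, copies[-1] + min_period,
                                        copies[-1] + max_period)
                if more is None:
                    break
                copies.append(more)
            array = _extend_and_build(contig, seq, copies, p, claimed_until)
            if array is not None and (
                    best is None
                    or (array.n_repeats, array.end - array.start)
                    > (best.n_repeats, best.end - best.start)):
                best = array
        if best is not None:
            candidates.append(best)
            claimed_until = best.end - 1  # end is 1-based inclusive
            i = best.end
        else:
            i += 1
    return candidates


def _extend_and_build(contig: SequenceRecord, seq: str, copies: List[int],
                      p: DetectionParams, claimed_until: int
                      ) -> Optional[CrisprArray]:
    k = p.seed_k
    # extend left while every copy agrees, respecting bounds and spacer minimum
    left = 0
    while True:
        nxt = left + 1
        if copies[0] - nxt <= claimed_until:
            break
        if k + nxt > p.repeat_len_max:
            break
        if any((copies[j] - copies[j - 1]) - (k + nxt) < p.spacer_len_min
               for j in range(1, len(copies))):
            break
        col = {seq[c - nxt] for c in copies}
        if len(col) != 1 or "N" in col:
            break
        left = nxt
    right = 0
    while True:
        nxt = right + 1
        if copies[-1] + k - 1 + nxt >= len(seq):
            break
        if left + k + nxt > p.repeat_len_max:
            break
        if any((copies[j] - copies[j - 1]) - (left + k + nxt) < p.spacer_len_min
               for j in range(1, len(copies))):
            break
        col = {seq[c + k - 1 + nxt] for c in copies}
        if len(col) != 1 or "N" in col:
            break
        right = nxt
    rep_len = left + k + right
    if rep_len < p.repeat_len_min:
        return None
    starts = [c - left for c in copies]
    # drop trailing copies whose preceding spacer violates the length range
    while len(starts) >= 2:
        gap = starts[-1] - (starts[-2] + rep_len)
        if p.spacer_len_min <= gap <= p.spacer_len_max:
            break
        starts.pop()
    if len(starts) < 2:
        return None
    repeats: List[Segment] = []
    spacers: List[Segment] = []
    for idx, s in enumerate(starts):
        repeats.append((s + 1, s + rep_len, seq[s:s + rep_len]))
        if idx + 1 < len(starts):
            sp_start = s + rep_len
            sp_end = starts[idx + 1]
            spacers.append((sp_start + 1, sp_end, seq[sp_start:sp_end]))
    consensus = consensus_sequence([r[2] for r in repeats])
    return CrisprArray(
        contig_id=contig.id, start=repeats[0][0], end=repeats[-1][1],
        repeats=tuple(repeats), spacers=tuple(spacers),
        consensus_repeat=consensus)


def validate_array(array: CrisprArray, params: DetectionParams) -> CrisprArray:
    """Structural validation: spacer count, repeat homogeneity, spacer
    dissimilarity and length ranges.  Returns a copy with ``validated`` set."""
    p = params
    ok = array.n_spacers >= p.min_spacers
    if ok:
        consensus = array.consensus_repeat
        for _, _, rep in array.repeats:
            div = 1.0 - sequence_identity(rep, consensus)
            if div > p.max_repeat_divergence + 1e-12:
                ok = False
                break
    if ok:
        for (_, _, a), (_, _, b) in zip(array.spacers, array.spacers[1:]):
            if sequence_identity(a, b) > p.max_spacer_pair_identity + 1e-12:
                ok = False
                break
    if ok:
        if not all(p.repeat_len_min <= len(r[2]) <= p.repeat_len_max
                   for r in array.repeats):
            ok = False
        if not all(p.spacer_len_min <= len(s[2]) <= p.spacer_len_max
                   for s in array.spacers):
            ok = False
    return dataclasses.replace(array, validated=ok)


DEFAULT_PROFILES: Dict[str, DetectionParams] = {
    "strict": DetectionParams(seed_k=8, repeat_len_min=21, repeat_len_max=44,
                              spacer_len_min=20, spacer_len_max=64,
                              max_repeat_divergence=0.1,
                              max_spacer_pair_identity=0.6),
    "lenient": DetectionParams(),
}


def detect_consensus(contigs: Iterable[SequenceRecord],
                     profiles: Optional[Dict[str, DetectionParams]] = None,
                     cas_contig_ids: Optional[Set[str]] = None,
                     ) -> List[CrisprArray]:
    """Run every profile over every contig and apply the retention rule:
    found by >= 2 profiles, or by >= 1 profile on a cas-carrying contig.
    Overlapping detections are merged (union coordinates; the member with
    the most repeats provides repeats/spacers/consensus)."""
    if profiles is None:
        profiles = DEFAULT_PROFILES
    if len(profiles) < 1:
        raise ValueError("at least one detection profile is required")
    cas_contig_ids = cas_contig_ids or set()

    per_contig: Dict[str, List[CrisprArray]] = defaultdict(list)
    for contig in contigs:
        for name in sorted(profiles):
            params = profiles[name]
            for cand in find_candidate_arrays(contig, params):
                cand = validate_array(cand, params)
                if cand.validated:
                    per_contig[contig.id].append(
                        dataclasses.replace(cand, profiles_hit=frozenset([name])))

    retained: List[CrisprArray] = []
    for contig_id in sorted(per_contig):
        merged = _merge_overlapping(per_contig[contig_id])
        for arr in merged:
            if len(arr.profiles_hit) >= 2 or contig_id in cas_contig_ids:
                retained.append(arr)
    retained.sort(key=lambda a: (a.contig_id, a.start))
    return retained


def _merge_overlapping(arrays: List[CrisprArray]) -> List[CrisprArray]:
    arrays = sorted(arrays, key=lambda a: (a.start, a.end))
    groups: List[List[CrisprArray]] = []
    for arr in arrays:
        if groups and arr.start <= max(a.end for a in groups[-1]):
            groups[-1].append(arr)
        else:
            groups.append([arr])
    out = []
    for group in groups:
        rep = max(group, key=lambda a: (a.n_repeats, -a.start))
        out.append(dataclasses.replace(
            rep,
            start=min(a.start for a in group),
            end=max(a.end for a in group),
            profiles_hit=frozenset().union(*(a.profiles_hit for a in group)),
        ))
    return out


def arrays_to_table_rows(arrays: Iterable[CrisprArray]) -> List[dict]:
    return [
        {
            "contig_id": a.contig_id,
            "start": a.start,
            "end": a.end,
            "n_repeats": a.n_repeats,
            "n_spacers": a.n_spacers,
            "consensus_repeat": a.consensus_repeat,
            "profiles": ",".join(sorted(a.profiles_hit)),
            "validated": a.validated,
            "cas_adjacent": a.cas_adjacent,
            "crispr_type": a.crispr_type or "",
        }
        for a in arrays
    ]
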
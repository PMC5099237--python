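"""Seeded local alignment with affine gaps and Karlin-Altschul E-values.

Search is gated by exact shared words of ``word_size``: when query and target
(on a given strand) share no exact word, no alignment is attempted.  When a
seed exists, the extension is a full affine-gap Smith-Waterman, so the score
is exact whenever any seed exists — in particular whenever a seed lies on the
optimal local alignment path.

Gap cost convention: a gap of length L costs ``gap_open + L * gap_extend``
(the opening penalty is charged on top of the per-base extension for the
first gapped base).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

NEG_INF = -10 ** 9


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -5
    gap_extend: int = -2
    word_size: int = 7
    evalue_max: float = 0.1

    def __post_init__(self) -> None:
        if self.word_size < 1:
            raise ValueError("word_size must be >= 1")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("match must be positive and mismatch negative")


@dataclass(frozen=True)
class LocalAlignment:
    score: int
    query_start: int   # 1-based inclusive, on the query as given
    query_end: int
    target_start: int  # 1-based inclusive, on the forward target strand
    target_end: int
    strand: str        # strand of the target that was aligned: '+' or '-'


def words(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)} - _n_words(seq, k)


def _n_words(seq: str, k: int) -> set[str]:
    if "N" not in seq:
        return set()
    return {seq[i:i + k] for i in range(len(seq) - k + 1) if "N" in seq[i:i + k]}


def has_shared_word(query: str, target: str, k: int) -> bool:
    if len(query) < k or len(target) < k:
        return False
    qw = words(query, k)
    return any(target[i:i + k] in qw for i in range(len(target) - k + 1))


def _encode(seq: str) -> np.ndarray:
    # A,C,G,T -> 0..3 ; N -> 4 (never matches, including N vs N)
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def smith_waterman_score(query: str, target: str, scheme: ScoringScheme
                         ) -> Tuple[int, int, int]:
    """Best local score and its end cell (qi, tj), both 1-based.

    Row-vectorised Gotoh: the within-row gap recurrence
    E[j] = max_{k<j} D[k] + gap_open + (j-k)*gap_extend is solved with a
    prefix max over D[k] - k*gap_extend.
    """
    q = _encode(query)
    t = _encode(target)
    m, n = len(q), len(t)
    go, ge = scheme.gap_open, scheme.gap_extend
    subst = np.where(t[None, :] == np.arange(4)[:, None], scheme.match, scheme.mismatch)
    subst = np.vstack([subst, np.full((1, n), scheme.mismatch)])  # row for N

    H_prev = np.zeros(n + 1, dtype=np.int64)
    F_prev = np.full(n + 1, NEG_INF, dtype=np.int64)
    js = np.arange(n + 1, dtype=np.int64)
    best, best_i, best_j = 0, 0, 0
    for i in range(1, m + 1):
        F = np.maximum(H_prev + go + ge, F_prev + ge)
        D = np.maximum(F, 0)
        diag = H_prev[:-1] + subst[q[i - 1]]
        np.maximum(D[1:], diag, out=D[1:])
        D[0] = 0
        # E[j] = go + ge*j + max_{k<j}(D[k] - ge*k)
        running = np.maximum.accumulate(D - ge * js)
        H = D.copy()
        np.maximum(H[1:], go + ge * js[1:] + running[:-1], out=H[1:])
        H[0] = 0
        j = int(H.argmax())
        if H[j] > best:
            best, best_i, best_j = int(H[j]), i, j
        H_prev, F_prev = H, F
    return best, best_i, best_j


def smith_waterman_traceback(query: str, target: str, scheme: ScoringScheme
                             ) -> Optional[LocalAlignment]:
    """Full Gotoh with traceback on (query x target); '+' strand coordinates."""
    score, qi, tj = smith_waterman_score(query, target, scheme)
    if score <= 0:
        return None
    # Re-run a pointered DP on the prefix rectangle ending at the best cell.
    # The rectangle is small (query is short), so plain Python is fine.
    go, ge = scheme.gap_open, scheme.gap_extend
    j_lo = max(0, tj - (qi * max(scheme.match, 1) - scheme.gap_open) - qi - 1)
    q = query[:qi]
    t = target[j_lo:tj]
    m, n = len(q), len(t)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG_INF, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG_INF, dtype=np.int64)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] + go + ge, E[i, j - 1] + ge)
            F[i, j] = max(H[i - 1, j] + go + ge, F[i - 1, j] + ge)
            s = scheme.match if (q[i - 1] == t[j - 1] and q[i - 1] != "N") else scheme.mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
    i, j = m, n
    assert H[i, j] == score, "traceback rectangle missed the optimum"
    state = "H"
    while i > 0 and j > 0 and H[i, j] > 0:
        if state == "H":
            s = scheme.match if (q[i - 1] == t[j - 1] and q[i - 1] != "N") else scheme.mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                break  # H[i,j] == 0: local start
        elif state == "E":
            if E[i, j] == H[i, j - 1] + go + ge:
                j -= 1
                state = "H"
            else:
                j -= 1
        else:  # F
            if F[i, j] == H[i - 1, j] + go + ge:
                i -= 1
                state = "H"
            else:
                i -= 1
    return LocalAlignment(score=score, query_start=i + 1, query_end=qi,
                          target_start=j_lo + j + 1, target_end=tj, strand="+")


def seeded_local_align(query: str, target: str, scheme: ScoringScheme,
                       both_strands: bool = True) -> Optional[LocalAlignment]:
    """Best seeded local alignment of query against target (optionally both strands)."""
    best: Optional[LocalAlignment] = None
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        t = target if strand == "+" else reverse_complement(target)
        if not has_shared_word(query, t, scheme.word_size):
            continue
        aln = smith_waterman_traceback(query, t, scheme)
        if aln is None:
            continue
        if strand == "-":
            n = len(target)
            aln = LocalAlignment(
                score=aln.score, query_start=aln.query_start, query_end=aln.query_end,
                target_start=n - aln.target_end + 1, target_end=n - aln.target_start + 1,
                strand="-")
        if best is None or aln.score > best.score:
            best = aln
    return best


@lru_cache(maxsize=None)
def karlin_altschul_params(match: int = 1, mismatch: int = -1,
                           p_match: float = 0.25) -> Tuple[float, float, float]:
    """(lambda, K, H) for an ungapped two-valued scheme, uniform composition.

    lambda solves E[exp(lambda * S)] = 1 for a single aligned pair.  K uses
    the classical random-walk expression
        K = delta * lambda * exp(-2*sigma) / (H * (1 - exp(-delta*lambda)))
    with sigma summed numerically over partial-sum distributions (binomial
    here).  Gapped parameters are approximated by the ungapped pair; E-values
    are therefore approximate, which is acceptable because hit *scores* are
    exact and thresholds are configurable.
    """
    p_mis = 1.0 - p_match

    def moment(lam: float) -> float:
        return p_match * math.exp(lam * match) + p_mis * math.exp(lam * mismatch) - 1.0

    lam = brentq(moment, 1e-9, 20.0)
    H = lam * (p_match * match * math.exp(lam * match)
               + p_mis * mismatch * math.exp(lam * mismatch))
    # score lattice step
    delta = math.gcd(abs(match), abs(mismatch))
    sigma = 0.0
    for j in range(1, 200):
        # S_j = match*X + mismatch*(j-X), X ~ Binom(j, p_match)
        x = np.arange(j + 1)
        s = match * x + mismatch * (j - x)
        pmf = binom.pmf(x, j, p_match)
        neg = s < 0
        sigma += (float(np.sum(pmf[neg] * np.exp(lam * s[neg])))
                  + float(np.sum(pmf[~neg]))) / j
    K = delta * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-delta * lam)))
    return lam, K, H


def evalue(score: int, query_len: int, db_len: int, scheme: ScoringScheme) -> float:
    lam, K, _ = karlin_altschul_params(scheme.match, scheme.mismatch)
    return K * query_len * db_len * math.exp(-lam * score)
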
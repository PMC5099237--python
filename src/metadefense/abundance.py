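"""Coverage and cpm normalization, feature aggregation, enrichment calls,
community profiles with LCA taxonomy, Bray-Curtis + complete linkage,
GC distributions, and the summary-statistic arithmetic used in reports.

cpm = (mean per-position contig coverage) / (total mapped basepairs) * 1e6;
summed over all contigs weighted by contig length this is exactly 1e6 when
depth and the total come from the same mapping.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import braycurtis as _braycurtis, squareform
from scipy.stats import pearsonr

from .core_io import AlignmentHit, DepthTable, SequenceRecord, Taxonomy


@dataclass(frozen=True)
class FeatureAbundance:
    feature_id: str
    sample_id: str
    raw_count: int
    cpm: float

    def __post_init__(self) -> None:
        if self.raw_count < 0 or self.cpm < 0:
            raise ValueError(f"negative abundance for feature {self.feature_id!r}")


@dataclass(frozen=True)
class EnrichmentCall:
    feature_id: str
    mean_sponge_cpm: float
    seawater_cpm: float
    flag: str  # sponge | seawater | none


def contig_coverage(depths: np.ndarray) -> float:
    """Mean depth over every position of the contig, zeros included."""
    arr = np.asarray(depths)
    if arr.size == 0:
        raise ValueError("empty depth vector")
    return float(arr.mean())


def cpm(coverage: float, total_mapped_bp: int) -> float:
    if total_mapped_bp <= 0:
        raise ValueError("total_mapped_bp must be positive")
    return coverage / total_mapped_bp * 1e6


def contig_cpm_table(depth_table: DepthTable,
                     total_mapped_bp: Optional[int] = None) -> Dict[str, float]:
    """Per-contig cpm; defaults to the table's own total mapped basepairs."""
    if total_mapped_bp is None:
        total_mapped_bp = depth_table.total_depth()
    return {contig: cpm(contig_coverage(vec), total_mapped_bp)
            for contig, vec in depth_table.items()}


def aggregate_feature_cpm(instances: Iterable[Tuple[str, str]],
                          contig_cpm: Mapping[str, float],
                          sample_id: str) -> List[FeatureAbundance]:
    """Sum the host contig's cpm over each feature instance.

    ``instances`` is an iterable of (feature_id, contig_id) pairs, one per
    feature occurrence."""
    sums: Dict[str, float] = defaultdict(float)
    counts: Counter = Counter()
    for feature_id, contig_id in instances:
        if contig_id not in contig_cpm:
            raise KeyError(
                f"feature {feature_id!r} sits on unknown contig {contig_id!r}")
        sums[feature_id] += contig_cpm[contig_id]
        counts[feature_id] += 1
    return [FeatureAbundance(f, sample_id, counts[f], sums[f])
            for f in sorted(sums)]


def enrichment_call(feature_id: str,
                    sponge_cpms: Sequence[float],
                    seawater_cpm: float,
                    factor: float = 1.5) -> EnrichmentCall:
    """Flag a feature as sponge- or seawater-enriched when one side exceeds
    ``factor`` times the other (mean over sponge samples vs the seawater
    value); a zero denominator with a positive numerator counts as enriched."""
    if len(sponge_cpms) < 1:
        raise ValueError("at least one sponge sample required")
    mean_sponge = float(np.mean(sponge_cpms))
    if mean_sponge == 0.0 and seawater_cpm == 0.0:
        flag = "none"
    elif seawater_cpm == 0.0:
        flag = "sponge"
    elif mean_sponge == 0.0:
        flag = "seawater"
    elif mean_sponge > factor * seawater_cpm:
        flag = "sponge"
    elif seawater_cpm > factor * mean_sponge:
        flag = "seawater"
    else:
        flag = "none"
    return EnrichmentCall(feature_id, mean_sponge, seawater_cpm, flag)


def bray_curtis(profile_a: Mapping[str, float],
                profile_b: Mapping[str, float]) -> float:
    """1 - 2*sum(min)/(sum(a)+sum(b)) over the union of taxa (missing = 0)."""
    taxa = sorted(set(profile_a) | set(profile_b))
    a = np.array([profile_a.get(t, 0.0) for t in taxa])
    b = np.array([profile_b.get(t, 0.0) for t in taxa])
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("Bray-Curtis is undefined for two all-zero profiles")
    return float(_braycurtis(a, b))


def dissimilarity_matrix(profiles: Mapping[str, Mapping[str, float]]
                         ) -> Tuple[List[str], np.ndarray]:
    samples = sorted(profiles)
    n = len(samples)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = bray_curtis(profiles[samples[i]], profiles[samples[j]])
            mat[i, j] = mat[j, i] = d
    return samples, mat


def complete_linkage(dist: np.ndarray, labels: Sequence[str]) -> str:
    """Agglomerative max-linkage clustering; returns a Newick string with
    merge heights as branch lengths."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if dist.shape[0] == 1:
        return f"{labels[0]};"
    Z = linkage(squareform(dist, checks=False), method="complete")
    return _linkage_to_newick(Z, list(labels))


def _linkage_to_newick(Z: np.ndarray, labels: List[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes: Dict[int, str] = {i: labels[i] for i in range(n)}
    min_leaf: Dict[int, str] = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        # deterministic child order: smallest leaf label first
        if min_leaf[b] < min_leaf[a]:
            a, b = b, a
        la = max(0.0, h - heights[a])
        lb = max(0.0, h - heights[b])
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = float(h)
        min_leaf[n + k] = min(min_leaf[a], min_leaf[b])
    return nodes[n + len(Z) - 1] + ";"


def lca_assign(hits: Sequence[AlignmentHit], taxonomy: Taxonomy,
               top_score_fraction: float = 0.1,
               min_hits: int = 1) -> Optional[int]:
    """Lowest common ancestor of the taxa of hits scoring within
    ``top_score_fraction`` of the best bit score; None when fewer than
    ``min_hits`` hits are available."""
    if len(hits) < min_hits or not hits:
        return None
    best = max(h.bit_score for h in hits)
    retained = [h for h in hits if h.bit_score >= (1.0 - top_score_fraction) * best]
    lineages = [taxonomy.lineage(h.subject_taxid) for h in retained]
    lca = taxonomy.root
    for level in zip(*lineages):
        if len(set(level)) == 1:
            lca = level[0]
        else:
            break
    return lca


def assign_queries(hits: Sequence[AlignmentHit], taxonomy: Taxonomy,
                   top_score_fraction: float = 0.1) -> Dict[str, Optional[int]]:
    by_query: Dict[str, List[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_query[h.query_id].append(h)
    return {q: lca_assign(by_query[q], taxonomy, top_score_fraction)
            for q in sorted(by_query)}


def community_profile(assignments: Mapping[str, Optional[int]],
                      taxonomy: Taxonomy, rank: str = "phylum",
                      weights: Optional[Mapping[str, float]] = None
                      ) -> Dict[str, float]:
    """Relative abundance over taxa at ``rank``; queries without an ancestor
    at that rank (or unassigned) fall into "other".  Sums to 1."""
    tallies: Dict[str, float] = defaultdict(float)
    total = 0.0
    for query, taxid in assignments.items():
        w = 1.0 if weights is None else float(weights[query])
        total += w
        if taxid is None:
            tallies["other"] += w
            continue
        at_rank = taxonomy.ancestor_at_rank(taxid, rank)
        tallies[taxonomy.name(at_rank) if at_rank is not None else "other"] += w
    if total == 0:
        raise ValueError("no queries to profile")
    return {t: v / total for t, v in sorted(tallies.items())}


def gc_distribution(records: Iterable[SequenceRecord],
                    bin_width: float = 0.01
                    ) -> Tuple[Dict[str, float], np.ndarray, np.ndarray]:
    """Per-record GC fraction (N excluded from numerator and denominator)
    plus a binned density histogram over [0, 1]."""
    per_record = {r.id: r.gc_fraction for r in records}
    values = np.array(list(per_record.values()))
    nbins = int(round(1.0 / bin_width))
    density, edges = np.histogram(values, bins=nbins, range=(0.0, 1.0), density=True)
    return per_record, density, edges


def percentage(numerator: int, denominator: int) -> float:
    """100*num/den, rounded half-up to two decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def ratio_2dp(numerator: int | float, denominator: int | float) -> float:
    """Plain quotient rounded half-up to two decimals (e.g. mean fold
    coverage = mapped basepairs / assembly size)."""
    if denominator == 0:
        raise ZeroDivisionError("ratio with zero denominator")
    value = Decimal(str(numerator)) / Decimal(str(denominator))
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def pearson_correlation(a: Sequence[float], b: Sequence[float]
                        ) -> Tuple[float, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("zero variance")
    r, p = pearsonr(a, b)
    return float(r), float(p)
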
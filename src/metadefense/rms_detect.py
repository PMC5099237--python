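"""Restriction-modification system calling: coverage filter, completeness
pairing (REase + MTase of the same type within a gene-distance window) and
merging into non-redundant clusters."""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .core_io import DomainHit, GeneRecord

RMS_TYPES = ("I", "II", "III")


@dataclass(frozen=True)
class RmsGene:
    gene_id: str
    contig_id: str
    index_on_contig: int
    role: str                       # best e-value role: REase | MTase | Specificity
    rms_type: str                   # I | II | III
    query_coverage: float
    evalue: float
    all_roles: frozenset = frozenset()  # every role with a qualifying hit

    def __post_init__(self) -> None:
        if self.role == "Specificity" and self.rms_type != "I":
            raise ValueError(
                f"gene {self.gene_id!r}: Specificity role is only valid for type I")


@dataclass(frozen=True)
class RmsSystem:
    contig_id: str
    rms_type: str
    gene_ids: Tuple[str, ...]
    index_start: int
    index_end: int
    complete: bool
    specificity_gene: Optional[str] = None


@dataclass(frozen=True)
class RmsCluster:
    contig_id: str
    rms_type: str
    gene_ids: Tuple[str, ...]
    index_start: int
    index_end: int
    n_systems: int


def filter_rms_hits(hits: Iterable[DomainHit],
                    gene_records: Iterable[GeneRecord],
                    min_coverage: float = 0.70) -> List[RmsGene]:
    """Keep REBASE-role hits with query coverage >= min_coverage (inclusive);
    per gene and type the best e-value hit defines the role.  All qualifying
    roles are retained in ``all_roles`` so that fused REase+MTase genes can
    be recognised downstream."""
    genes = {g.gene_id: g for g in gene_records}
    grouped: Dict[Tuple[str, str], List[DomainHit]] = defaultdict(list)
    for h in hits:
        if h.role is None or h.rms_type is None:
            continue
        if h.query_coverage >= min_coverage:
            grouped[(h.gene_id, h.rms_type)].append(h)
    out: List[RmsGene] = []
    for (gene_id, rms_type) in sorted(grouped):
        if gene_id not in genes:
            raise KeyError(f"RMS hit for gene {gene_id!r} absent from gene table")
        ranked = sorted(grouped[(gene_id, rms_type)],
                        key=lambda h: (h.evalue, h.role))
        best = ranked[0]
        rec = genes[gene_id]
        out.append(RmsGene(
            gene_id=gene_id, contig_id=rec.contig_id,
            index_on_contig=rec.index_on_contig,
            role=best.role, rms_type=rms_type,
            query_coverage=best.query_coverage, evalue=best.evalue,
            all_roles=frozenset(h.role for h in ranked)))
    return out


def pair_complete_systems(genes: Sequence[RmsGene],
                          max_gene_distance: int = 4) -> List[RmsSystem]:
    """A complete system is an REase and an MTase of the same type at most
    ``max_gene_distance`` gene ordinals apart; each REase pairs with its
    nearest qualifying MTase (leftmost on tie).  A single gene with both
    qualifying roles is a complete fused system of span 0.  Type I systems
    record a Specificity gene inside the pair window when present."""
    systems: List[RmsSystem] = []
    by_group: Dict[Tuple[str, str], List[RmsGene]] = defaultdict(list)
    for g in genes:
        by_group[(g.contig_id, g.rms_type)].append(g)
    for (contig_id, rms_type) in sorted(by_group):
        members = sorted(by_group[(contig_id, rms_type)],
                         key=lambda g: g.index_on_contig)
        reases = [g for g in members
                  if g.role == "REase" or "REase" in g.all_roles]
        mtases = [g for g in members
                  if g.role == "MTase" or "MTase" in g.all_roles]
        specs = [g for g in members
                 if g.role == "Specificity" or "Specificity" in g.all_roles]
        for re_gene in reases:
            if "MTase" in re_gene.all_roles and "REase" in re_gene.all_roles:
                systems.append(_make_system(contig_id, rms_type,
                                            [re_gene], specs, max_gene_distance))
                continue
            candidates = [m for m in mtases if m.gene_id != re_gene.gene_id
                          and abs(m.index_on_contig - re_gene.index_on_contig)
                          <= max_gene_distance]
            if not candidates:
                continue
            nearest = min(candidates,
                          key=lambda m: (abs(m.index_on_contig - re_gene.index_on_contig),
                                         m.index_on_contig))
            systems.append(_make_system(contig_id, rms_type,
                                        [re_gene, nearest], specs, max_gene_distance))
    return systems


def _make_system(contig_id: str, rms_type: str, members: List[RmsGene],
                 specs: List[RmsGene], max_gene_distance: int) -> RmsSystem:
    lo = min(g.index_on_contig for g in members)
    hi = max(g.index_on_contig for g in members)
    spec_gene = None
    if rms_type == "I":
        in_window = [s for s in specs
                     if lo - max_gene_distance <= s.index_on_contig <= hi + max_gene_distance
                     and s.gene_id not in {g.gene_id for g in members}]
        if in_window:
            spec_gene = min(in_window, key=lambda s: s.index_on_contig).gene_id
            members = members + [g for g in specs if g.gene_id == spec_gene]
            lo = min(g.index_on_contig for g in members)
            hi = max(g.index_on_contig for g in members)
    return RmsSystem(contig_id=contig_id, rms_type=rms_type,
                     gene_ids=tuple(sorted({g.gene_id for g in members})),
                     index_start=lo, index_end=hi, complete=True,
                     specificity_gene=spec_gene)


def merge_into_clusters(systems: Iterable[RmsSystem],
                        window: int = 4) -> List[RmsCluster]:
    """Transitively merge same-type systems on one contig whose index spans
    overlap or lie within ``window`` gene ordinals; the cluster count is the
    reported RMS count."""
    by_group: Dict[Tuple[str, str], List[RmsSystem]] = defaultdict(list)
    for s in systems:
        by_group[(s.contig_id, s.rms_type)].append(s)
    clusters: List[RmsCluster] = []
    for (contig_id, rms_type) in sorted(by_group):
        spans = sorted(by_group[(contig_id, rms_type)],
                       key=lambda s: (s.index_start, s.index_end))
        current: List[RmsSystem] = [spans[0]]
        cur_end = spans[0].index_end
        for s in spans[1:]:
            if s.index_start - cur_end <= window:
                current.append(s)
                cur_end = max(cur_end, s.index_end)
            else:
                clusters.append(_make_cluster(contig_id, rms_type, current))
                current = [s]
                cur_end = s.index_end
        clusters.append(_make_cluster(contig_id, rms_type, current))
    return clusters


def _make_cluster(contig_id: str, rms_type: str,
                  members: List[RmsSystem]) -> RmsCluster:
    gene_ids = sorted({gid for s in members for gid in s.gene_ids})
    return RmsCluster(
        contig_id=contig_id, rms_type=rms_type, gene_ids=tuple(gene_ids),
        index_start=min(s.index_start for s in members),
        index_end=max(s.index_end for s in members),
        n_systems=len(members))


def call_rms(hits: Iterable[DomainHit], gene_records: Iterable[GeneRecord],
             min_coverage: float = 0.70, max_gene_distance: int = 4,
             cluster_window: int = 4) -> List[RmsCluster]:
    """End-to-end RMS calling: filter, pair, merge."""
    gene_records = list(gene_records)
    genes = filter_rms_hits(hits, gene_records, min_coverage=min_coverage)
    systems = pair_complete_systems(genes, max_gene_distance=max_gene_distance)
    return merge_into_clusters(systems, window=cluster_window)


def clusters_to_table_rows(clusters: Iterable[RmsCluster]) -> List[dict]:
    return [
        {
            "contig_id": c.contig_id,
            "rms_type": c.rms_type,
            "index_start": c.index_start,
            "index_end": c.index_end,
            "n_systems": c.n_systems,
            "genes": ",".join(c.gene_ids),
        }
        for c in clusters
    ]
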
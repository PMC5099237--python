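"""cas gene identification from domain hits, type/subtype assignment, and
array-to-locus adjacency.

The accession->cas-name mapping and the subtype signature table ship as
editable TSV config files (``metadefense/data/cas_mapping.tsv`` and
``cas_subtypes.tsv``); the code only interprets them.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .core_io import DomainHit, GeneRecord
from .crispr_detect import CrisprArray

# signature gene -> CRISPR-Cas type
TYPE_SIGNATURES = {"cas3": "I", "cas9": "II", "cas10": "III"}


@dataclass(frozen=True)
class CasGene:
    gene_id: str
    cas_name: str
    accessions: Tuple[str, ...]
    best_evalue: float


@dataclass(frozen=True)
class CasLocus:
    contig_id: str
    index_start: int
    index_end: int
    genes: Tuple[CasGene, ...]
    assigned_type: str = "unknown"   # I | II | III | unknown
    subtype: Optional[str] = None


def load_cas_mapping(path: Optional[str] = None) -> Dict[str, str]:
    """accession -> cas name; defaults to the table shipped with the package."""
    if path is None:
        source = resources.files("metadefense.data").joinpath("cas_mapping.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["accession"], df["cas_name"]))


def load_subtype_signatures(path: Optional[str] = None) -> Dict[str, str]:
    """accession -> subtype label (e.g. I-E); shipped table by default."""
    if path is None:
        source = resources.files("metadefense.data").joinpath("cas_subtypes.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["accession"], df["subtype"]))


def identify_cas_genes(hits: Iterable[DomainHit],
                       mapping: Mapping[str, str]) -> List[CasGene]:
    """A gene is a cas gene iff any of its hit accessions is in the mapping;
    the hit with the best (lowest) e-value names it."""
    if not mapping:
        raise ValueError("cas accession mapping is empty")
    by_gene: Dict[str, List[DomainHit]] = defaultdict(list)
    for h in hits:
        if h.accession in mapping:
            by_gene[h.gene_id].append(h)
    out = []
    for gene_id in sorted(by_gene):
        gene_hits = sorted(by_gene[gene_id], key=lambda h: (h.evalue, h.accession))
        best = gene_hits[0]
        out.append(CasGene(
            gene_id=gene_id,
            cas_name=mapping[best.accession],
            accessions=tuple(dict.fromkeys(h.accession for h in gene_hits)),
            best_evalue=best.evalue,
        ))
    return out


def assign_cas_type(genes: Sequence[CasGene],
                    subtype_signatures: Optional[Mapping[str, str]] = None,
                    ) -> Tuple[str, Optional[str]]:
    """Type from signature genes (cas3 -> I, cas9 -> II, cas10 -> III);
    conflicting or absent signatures give "unknown".  A subtype is assigned
    only when exactly one configured subtype accession is present and it is
    consistent with the assigned type."""
    if not genes:
        raise ValueError("cannot type an empty locus")
    present_types = {TYPE_SIGNATURES[g.cas_name]
                     for g in genes if g.cas_name in TYPE_SIGNATURES}
    if len(present_types) != 1:
        return "unknown", None
    assigned = present_types.pop()
    subtype = None
    if subtype_signatures:
        found = {subtype_signatures[a]
                 for g in genes for a in g.accessions if a in subtype_signatures}
        consistent = {s for s in found if s.split("-")[0] == assigned}
        if len(consistent) == 1:
            subtype = consistent.pop()
    return assigned, subtype


def group_cas_loci(cas_genes: Iterable[CasGene],
                   gene_records: Iterable[GeneRecord],
                   max_gene_gap: int = 5,
                   subtype_signatures: Optional[Mapping[str, str]] = None,
                   ) -> List[CasLocus]:
    """Cluster cas genes on one contig into loci when consecutive cas genes
    are at most ``max_gene_gap`` gene ordinals apart, then type each locus."""
    index_of: Dict[str, GeneRecord] = {g.gene_id: g for g in gene_records}
    per_contig: Dict[str, List[Tuple[int, CasGene]]] = defaultdict(list)
    for cg in cas_genes:
        if cg.gene_id not in index_of:
            raise KeyError(f"cas gene {cg.gene_id!r} absent from the gene table")
        rec = index_of[cg.gene_id]
        per_contig[rec.contig_id].append((rec.index_on_contig, cg))
    loci: List[CasLocus] = []
    for contig_id in sorted(per_contig):
        members = sorted(per_contig[contig_id], key=lambda t: t[0])
        cluster: List[Tuple[int, CasGene]] = [members[0]]
        for item in members[1:]:
            if item[0] - cluster[-1][0] <= max_gene_gap:
                cluster.append(item)
            else:
                loci.append(_build_locus(contig_id, cluster, subtype_signatures))
                cluster = [item]
        loci.append(_build_locus(contig_id, cluster, subtype_signatures))
    return loci


def _build_locus(contig_id: str, cluster: List[Tuple[int, "CasGene"]],
                 subtype_signatures: Optional[Mapping[str, str]]) -> CasLocus:
    genes = tuple(cg for _, cg in cluster)
    assigned, subtype = assign_cas_type(genes, subtype_signatures)
    return CasLocus(contig_id=contig_id,
                    index_start=cluster[0][0], index_end=cluster[-1][0],
                    genes=genes, assigned_type=assigned, subtype=subtype)


def link_arrays_to_cas(arrays: Iterable[CrisprArray],
                       loci: Sequence[CasLocus],
                       gene_records: Iterable[GeneRecord],
                       max_gene_gap: int = 5) -> List[CrisprArray]:
    """Set ``cas_adjacent`` (and the locus type) on each array when a cas
    locus lies within ``max_gene_gap`` gene ordinals of the genes flanking
    the array."""
    genes_by_contig: Dict[str, List[GeneRecord]] = defaultdict(list)
    for g in gene_records:
        genes_by_contig[g.contig_id].append(g)
    for gs in genes_by_contig.values():
        gs.sort(key=lambda g: g.index_on_contig)
    loci_by_contig: Dict[str, List[CasLocus]] = defaultdict(list)
    for locus in loci:
        loci_by_contig[locus.contig_id].append(locus)

    out: List[CrisprArray] = []
    for array in arrays:
        adjacent = False
        linked_type: Optional[str] = None
        contig_loci = loci_by_contig.get(array.contig_id, [])
        if contig_loci:
            lo, hi = _flanking_index_interval(
                genes_by_contig.get(array.contig_id, []), array)
            best_gap = None
            for locus in contig_loci:
                gap = _interval_gap(lo, hi, locus.index_start, locus.index_end)
                if gap <= max_gene_gap and (best_gap is None or gap < best_gap):
                    best_gap = gap
                    adjacent = True
                    linked_type = locus.assigned_type
        out.append(dataclasses.replace(array, cas_adjacent=adjacent,
                                       crispr_type=linked_type if adjacent else array.crispr_type))
    return out


def _flanking_index_interval(genes: List[GeneRecord],
                             array: CrisprArray) -> Tuple[int, int]:
    """Gene-ordinal interval spanned by the array: from the last gene ending
    before it to the first gene starting after it (inclusive of overlaps)."""
    if not genes:
        return (0, 0)
    lo = None
    hi = None
    for g in genes:
        if g.end < array.start:
            lo = g.index_on_contig
        if hi is None and g.start > array.end:
            hi = g.index_on_contig
        if g.start <= array.end and g.end >= array.start:  # overlapping gene
            lo = g.index_on_contig if lo is None else min(lo, g.index_on_contig)
            hi = g.index_on_contig if hi is None else max(hi, g.index_on_contig)
    if lo is None:
        lo = genes[0].index_on_contig
    if hi is None:
        hi = genes[-1].index_on_contig
    return (min(lo, hi), max(lo, hi))


def _interval_gap(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> int:
    if b_lo > a_hi:
        return b_lo - a_hi
    if a_lo > b_hi:
        return a_lo - b_hi
    return 0
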
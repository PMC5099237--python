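"""Readers/writers for external formats and the shared sequence/annotation data model.

All on-disk coordinates are 1-based inclusive (samtools/GFF convention).
Sequences are uppercased on read; only the alphabet {A,C,G,T,N} is accepted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_BASES = frozenset("ACGTN")

GENE_TABLE_COLUMNS = ["gene_id", "contig_id", "index", "start", "end", "strand"]
DOMAIN_HIT_COLUMNS = [
    "gene_id", "accession", "source_db", "evalue", "query_coverage", "role", "rms_type",
]
BLAST_TABULAR_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length", "mismatches",
    "gap_openings", "q_start", "q_end", "s_start", "s_end", "evalue", "bit_score",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (contig, spacer, repeat, read...)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record with empty id")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc_fraction(self) -> float:
        """GC over unambiguous bases; N excluded from numerator and denominator."""
        seq = self.sequence
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt == 0:
            raise ValueError(f"record {self.id!r} has no unambiguous bases")
        return (seq.count("G") + seq.count("C")) / acgt


def _check_sequence(rec_id: str, seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(
            f"record {rec_id!r} contains invalid characters: {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | os.PathLike) -> List[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, enforcing unique ids and ACGTN."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: List[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _check_sequence(rec.id, str(rec.seq))
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, sequence=seq, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


def filter_contigs(records: List[SequenceRecord], min_len: int = 1000) -> List[SequenceRecord]:
    """Keep contigs of length >= min_len (inclusive boundary; see README)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [r for r in records if len(r) >= min_len]


class DepthTable:
    """Per-contig vectors of per-position read depth (position 1 = index 0)."""

    def __init__(self, depths: Mapping[str, np.ndarray]):
        self._depths: Dict[str, np.ndarray] = {}
        for contig, vec in depths.items():
            arr = np.asarray(vec, dtype=np.int64)
            if arr.ndim != 1:
                raise ValueError(f"depth vector for {contig!r} is not 1-D")
            if (arr < 0).any():
                raise ValueError(f"negative depth for contig {contig!r}")
            self._depths[contig] = arr

    def __contains__(self, contig: str) -> bool:
        return contig in self._depths

    def __getitem__(self, contig: str) -> np.ndarray:
        return self._depths[contig]

    @property
    def contigs(self) -> List[str]:
        return list(self._depths)

    def total_depth(self) -> int:
        """Sum of all per-position depths == total mapped basepairs."""
        return int(sum(int(v.sum()) for v in self._depths.values()))

    def items(self):
        return self._depths.items()


def read_depth_table(path: str | os.PathLike,
                     contig_lengths: Mapping[str, int]) -> DepthTable:
    """Read a samtools-depth style TSV (contig, 1-based position, depth).

    Positions absent from the file are filled with depth 0; every contig in
    ``contig_lengths`` gets a vector of exactly its length.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"depth table not found: {path}")
    vectors = {c: np.zeros(int(n), dtype=np.int64) for c, n in contig_lengths.items()}
    if os.path.getsize(path) > 0:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["contig", "pos", "depth"],
                         dtype={"contig": str})
        for col in ("pos", "depth"):
            vals = df[col]
            if not np.issubdtype(vals.dtype, np.integer):
                raise ValueError(f"non-integer values in depth table column {col!r}")
        if (df["pos"] <= 0).any():
            raise ValueError("depth table contains a position <= 0 (positions are 1-based)")
        if (df["depth"] < 0).any():
            raise ValueError("depth table contains a negative depth")
        for contig, sub in df.groupby("contig", sort=False):
            if contig not in vectors:
                raise KeyError(f"depth table references unknown contig {contig!r}")
            pos = sub["pos"].to_numpy()
            if (pos > len(vectors[contig])).any():
                raise ValueError(
                    f"position beyond length of contig {contig!r} in depth table")
            vectors[contig][pos - 1] = sub["depth"].to_numpy()
    return DepthTable(vectors)


def write_depth_table(table: DepthTable, path: str | os.PathLike,
                      omit_zeros: bool = True) -> None:
    with open(path, "w") as fh:
        for contig, vec in table.items():
            for i, d in enumerate(vec, start=1):
                if omit_zeros and d == 0:
                    continue
                fh.write(f"{contig}\t{i}\t{int(d)}\n")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    contig_id: str
    index_on_contig: int
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id!r}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")


def read_gene_table(path: str | os.PathLike) -> List[GeneRecord]:
    """Read a gene coordinate TSV; validates consecutive 0-based indices per contig."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig_id": str})
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table {path} missing columns: {sorted(missing)}")
    genes = [
        GeneRecord(row.gene_id, row.contig_id, int(row.index),
                   int(row.start), int(row.end), row.strand)
        for row in df.itertuples()
    ]
    by_contig: Dict[str, List[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    for contig, gs in by_contig.items():
        gs_sorted = sorted(gs, key=lambda g: g.start)
        if [g.index_on_contig for g in gs_sorted] != list(range(len(gs_sorted))):
            raise ValueError(
                f"gene indices on contig {contig!r} are not consecutive from 0 "
                "in coordinate order")
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | os.PathLike) -> None:
    rows = [
        (g.gene_id, g.contig_id, g.index_on_contig, g.start, g.end, g.strand)
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DomainHit:
    """A gene-level annotation hit (COG/Pfam/TIGRFAM accession or REBASE role)."""

    gene_id: str
    accession: str
    source_db: str
    evalue: float
    query_coverage: float
    role: Optional[str] = None       # REase | MTase | Specificity
    rms_type: Optional[str] = None   # I | II | III

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit on {self.gene_id!r}: negative e-value")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError(f"hit on {self.gene_id!r}: query_coverage outside [0,1]")
        if self.role is not None and self.role not in ("REase", "MTase", "Specificity"):
            raise ValueError(f"hit on {self.gene_id!r}: invalid role {self.role!r}")
        if self.rms_type is not None and self.rms_type not in ("I", "II", "III"):
            raise ValueError(f"hit on {self.gene_id!r}: invalid rms_type {self.rms_type!r}")


def read_domain_hits(path: str | os.PathLike) -> List[DomainHit]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "accession": str})
    missing = set(DOMAIN_HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"domain hit table {path} missing columns: {sorted(missing)}")
    hits = []
    for row in df.itertuples():
        role = None if pd.isna(row.role) else str(row.role)
        rms_type = None if pd.isna(row.rms_type) else str(row.rms_type)
        hits.append(DomainHit(row.gene_id, row.accession, row.source_db,
                              float(row.evalue), float(row.query_coverage),
                              role, rms_type))
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | os.PathLike) -> None:
    rows = [
        (h.gene_id, h.accession, h.source_db, h.evalue, h.query_coverage,
         h.role if h.role is not None else "",
         h.rms_type if h.rms_type is not None else "")
        for h in hits
    ]
    pd.DataFrame(rows, columns=DOMAIN_HIT_COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    subject_taxid: int
    percent_identity: float
    alignment_length: int
    bit_score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise ValueError("negative bit score")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent identity outside [0,100]")


def read_alignment_hits(path: str | os.PathLike,
                        subject_taxids: Mapping[str, int]) -> List[AlignmentHit]:
    """Read 12-column BLAST tabular output; subject taxids come from a lookup."""
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST_TABULAR_COLUMNS,
                     dtype={"query_id": str, "subject_id": str})
    hits = []
    for row in df.itertuples():
        if row.subject_id not in subject_taxids:
            raise KeyError(f"no taxid known for subject {row.subject_id!r}")
        hits.append(AlignmentHit(
            row.query_id, row.subject_id, int(subject_taxids[row.subject_id]),
            float(row.percent_identity), int(row.alignment_length),
            float(row.bit_score), float(row.evalue)))
    return hits


@dataclass(frozen=True)
class TaxonomyNode:
    taxid: int
    parent_taxid: int
    rank: str
    name: str


class Taxonomy:
    """A rooted taxonomy tree; the root is its own parent."""

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self.nodes: Dict[int, TaxonomyNode] = {n.taxid: n for n in nodes}
        roots = [n.taxid for n in self.nodes.values() if n.parent_taxid == n.taxid]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for n in self.nodes.values():
            if n.parent_taxid not in self.nodes:
                raise ValueError(f"taxid {n.taxid} has unknown parent {n.parent_taxid}")
        # cycle check: every node must reach the root
        for taxid in self.nodes:
            seen = set()
            cur = taxid
            while cur != self.root:
                if cur in seen:
                    raise ValueError(f"cycle in taxonomy at taxid {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent_taxid

    def lineage(self, taxid: int) -> List[int]:
        """Path from root to taxid (inclusive)."""
        if taxid not in self.nodes:
            raise KeyError(f"unknown taxid {taxid}")
        path = [taxid]
        while path[-1] != self.root:
            path.append(self.nodes[path[-1]].parent_taxid)
        return path[::-1]

    def ancestor_at_rank(self, taxid: int, rank: str) -> Optional[int]:
        for t in self.lineage(taxid):
            if self.nodes[t].rank == rank:
                return t
        return None

    def name(self, taxid: int) -> str:
        return self.nodes[taxid].name


def read_taxonomy(path: str | os.PathLike) -> Taxonomy:
    df = pd.read_csv(path, sep="\t", dtype={"rank": str, "name": str})
    required = {"taxid", "parent_taxid", "rank", "name"}
    if missing := required - set(df.columns):
        raise ValueError(f"taxonomy table {path} missing columns: {sorted(missing)}")
    return Taxonomy(
        TaxonomyNode(int(r.taxid), int(r.parent_taxid), r.rank, r.name)
        for r in df.itertuples()
    )


def write_taxonomy(tax: Taxonomy, path: str | os.PathLike) -> None:
    rows = [(n.taxid, n.parent_taxid, n.rank, n.name) for n in tax.nodes.values()]
    pd.DataFrame(rows, columns=["taxid", "parent_taxid", "rank", "name"]).to_csv(
        path, sep="\t", index=False)
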
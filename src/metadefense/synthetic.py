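"""Synthetic multi-sample metagenomes with planted defense features and a
machine-readable truth ledger.

The simulator emits exactly the formats ``core_io`` reads: contig FASTA, a
gene coordinate table, a domain-hit table (annotations are generated
directly; no protein sequences), a samtools-depth style table together with
its total mapped basepairs, BLAST-tabular alignment hits for LCA, and the
truth ledger as TSV + JSON.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .core_io import (DepthTable, DomainHit, GeneRecord, SequenceRecord,
                      Taxonomy, TaxonomyNode, write_depth_table,
                      write_domain_hits, write_fasta, write_gene_table,
                      write_taxonomy)

BASES = np.array(list("ACGT"))

# accessions used for planted cas operons; must exist in data/cas_mapping.tsv
CAS_OPERON_ACCESSIONS = {
    "cas1": ("TIGR00287", "TIGRFAM"),
    "cas2": ("COG1343", "COG"),
    "cas3": ("TIGR01587", "TIGRFAM"),
}

GENE_PERIOD = 1000   # one gene every kb
GENE_LENGTH = 900
FEATURE_PAD = 300    # clearance around planted sequence features (bp)


@dataclass(frozen=True)
class SampleConfig:
    sample_id: str
    role: str = "sponge"                  # sponge | seawater
    n_contigs: int = 10
    contig_len_min: int = 20_000
    contig_len_max: int = 50_000
    gc: float = 0.5
    n_arrays: int = 0
    repeat_len: int = 32
    spacer_len: int = 36
    n_spacers_min: int = 2
    n_spacers_max: int = 5
    mutation_rate: float = 0.0
    cas_fraction: float = 0.0
    n_single_spacer_decoys: int = 0
    rms_pairs: Mapping[str, int] = field(default_factory=dict)  # type -> count
    rms_distance_min: int = 1
    rms_distance_max: int = 4
    n_rms_decoys: int = 0
    coverage_min: float = 5.0
    coverage_max: float = 30.0
    coverage_model: str = "poisson"       # poisson | uniform
    taxon_pool: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ("sponge", "seawater"):
            raise ValueError(f"invalid role {self.role!r}")
        if self.contig_len_min > self.contig_len_max:
            raise ValueError("contig_len_min > contig_len_max")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate outside [0,1]")
        if not 0.0 <= self.cas_fraction <= 1.0:
            raise ValueError("cas_fraction outside [0,1]")
        if self.coverage_min < 0 or self.coverage_max < self.coverage_min:
            raise ValueError("invalid coverage range")
        if self.coverage_model not in ("poisson", "uniform"):
            raise ValueError(f"unknown coverage model {self.coverage_model!r}")


@dataclass(frozen=True)
class SimulationConfig:
    samples: Tuple[SampleConfig, ...]
    seed: int

    @staticmethod
    def from_yaml(path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = tuple(
            SampleConfig(**{**s, "rms_pairs": dict(s.get("rms_pairs", {})),
                            "taxon_pool": tuple(s.get("taxon_pool", ()))})
            for s in raw["samples"])
        return SimulationConfig(samples=samples, seed=int(raw["seed"]))


@dataclass(frozen=True)
class TruthRecord:
    feature_type: str   # crispr_array | crispr_decoy | cas_locus | rms_pair | rms_decoy | contig_taxon
    sample_id: str
    contig_id: str
    start: int          # 1-based inclusive; 0 for non-positional records
    end: int
    detail: str         # JSON fragment with feature-specific fields
    expected_detectable: bool


@dataclass
class SampleData:
    config: SampleConfig
    contigs: List[SequenceRecord]
    genes: List[GeneRecord]
    domain_hits: List[DomainHit]
    depth: DepthTable
    total_mapped_bp: int
    truth: List[TruthRecord]
    contig_taxids: Dict[str, int]


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=length, p=probs))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return seq
    out = list(seq)
    for i, b in enumerate(out):
        if rng.random() < rate:
            out[i] = rng.choice([x for x in "ACGT" if x != b])
    return "".join(out)


def make_spacers(rng: np.random.Generator, n: int, length: int,
                 max_identity: float = 0.6, max_tries: int = 200) -> List[str]:
    """Random spacers with adjacent pairwise identity <= max_identity."""
    spacers: List[str] = []
    for _ in range(n):
        for attempt in range(max_tries):
            cand = random_dna(rng, length)
            if not spacers or _identity(spacers[-1], cand) <= max_identity:
                spacers.append(cand)
                break
        else:
            raise RuntimeError("could not satisfy spacer dissimilarity")
    return spacers


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / max(len(a), len(b))


def plant_crispr(sequence: str, position: int, repeat: str,
                 spacers: Sequence[str], mutation_rate: float,
                 rng: np.random.Generator) -> Tuple[str, int, int]:
    """Overwrite ``sequence`` at 0-based ``position`` with the block
    repeat (+per-copy mutations) interleaved with the spacers; returns
    (new sequence, 1-based start, 1-based end)."""
    parts: List[str] = []
    for i in range(len(spacers) + 1):
        parts.append(_mutate(repeat, mutation_rate, rng))
        if i < len(spacers):
            parts.append(spacers[i])
    block = "".join(parts)
    if position < 0 or position + len(block) > len(sequence):
        raise ValueError("planted block does not fit on the contig")
    new_seq = sequence[:position] + block + sequence[position + len(block):]
    return new_seq, position + 1, position + len(block)


def simulate_depth(contig_lengths: Mapping[str, int],
                   target_coverages: Mapping[str, float],
                   model: str, rng: np.random.Generator
                   ) -> Tuple[DepthTable, int]:
    """Per-position depths (Poisson around the target, or a uniform constant)
    plus the exact total mapped basepairs."""
    vectors: Dict[str, np.ndarray] = {}
    for contig, length in contig_lengths.items():
        cov = target_coverages[contig]
        if cov < 0:
            raise ValueError(f"negative coverage for contig {contig!r}")
        if model == "poisson":
            vectors[contig] = rng.poisson(cov, size=length).astype(np.int64)
        elif model == "uniform":
            vectors[contig] = np.full(length, int(round(cov)), dtype=np.int64)
        else:
            raise ValueError(f"unknown coverage model {model!r}")
    table = DepthTable(vectors)
    return table, table.total_depth()


class _Allocator:
    """Tracks reserved regions so planted features never collide."""

    def __init__(self, contig_lengths: Sequence[int]):
        self.lengths = list(contig_lengths)
        self.regions: List[List[Tuple[int, int]]] = [[] for _ in contig_lengths]
        self.used_genes: List[set] = [set() for _ in contig_lengths]

    def place_block(self, contig_idx: int, block_len: int,
                    rng: np.random.Generator, max_tries: int = 300) -> int:
        """0-based start for a sequence block, with FEATURE_PAD clearance."""
        length = self.lengths[contig_idx]
        if block_len + 2 * FEATURE_PAD > length:
            raise ValueError(
                f"contig {contig_idx} (len {length}) too short for a "
                f"{block_len} bp feature")
        for _ in range(max_tries):
            pos = int(rng.integers(FEATURE_PAD, length - block_len - FEATURE_PAD))
            lo, hi = pos - FEATURE_PAD, pos + block_len + FEATURE_PAD
            if all(hi <= s or lo >= e for s, e in self.regions[contig_idx]):
                self.regions[contig_idx].append((lo, hi))
                return pos
        raise RuntimeError(f"could not place a feature on contig {contig_idx}")

    def reserve_genes(self, contig_idx: int, indices: Sequence[int],
                      margin: int = 5) -> None:
        for i in indices:
            for j in range(i - margin, i + margin + 1):
                self.used_genes[contig_idx].add(j)

    def find_gene_run(self, contig_idx: int, span: int, n_genes: int,
                      rng: np.random.Generator, margin: int = 5) -> int:
        """First free run covering indices [i, i+span], scanning cyclically
        from a random start so placement stays seed-dependent but total."""
        if span + 1 > n_genes:
            raise ValueError("contig has too few genes for the requested run")
        offset = int(rng.integers(0, n_genes - span))
        for step in range(n_genes - span):
            i = (offset + step) % (n_genes - span)
            if all(j not in self.used_genes[contig_idx]
                   for j in range(i, i + span + 1)):
                self.reserve_genes(contig_idx, range(i, i + span + 1), margin)
                return i
        raise RuntimeError(
            f"no free gene run of span {span} left on contig {contig_idx}")


def simulate_sample(config: SampleConfig, seed: int) -> SampleData:
    rng = np.random.default_rng(seed)
    sid = config.sample_id
    lengths = [int(rng.integers(config.contig_len_min, config.contig_len_max + 1))
               for _ in range(config.n_contigs)]
    # fail early when the requested features cannot fit
    array_block = (config.repeat_len * (config.n_spacers_max + 1)
                   + config.spacer_len * config.n_spacers_max)
    if (config.n_arrays or config.n_single_spacer_decoys) and \
            min(lengths) < array_block + 2 * FEATURE_PAD:
        raise ValueError("contigs too short to host the requested arrays")

    sequences = [random_dna(rng, n, config.gc) for n in lengths]
    contig_ids = [f"{sid}_c{i:03d}" for i in range(config.n_contigs)]
    alloc = _Allocator(lengths)
    truth: List[TruthRecord] = []
    domain_hits: List[DomainHit] = []
    n_genes = [length // GENE_PERIOD for length in lengths]

    # ---- CRISPR arrays (and single-spacer decoys) -------------------------
    cas_needed = int(round(config.cas_fraction * config.n_arrays))
    array_specs = ([("crispr_array", k < cas_needed, None)
                    for k in range(config.n_arrays)]
                   + [("crispr_decoy", False, 1)
                      for _ in range(config.n_single_spacer_decoys)])
    for fi, (ftype, wants_cas, forced_spacers) in enumerate(array_specs):
        ci = fi % config.n_contigs
        n_sp = forced_spacers if forced_spacers is not None else int(
            rng.integers(config.n_spacers_min, config.n_spacers_max + 1))
        repeat = random_dna(rng, config.repeat_len)
        spacers = make_spacers(rng, n_sp, config.spacer_len)
        block_len = config.repeat_len * (n_sp + 1) + config.spacer_len * n_sp
        pos = alloc.place_block(ci, block_len, rng)
        sequences[ci], start, end = plant_crispr(
            sequences[ci], pos, repeat, spacers, config.mutation_rate, rng)
        detectable = (ftype == "crispr_array"
                      and config.mutation_rate <= 0.05)
        detail = {"repeat": repeat, "n_spacers": n_sp, "spacers": spacers,
                  "cas_adjacent": bool(wants_cas)}
        truth.append(TruthRecord(ftype, sid, contig_ids[ci], start, end,
                                 json.dumps(detail, sort_keys=True), detectable))
        # reserve the gene ordinals the array spans so RMS planting avoids them
        alloc.reserve_genes(ci, range((start - 1) // GENE_PERIOD,
                                      (end - 1) // GENE_PERIOD + 1), margin=0)
        if wants_cas:
            g0 = min((end - 1) // GENE_PERIOD + 1, n_genes[ci] - 3)
            operon = list(range(g0, g0 + 3))
            alloc.reserve_genes(ci, operon)
            for gi, (cas_name, (acc, db)) in zip(operon,
                                                 CAS_OPERON_ACCESSIONS.items()):
                domain_hits.append(DomainHit(
                    gene_id=f"{contig_ids[ci]}_g{gi:04d}", accession=acc,
                    source_db=db, evalue=1e-30, query_coverage=0.95))
            truth.append(TruthRecord(
                "cas_locus", sid, contig_ids[ci],
                operon[0] * GENE_PERIOD + 1, operon[-1] * GENE_PERIOD + GENE_LENGTH,
                json.dumps({"gene_indices": operon,
                            "accessions": [a for a, _ in
                                           CAS_OPERON_ACCESSIONS.values()]},
                           sort_keys=True), True))

    # ---- RMS pairs and decoy singletons -----------------------------------
    rms_jobs: List[Tuple[str, str]] = []   # (kind, rms_type)
    for rms_type in sorted(config.rms_pairs):
        rms_jobs += [("rms_pair", rms_type)] * config.rms_pairs[rms_type]
    decoy_types = sorted(config.rms_pairs) or ["II"]
    rms_jobs += [("rms_decoy", decoy_types[i % len(decoy_types)])
                 for i in range(config.n_rms_decoys)]
    for fi, (kind, rms_type) in enumerate(rms_jobs):
        ci = (fi + 3) % config.n_contigs
        if kind == "rms_pair":
            d = int(rng.integers(config.rms_distance_min,
                                 config.rms_distance_max + 1))
            i0 = alloc.find_gene_run(ci, d, n_genes[ci], rng)
            re_idx, mt_idx = i0, i0 + d
            for idx, role in ((re_idx, "REase"), (mt_idx, "MTase")):
                domain_hits.append(DomainHit(
                    gene_id=f"{contig_ids[ci]}_g{idx:04d}",
                    accession=f"REBASE_{role}_{rms_type}", source_db="REBASE",
                    evalue=1e-25, query_coverage=0.85,
                    role=role, rms_type=rms_type))
            truth.append(TruthRecord(
                "rms_pair", sid, contig_ids[ci],
                re_idx * GENE_PERIOD + 1, mt_idx * GENE_PERIOD + GENE_LENGTH,
                json.dumps({"rms_type": rms_type, "REase_index": re_idx,
                            "MTase_index": mt_idx, "distance": d},
                           sort_keys=True), True))
        else:
            i0 = alloc.find_gene_run(ci, 0, n_genes[ci], rng)
            role = "MTase" if fi % 2 else "REase"
            domain_hits.append(DomainHit(
                gene_id=f"{contig_ids[ci]}_g{i0:04d}",
                accession=f"REBASE_{role}_{rms_type}", source_db="REBASE",
                evalue=1e-25, query_coverage=0.85,
                role=role, rms_type=rms_type))
            truth.append(TruthRecord(
                "rms_decoy", sid, contig_ids[ci],
                i0 * GENE_PERIOD + 1, i0 * GENE_PERIOD + GENE_LENGTH,
                json.dumps({"rms_type": rms_type, "role": role}, sort_keys=True),
                False))

    # ---- gene table --------------------------------------------------------
    genes: List[GeneRecord] = []
    for ci, cid in enumerate(contig_ids):
        for gi in range(n_genes[ci]):
            genes.append(GeneRecord(
                gene_id=f"{cid}_g{gi:04d}", contig_id=cid, index_on_contig=gi,
                start=gi * GENE_PERIOD + 1, end=gi * GENE_PERIOD + GENE_LENGTH,
                strand="+"))

    # ---- coverage ----------------------------------------------------------
    contig_lengths = dict(zip(contig_ids, lengths))
    coverages = {cid: float(rng.uniform(config.coverage_min, config.coverage_max))
                 for cid in contig_ids}
    depth, total_bp = simulate_depth(contig_lengths, coverages,
                                     config.coverage_model, rng)

    # ---- taxonomy labels ---------------------------------------------------
    contig_taxids: Dict[str, int] = {}
    if config.taxon_pool:
        for cid in contig_ids:
            taxid = int(rng.choice(np.array(config.taxon_pool)))
            contig_taxids[cid] = taxid
            truth.append(TruthRecord(
                "contig_taxon", sid, cid, 0, 0,
                json.dumps({"taxid": taxid}), True))

    contigs = [SequenceRecord(cid, seq)
               for cid, seq in zip(contig_ids, sequences)]
    return SampleData(config=config, contigs=contigs, genes=genes,
                      domain_hits=domain_hits, depth=depth,
                      total_mapped_bp=total_bp, truth=truth,
                      contig_taxids=contig_taxids)


def default_taxonomy() -> Taxonomy:
    """A small fixed tree: root -> Bacteria -> six phyla -> genera -> species."""
    nodes = [
        TaxonomyNode(1, 1, "root", "root"),
        TaxonomyNode(2, 1, "superkingdom", "Bacteria"),
    ]
    phyla = ["Proteobacteria", "Actinobacteria", "Chloroflexi",
             "Firmicutes", "Bacteroidetes", "Cyanobacteria"]
    taxid = 10
    for i, name in enumerate(phyla):
        phylum_id = 10 + i
        nodes.append(TaxonomyNode(phylum_id, 2, "phylum", name))
        for g in range(2):
            genus_id = 100 + i * 10 + g
            nodes.append(TaxonomyNode(genus_id, phylum_id, "genus",
                                      f"{name}_genus{g}"))
            for s in range(2):
                species_id = 1000 + i * 100 + g * 10 + s
                nodes.append(TaxonomyNode(species_id, genus_id, "species",
                                          f"{name}_sp{g}{s}"))
    return Taxonomy(nodes)


SPECIES_TAXIDS: Tuple[int, ...] = tuple(
    1000 + i * 100 + g * 10 + s
    for i in range(6) for g in range(2) for s in range(2))


def write_sample(sample: SampleData, outdir: str) -> Dict[str, str]:
    """Write every artifact of one sample; returns a manifest of paths."""
    os.makedirs(outdir, exist_ok=True)
    sid = sample.config.sample_id
    paths = {
        "contigs": os.path.join(outdir, f"{sid}.contigs.fasta"),
        "genes": os.path.join(outdir, f"{sid}.genes.tsv"),
        "domain_hits": os.path.join(outdir, f"{sid}.domain_hits.tsv"),
        "depth": os.path.join(outdir, f"{sid}.depth.tsv"),
        "total_mapped_bp": os.path.join(outdir, f"{sid}.total_mapped_bp.txt"),
        "alignment_hits": os.path.join(outdir, f"{sid}.alignment_hits.tsv"),
        "subject_taxids": os.path.join(outdir, f"{sid}.subject_taxids.tsv"),
        "truth_tsv": os.path.join(outdir, f"{sid}.truth.tsv"),
        "truth_json": os.path.join(outdir, f"{sid}.truth.json"),
    }
    write_fasta(sample.contigs, paths["contigs"])
    write_gene_table(sample.genes, paths["genes"])
    write_domain_hits(sample.domain_hits, paths["domain_hits"])
    write_depth_table(sample.depth, paths["depth"], omit_zeros=False)
    with open(paths["total_mapped_bp"], "w") as fh:
        fh.write(f"{sample.total_mapped_bp}\n")
    with open(paths["alignment_hits"], "w") as fh_hits, \
            open(paths["subject_taxids"], "w") as fh_tax:
        fh_tax.write("subject_id\ttaxid\n")
        for cid, taxid in sample.contig_taxids.items():
            subject = f"ref_{taxid}"
            fh_hits.write(f"{cid}\t{subject}\t98.0\t500\t5\t0\t1\t500\t1\t500"
                          f"\t1e-50\t900.0\n")
            fh_tax.write(f"{subject}\t{taxid}\n")
    rows = [dataclasses.asdict(t) for t in sample.truth]
    with open(paths["truth_tsv"], "w") as fh:
        cols = ["feature_type", "sample_id", "contig_id", "start", "end",
                "detail", "expected_detectable"]
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")
    with open(paths["truth_json"], "w") as fh:
        json.dump(rows, fh, indent=1, sort_keys=True)
    return paths


def simulate_all(config: SimulationConfig) -> Dict[str, SampleData]:
    """Simulate every sample; per-sample seeds are derived from the master
    seed so samples are independent but jointly deterministic."""
    out: Dict[str, SampleData] = {}
    for i, sample_cfg in enumerate(config.samples):
        out[sample_cfg.sample_id] = simulate_sample(sample_cfg,
                                                    seed=config.seed + 7919 * i)
    return out
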
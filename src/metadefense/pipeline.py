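"""End-to-end orchestration: per-sample stage outputs plus combined
summary tables, community clustering and enrichment calls.

Every number in the summary is recomputed from stage outputs; the reporter
holds no private state.  All thresholds live in one config mapping whose
defaults ship in ``metadefense/data/defaults.yaml``.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import abundance, cas_typing, crispr_detect, rms_detect, spacer_analysis
from .alignment import ScoringScheme
from .core_io import (SequenceRecord, filter_contigs, read_alignment_hits,
                      read_depth_table, read_domain_hits, read_fasta,
                      read_gene_table, read_taxonomy, write_fasta)
from .crispr_detect import arrays_to_table_rows
from .rms_detect import clusters_to_table_rows

logger = logging.getLogger("metadefense")


def load_defaults(path: Optional[str] = None) -> Dict:
    if path is None:
        source = resources.files("metadefense.data").joinpath("defaults.yaml")
        with resources.as_file(source) as p:
            with open(p) as fh:
                return yaml.safe_load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh)


@dataclass
class SampleManifest:
    sample_id: str
    role: str
    contigs: str
    depth: str
    genes: str
    domain_hits: str
    total_mapped_bp: Optional[str] = None
    alignment_hits: Optional[str] = None
    subject_taxids: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ("sponge", "seawater"):
            raise ValueError(f"sample {self.sample_id!r}: invalid role {self.role!r}")


@dataclass
class Manifest:
    samples: List[SampleManifest]
    taxonomy: Optional[str] = None
    targets: Optional[str] = None
    repeat_reference: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("sample ids are not unique")
        if not ids:
            raise ValueError("manifest contains no samples")

    @staticmethod
    def from_yaml(path: str) -> "Manifest":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = [SampleManifest(**s) for s in raw["samples"]]
        return Manifest(samples=samples, taxonomy=raw.get("taxonomy"),
                        targets=raw.get("targets"),
                        repeat_reference=raw.get("repeat_reference"))

    def referenced_files(self) -> List[str]:
        files = []
        for s in self.samples:
            files += [s.contigs, s.depth, s.genes, s.domain_hits]
            files += [p for p in (s.total_mapped_bp, s.alignment_hits,
                                  s.subject_taxids) if p]
        files += [p for p in (self.taxonomy, self.targets, self.repeat_reference) if p]
        return files


@dataclass
class SampleResult:
    sample_id: str
    role: str
    n_contigs: int
    assembly_bp: int
    mean_coverage: float
    mean_gc: float
    total_mapped_bp: int
    arrays: List[crispr_detect.CrisprArray]
    spacer_catalogue: spacer_analysis.SpacerCatalogue
    repeat_counts: Dict[str, int]
    rms_clusters: List[rms_detect.RmsCluster]
    cas_genes: List[cas_typing.CasGene]
    cas_loci: List[cas_typing.CasLocus]
    contig_cpm: Dict[str, float]
    contig_phylum: Dict[str, Optional[str]]
    spacer_hits: List[spacer_analysis.SpacerHit]
    category_tallies: Dict[str, int]
    known_repeats: List[str]


def _read_targets(path: str) -> List[Tuple[SequenceRecord, str]]:
    """Target FASTA whose descriptions carry ``category=<phage|virus|plasmid>``."""
    out = []
    for rec in read_fasta(path):
        category = None
        for token in rec.description.split():
            if token.startswith("category="):
                category = token.split("=", 1)[1]
        if category is None:
            raise ValueError(f"target {rec.id!r} lacks a category label")
        out.append((rec, category))
    return out


def run_sample(sample: SampleManifest, config: Mapping,
               taxonomy=None, targets=None, repeat_reference=None,
               outdir: Optional[str] = None) -> SampleResult:
    cfg = config
    contigs = read_fasta(sample.contigs)
    kept = filter_contigs(contigs, min_len=cfg["min_contig_len"])
    logger.info("%s: %d contigs read, %d kept (min length %d)",
                sample.sample_id, len(contigs), len(kept), cfg["min_contig_len"])
    genes = read_gene_table(sample.genes)
    hits = read_domain_hits(sample.domain_hits)

    mapping = cas_typing.load_cas_mapping(cfg.get("cas_mapping_path"))
    subtypes = cas_typing.load_subtype_signatures(cfg.get("cas_subtypes_path"))
    cas_genes = cas_typing.identify_cas_genes(hits, mapping)
    gene_contig = {g.gene_id: g.contig_id for g in genes}
    cas_contig_ids = {gene_contig[g.gene_id] for g in cas_genes
                      if g.gene_id in gene_contig}
    cas_loci = cas_typing.group_cas_loci(cas_genes, genes,
                                         max_gene_gap=cfg["cas_max_gene_gap"],
                                         subtype_signatures=subtypes) \
        if cas_genes else []

    arrays = crispr_detect.detect_consensus(kept, cas_contig_ids=cas_contig_ids)
    arrays = cas_typing.link_arrays_to_cas(arrays, cas_loci, genes,
                                           max_gene_gap=cfg["cas_max_gene_gap"])

    catalogue = spacer_analysis.collect_spacers(arrays,
                                                id_prefix=f"{sample.sample_id}|")
    repeat_counts = dict(spacer_analysis.collect_repeats(arrays))
    rms_clusters = rms_detect.call_rms(
        hits, genes, min_coverage=cfg["rms_min_coverage"],
        max_gene_distance=cfg["rms_max_gene_distance"],
        cluster_window=cfg["rms_cluster_window"])

    contig_lengths = {c.id: len(c) for c in contigs}
    depth = read_depth_table(sample.depth, contig_lengths)
    if sample.total_mapped_bp:
        with open(sample.total_mapped_bp) as fh:
            total_mapped_bp = int(fh.read().strip())
    else:
        total_mapped_bp = depth.total_depth()
    contig_cpm = abundance.contig_cpm_table(depth, total_mapped_bp)

    contig_phylum: Dict[str, Optional[str]] = {}
    if taxonomy is not None and sample.alignment_hits and sample.subject_taxids:
        taxids = pd.read_csv(sample.subject_taxids, sep="\t")
        lookup = dict(zip(taxids["subject_id"], taxids["taxid"]))
        ahits = read_alignment_hits(sample.alignment_hits, lookup)
        assignments = abundance.assign_queries(
            ahits, taxonomy, top_score_fraction=cfg["lca_top_score_fraction"])
        for contig_id, taxid in assignments.items():
            if taxid is None:
                contig_phylum[contig_id] = None
            else:
                at_rank = taxonomy.ancestor_at_rank(taxid, "phylum")
                contig_phylum[contig_id] = (taxonomy.name(at_rank)
                                            if at_rank is not None else None)

    spacer_hits: List[spacer_analysis.SpacerHit] = []
    category_tallies: Dict[str, int] = {}
    if targets and catalogue.distinct:
        scheme = ScoringScheme(word_size=cfg["target_word_size"],
                               evalue_max=cfg["target_evalue_max"])
        spacer_records = [SequenceRecord(f"sp{idx}", seq)
                          for idx, seq in enumerate(sorted(catalogue.counts))]
        spacer_hits = spacer_analysis.search_targets(spacer_records, targets, scheme)
        _, tallies = spacer_analysis.categorize_targets(
            [r.id for r in spacer_records], spacer_hits)
        category_tallies = dict(tallies)

    known_repeats: List[str] = []
    if repeat_reference is not None and repeat_counts:
        repeat_records = [SequenceRecord(f"dr{idx}", seq)
                          for idx, seq in enumerate(sorted(repeat_counts))]
        known_repeats, _ = spacer_analysis.match_repeats_to_reference(
            repeat_records, repeat_reference,
            max_evalue=cfg["repeat_reference_evalue_max"])

    gc_values, _, _ = abundance.gc_distribution(kept)
    assembly_bp = sum(len(c) for c in kept)
    mean_gc = (sum(gc_values[c.id] * len(c) for c in kept) / assembly_bp
               if assembly_bp else 0.0)
    mean_coverage = abundance.ratio_2dp(total_mapped_bp,
                                        sum(contig_lengths.values()))

    result = SampleResult(
        sample_id=sample.sample_id, role=sample.role,
        n_contigs=len(kept), assembly_bp=assembly_bp,
        mean_coverage=mean_coverage, mean_gc=mean_gc,
        total_mapped_bp=total_mapped_bp, arrays=arrays,
        spacer_catalogue=catalogue, repeat_counts=repeat_counts,
        rms_clusters=rms_clusters, cas_genes=cas_genes, cas_loci=cas_loci,
        contig_cpm=contig_cpm, contig_phylum=contig_phylum,
        spacer_hits=spacer_hits, category_tallies=category_tallies,
        known_repeats=known_repeats)
    if outdir:
        _write_sample_outputs(result, outdir)
    return result


def _write_sample_outputs(res: SampleResult, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    sid = res.sample_id
    pd.DataFrame(arrays_to_table_rows(res.arrays)).to_csv(
        os.path.join(outdir, f"{sid}.arrays.tsv"), sep="\t", index=False)
    spacer_recs = []
    for seq, labels in sorted(res.spacer_catalogue.sources.items()):
        for label in labels:
            spacer_recs.append(SequenceRecord(label.replace("|", "_"), seq))
    if spacer_recs:
        write_fasta(spacer_recs, os.path.join(outdir, f"{sid}.spacers.fasta"))
    repeat_recs = [SequenceRecord(f"{sid}_dr{idx}", seq)
                   for idx, seq in enumerate(sorted(res.repeat_counts))]
    if repeat_recs:
        write_fasta(repeat_recs, os.path.join(outdir, f"{sid}.repeats.fasta"))
    pd.DataFrame(clusters_to_table_rows(res.rms_clusters)).to_csv(
        os.path.join(outdir, f"{sid}.rms_clusters.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [(g.gene_id, g.cas_name, ";".join(g.accessions), g.best_evalue)
         for g in res.cas_genes],
        columns=["gene_id", "cas_name", "accessions", "evalue"]).to_csv(
        os.path.join(outdir, f"{sid}.cas_genes.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [(l.contig_id, l.index_start, l.index_end, l.assigned_type,
          l.subtype or "") for l in res.cas_loci],
        columns=["contig_id", "index_start", "index_end", "type", "subtype"]
    ).to_csv(os.path.join(outdir, f"{sid}.cas_loci.tsv"), sep="\t", index=False)
    pd.DataFrame(sorted(res.contig_cpm.items()),
                 columns=["contig_id", "cpm"]).to_csv(
        os.path.join(outdir, f"{sid}.contig_cpm.tsv"), sep="\t", index=False)
    if res.spacer_hits:
        pd.DataFrame(
            [(h.spacer_id, h.target_id, h.target_category, h.score, h.evalue,
              h.spacer_start, h.spacer_end, h.target_start, h.target_end,
              h.strand) for h in res.spacer_hits],
            columns=["spacer_id", "target_id", "category", "score", "evalue",
                     "spacer_start", "spacer_end", "target_start",
                     "target_end", "strand"]).to_csv(
            os.path.join(outdir, f"{sid}.spacer_hits.tsv"), sep="\t", index=False)


def summarize_sample(res: SampleResult) -> Dict[str, object]:
    """One Table-2/Table-3 style summary row for a sample."""
    arrays = res.arrays
    n_arrays = len(arrays)
    assembly_mb = res.assembly_bp / 1e6
    arrays_with_tax = [a for a in arrays
                       if res.contig_phylum.get(a.contig_id) is not None]
    phylum_tallies: Dict[str, int] = {}
    for a in arrays_with_tax:
        phylum = res.contig_phylum[a.contig_id]
        phylum_tallies[phylum] = phylum_tallies.get(phylum, 0) + 1
    cas_arrays = [a for a in arrays if a.cas_adjacent]
    type_tallies = {"I": 0, "II": 0, "III": 0, "unknown": 0}
    for a in cas_arrays:
        type_tallies[a.crispr_type or "unknown"] += 1
    cat = res.spacer_catalogue
    row: Dict[str, object] = {
        "sample_id": res.sample_id,
        "role": res.role,
        "n_contigs": res.n_contigs,
        "assembly_bp": res.assembly_bp,
        "mean_coverage": res.mean_coverage,
        "mean_gc_percent": round(res.mean_gc * 100, 2),
        "crispr_arrays": n_arrays,
        "crispr_per_mb": round(n_arrays / assembly_mb, 2) if assembly_mb else 0.0,
        "crispr_cpm": round(sum(res.contig_cpm.get(a.contig_id, 0.0)
                                for a in arrays), 6),
        "crispr_with_taxonomy": len(arrays_with_tax),
        "pct_with_taxonomy": (abundance.percentage(len(arrays_with_tax), n_arrays)
                              if n_arrays else 0.0),
        "crispr_with_cas": len(cas_arrays),
        "pct_with_cas": (abundance.percentage(len(cas_arrays), n_arrays)
                         if n_arrays else 0.0),
        "type_I": type_tallies["I"],
        "type_II": type_tallies["II"],
        "type_III": type_tallies["III"],
        "type_unknown": type_tallies["unknown"],
        "largest_array_spacers": max((a.n_spacers for a in arrays), default=0),
        "total_spacers": cat.total,
        "distinct_spacers": cat.distinct,
        "singleton_spacers": cat.singletons,
        "multi_occurring_spacers": cat.multi_occurring,
        "spacers_with_target": _spacers_with_target(res),
        "target_phage": res.category_tallies.get("phage", 0),
        "target_virus": res.category_tallies.get("virus", 0),
        "target_plasmid": res.category_tallies.get("plasmid", 0),
        "target_unknown": res.category_tallies.get("unknown", 0),
        "total_repeats": n_arrays,
        "unique_repeats": len(res.repeat_counts),
        "repeats_known": len(res.known_repeats),
        "rms_clusters": len(res.rms_clusters),
        "rms_type_I": sum(1 for c in res.rms_clusters if c.rms_type == "I"),
        "rms_type_II": sum(1 for c in res.rms_clusters if c.rms_type == "II"),
        "rms_type_III": sum(1 for c in res.rms_clusters if c.rms_type == "III"),
    }
    for phylum, count in sorted(phylum_tallies.items()):
        row[f"phylum_{phylum}"] = count
    return row


def _spacers_with_target(res: SampleResult) -> int:
    return len({h.spacer_id for h in res.spacer_hits})


def summarize_crispr(results: Sequence[SampleResult]) -> pd.DataFrame:
    rows = [summarize_sample(r) for r in results]
    df = pd.DataFrame(rows)
    return df.fillna(0)


def community_profiles(results: Sequence[SampleResult]
                       ) -> Dict[str, Dict[str, float]]:
    """Per-sample relative phylum abundance weighted by contig cpm."""
    profiles: Dict[str, Dict[str, float]] = {}
    for res in results:
        if not res.contig_phylum:
            continue
        tallies: Dict[str, float] = {}
        for contig, phylum in res.contig_phylum.items():
            key = phylum if phylum is not None else "other"
            tallies[key] = tallies.get(key, 0.0) + res.contig_cpm.get(contig, 0.0)
        total = sum(tallies.values())
        if total > 0:
            profiles[res.sample_id] = {k: v / total for k, v in tallies.items()}
    return profiles


def feature_cpm_matrix(results: Sequence[SampleResult]) -> pd.DataFrame:
    """cpm per defense feature per sample (CRISPR arrays, RMS types, cas genes)."""
    rows = []
    for res in results:
        instances = [("CRISPR_array", a.contig_id) for a in res.arrays]
        instances += [(f"RMS_type_{c.rms_type}", c.contig_id)
                      for c in res.rms_clusters]
        gene_contig = {}
        for locus in res.cas_loci:
            for g in locus.genes:
                gene_contig[g.gene_id] = locus.contig_id
        instances += [(f"cas:{g.cas_name}", gene_contig[g.gene_id])
                      for locus in res.cas_loci for g in locus.genes]
        for fa in abundance.aggregate_feature_cpm(instances, res.contig_cpm,
                                                  res.sample_id):
            rows.append((fa.feature_id, fa.sample_id, fa.raw_count, fa.cpm))
    return pd.DataFrame(rows, columns=["feature_id", "sample_id",
                                       "raw_count", "cpm"])


def enrichment_table(feature_cpm: pd.DataFrame, roles: Mapping[str, str],
                     factor: float = 1.5) -> pd.DataFrame:
    sponge = [s for s, r in roles.items() if r == "sponge"]
    seawater = [s for s, r in roles.items() if r == "seawater"]
    if not sponge or len(seawater) != 1:
        return pd.DataFrame(columns=["feature_id", "mean_sponge_cpm",
                                     "seawater_cpm", "flag"])
    wide = feature_cpm.pivot_table(index="feature_id", columns="sample_id",
                                   values="cpm", fill_value=0.0, aggfunc="sum")
    rows = []
    for feature in wide.index:
        call = abundance.enrichment_call(
            feature,
            [float(wide.loc[feature].get(s, 0.0)) for s in sponge],
            float(wide.loc[feature].get(seawater[0], 0.0)), factor=factor)
        rows.append((call.feature_id, call.mean_sponge_cpm,
                     call.seawater_cpm, call.flag))
    return pd.DataFrame(rows, columns=["feature_id", "mean_sponge_cpm",
                                       "seawater_cpm", "flag"])


def run_pipeline(manifest: Manifest, outdir: str,
                 config: Optional[Mapping] = None) -> Dict[str, object]:
    """Run every stage for every sample and write the combined report."""
    cfg = dict(load_defaults())
    if config:
        cfg.update(config)
    missing = [p for p in manifest.referenced_files() if not os.path.exists(p)]
    if missing:
        raise FileNotFoundError(f"manifest references missing files: {missing}")
    os.makedirs(outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(outdir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("thresholds: %s", json.dumps(cfg, sort_keys=True, default=str))
    try:
        taxonomy = read_taxonomy(manifest.taxonomy) if manifest.taxonomy else None
        targets = _read_targets(manifest.targets) if manifest.targets else None
        repeat_ref = (read_fasta(manifest.repeat_reference)
                      if manifest.repeat_reference else None)
        results = [run_sample(s, cfg, taxonomy=taxonomy, targets=targets,
                              repeat_reference=repeat_ref,
                              outdir=os.path.join(outdir, s.sample_id))
                   for s in manifest.samples]
        summary = summarize_crispr(results)
        summary.to_csv(os.path.join(outdir, "summary.tsv"), sep="\t", index=False)
        fcpm = feature_cpm_matrix(results)
        fcpm.to_csv(os.path.join(outdir, "feature_cpm.tsv"), sep="\t", index=False)
        roles = {s.sample_id: s.role for s in manifest.samples}
        enrich = enrichment_table(fcpm, roles, factor=cfg["enrichment_factor"])
        enrich.to_csv(os.path.join(outdir, "enrichment.tsv"), sep="\t", index=False)
        profiles = community_profiles(results)
        if len(profiles) >= 2:
            labels, mat = abundance.dissimilarity_matrix(profiles)
            pd.DataFrame(mat, index=labels, columns=labels).to_csv(
                os.path.join(outdir, "braycurtis.tsv"), sep="\t")
            newick = abundance.complete_linkage(mat, labels)
            with open(os.path.join(outdir, "dendrogram.nwk"), "w") as fh:
                fh.write(newick + "\n")
        return {"results": results, "summary": summary, "feature_cpm": fcpm,
                "enrichment": enrich, "profiles": profiles}
    finally:
        logger.removeHandler(handler)
        handler.close()
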
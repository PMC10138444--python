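"""End-to-end orchestration of the ceRNA inference stages.

A :class:`PipelineConfig` points at a dataset bundle (the layout written
by :func:`cernapipe.simulate.simulate_scenario`, or equivalently named
user files) plus thresholds and a seed.  :func:`run_pipeline` executes

    normalize -> qc -> de -> trend -> targets -> circ -> lnc -> cerna -> enrich

writing one TSV/GraphML/JSON artifact set per stage and a manifest with
input checksums, the seed and the parameter snapshot.  Reruns with an
identical config reproduce identical outputs.

Stage results are also returned in memory (:class:`PipelineResult`) so
library callers, the test-suite and the acceptance script can inspect
them without re-reading files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import backsplice, cerna, diffexpr, enrich, expression, gffio, lncrna, trends
from ._util import sha256_file
from .targeting import scan_targets

logger = logging.getLogger(__name__)

INPUT_KEYS = (
    "counts_mrna", "counts_lncrna", "counts_circrna", "counts_mirna",
    "annotation", "transcripts", "mirnas", "reads", "terms", "genome",
)
THRESHOLD_DEFAULTS: dict[str, float] = {
    "fdr_max": 0.05, "p_max": 0.05, "lfc_min": 1.0,
    "rho_max": -0.3, "r_min": 0.5,
    "max_penalty": 4.0,
    "min_support": 2, "anchor_len": 20,
    "cis_window": 100_000, "trans_r_min": 0.999,
    "lnc_min_len": 200, "lnc_max_orf_codons": 100,
    "qc_low_r": 0.8, "enrich_alpha": 0.05,
    "trend_permutations": 1000,
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    inputs: dict[str, str]
    outdir: str
    seed: int = 0
    thresholds: dict[str, float] = field(default_factory=dict)
    stages: tuple[str, ...] = ("normalize", "qc", "de", "trend", "targets",
                               "circ", "lnc", "cerna", "enrich")

    def __post_init__(self):
        unknown = set(self.thresholds) - set(THRESHOLD_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown threshold keys: {sorted(unknown)}")
        unknown_inputs = set(self.inputs) - set(INPUT_KEYS)
        if unknown_inputs:
            raise ConfigError(f"unknown input keys: {sorted(unknown_inputs)}")
        if len(self.stages) < 2:
            raise ConfigError("stage order must list >= 2 stages")

    def threshold(self, key: str) -> float:
        return self.thresholds.get(key, THRESHOLD_DEFAULTS[key])

    def path(self, key: str) -> Path:
        if key not in self.inputs:
            raise ConfigError(f"missing input {key!r}")
        p = Path(self.inputs[key])
        if not p.exists():
            raise ConfigError(f"input {key!r} not found: {p}")
        return p

    @classmethod
    def from_bundle(cls, bundle_dir: str | Path, outdir: str | Path,
                    seed: int = 0, thresholds: dict | None = None,
                    ) -> "PipelineConfig":
        b = Path(bundle_dir)
        names = {
            "counts_mrna": "counts_mrna.tsv", "counts_lncrna": "counts_lncrna.tsv",
            "counts_circrna": "counts_circrna.tsv", "counts_mirna": "counts_mirna.tsv",
            "annotation": "annotation.gff3", "transcripts": "transcripts.fa",
            "mirnas": "mirnas.fa", "reads": "reads.fa", "terms": "terms.tsv",
            "genome": "genome.fa",
        }
        return cls(inputs={k: str(b / v) for k, v in names.items()},
                   outdir=str(outdir), seed=seed, thresholds=thresholds or {})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


@dataclass
class PipelineResult:
    de_tables: dict[str, pd.DataFrame]
    de_sets: dict[str, set[str]]
    expr_by_class: dict[str, expression.ExpressionMatrix]
    target_hits: list
    junctions: list
    associations: list
    triads: list
    network: cerna.CeRNANetwork | None
    enrichment: list
    profile_results: list
    manifest: dict[str, Any]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the configured stages over a dataset bundle."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "thresholds": {k: config.threshold(k) for k in THRESHOLD_DEFAULTS},
        "inputs": {}, "outputs": {}, "stages": list(config.stages),
    }

    genes = gffio.read_gff3(config.path("annotation"))
    genes_by_id = {g.gene_id: g for g in genes}
    circ_catalog = gffio.read_circ_features(config.path("annotation"))
    lengths = {g.gene_id: g.exon_union_length() for g in genes}
    for c in circ_catalog:
        lengths[c["circ_id"]] = c["end"] - c["start"] + 1
    transcripts = gffio.read_fasta(config.path("transcripts"))
    mirna_seqs = gffio.read_fasta(config.path("mirnas"))
    for mid, seq in mirna_seqs.items():
        lengths.setdefault(mid, len(seq))

    counts = {}
    for cls, key in (("mRNA", "counts_mrna"), ("lncRNA", "counts_lncrna"),
                     ("circRNA", "counts_circrna"), ("miRNA", "counts_mirna")):
        known = (list(genes_by_id) + [c["circ_id"] for c in circ_catalog]
                 + list(mirna_seqs))
        counts[cls] = expression.read_counts(config.path(key), annotation=known)
        manifest["inputs"][key] = sha256_file(config.path(key))
    for key in ("annotation", "transcripts", "mirnas", "reads", "terms"):
        manifest["inputs"][key] = sha256_file(config.path(key))

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"][name] = sha256_file(path)

    # ---- normalize: FPKM for mRNA/lncRNA/circRNA, TPM for miRNA
    expr_by_class: dict[str, expression.ExpressionMatrix] = {}
    if "normalize" in config.stages:
        for cls, mode in (("mRNA", "fpkm"), ("lncRNA", "fpkm"),
                          ("circRNA", "fpkm"), ("miRNA", "tpm")):
            expr_by_class[cls] = expression.normalize(counts[cls], lengths, mode)
            emit(f"abundance_{cls.lower()}.tsv",
                 lambda p, e=expr_by_class[cls]: e.write_tsv(p))
    else:
        expr_by_class = dict(counts)

    # ---- replicate QC (report-only)
    if "qc" in config.stages:
        qc = expression.replicate_qc(expr_by_class["mRNA"],
                                     k=min(3, counts["mRNA"].n_samples),
                                     low_r=config.threshold("qc_low_r"))
        emit("qc_pearson.tsv", lambda p: qc.pearson.to_csv(p, sep="\t"))
        emit("qc_report.json",
             lambda p: Path(p).write_text(json.dumps(qc.to_json_dict(), indent=1)))

    # ---- differential expression, all pairwise contrasts
    de_tables: dict[str, pd.DataFrame] = {}
    de_sets: dict[str, set[str]] = {}
    if "de" in config.stages:
        for cls in ("mRNA", "lncRNA", "circRNA", "miRNA"):
            table = diffexpr.run_contrasts(counts[cls], cls)
            de_tables[cls] = table
            de_sets[cls] = diffexpr.de_gene_set(table)
            emit(f"de_{cls.lower()}.tsv",
                 lambda p, t=table: t.to_csv(p, sep="\t", index=False))
        logger.info("DE sets: %s", {k: len(v) for k, v in de_sets.items()})

    # ---- trend profiles of DE mRNAs
    profile_results: list = []
    if "trend" in config.stages and de_sets.get("mRNA"):
        tc = trends.TrendConfig(
            T=len(counts["mRNA"].stage_order), seed=config.seed,
            n_permutations=int(config.threshold("trend_permutations")))
        means = expr_by_class["mRNA"].subset(sorted(de_sets["mRNA"])).stage_means()
        vectors = trends.vectors_from_stage_means(means)
        assign_table, profile_results = trends.assign_and_enrich(vectors, tc)
        emit("trend_assignments.tsv",
             lambda p: assign_table.to_csv(p, sep="\t", index=False))
        emit("trend_profiles.tsv",
             lambda p: trends.profile_table(profile_results).to_csv(
                 p, sep="\t", index=False))

    # ---- miRNA target scanning
    target_hits: list = []
    if "targets" in config.stages:
        mrna_seq = {g.gene_id: transcripts[g.gene_id] for g in genes
                    if g.biotype == "protein_coding" and g.gene_id in transcripts}
        lnc_seq = {g.gene_id: transcripts[g.gene_id] for g in genes
                   if g.biotype == "lncRNA" and g.gene_id in transcripts}
        circ_seq = {c["circ_id"]: transcripts[c["circ_id"]]
                    for c in circ_catalog if c["circ_id"] in transcripts}
        mp = config.threshold("max_penalty")
        target_hits = (
            scan_targets(mirna_seqs, mrna_seq, "mRNA", mp)
            + scan_targets(mirna_seqs, lnc_seq, "lncRNA", mp)
            + scan_targets(mirna_seqs, circ_seq, "circRNA", mp, circular=True)
        )
        emit("target_hits.tsv", lambda p: pd.DataFrame(
            [{"mirna_id": h.mirna_id, "target_id": h.target_id,
              "class": h.target_class, "start": h.start,
              "penalty": h.penalty, "mirna_aln": h.alignment[0],
              "match_aln": h.alignment[1], "target_aln": h.alignment[2]}
             for h in target_hits]).to_csv(p, sep="\t", index=False))

    # ---- back-splice detection and circRNA validation
    junctions: list = []
    if "circ" in config.stages:
        reads_path = config.path("reads")
        junctions = backsplice.detect_backsplice(
            reads_path, config.path("genome"),
            anchor_len=int(config.threshold("anchor_len")),
            min_support=int(config.threshold("min_support")))
        total_reads = sum(1 for line in open(reads_path)
                          if line.startswith(">") or line.startswith("@"))
        backsplice.quantify_junctions(junctions, max(total_reads, 1))
        for j in junctions:
            backsplice.classify_junction(j, genes)
        emit("junctions.tsv", lambda p: pd.DataFrame(
            backsplice.junction_table_rows(junctions)).to_csv(
                p, sep="\t", index=False))
        detected = {(j.chrom, j.acceptor_pos + 1, j.donor_pos + 1, j.strand)
                    for j in junctions}
        validated = {c["circ_id"] for c in circ_catalog
                     if (c["chrom"], c["start"], c["end"], c["strand"]) in detected}
        if "circRNA" in de_sets:
            de_sets["circRNA"] &= validated
        manifest["validated_circrnas"] = sorted(validated)

    # ---- lncRNA filtering and associations
    associations: list = []
    if "lnc" in config.stages:
        lnc_seq = {g.gene_id: transcripts[g.gene_id] for g in genes
                   if g.biotype == "lncRNA" and g.gene_id in transcripts}
        noncoding = lncrna.filter_noncoding(
            lnc_seq, min_len=int(config.threshold("lnc_min_len")),
            max_orf_codons=int(config.threshold("lnc_max_orf_codons")))
        if "lncRNA" in de_sets:
            de_sets["lncRNA"] &= noncoding
        lnc_expr_ids = set(expr_by_class["lncRNA"].gene_ids)
        mrna_expr_ids = set(expr_by_class["mRNA"].gene_ids)
        lnc_models = [g for g in genes if g.biotype == "lncRNA"
                      and g.gene_id in noncoding and g.gene_id in lnc_expr_ids]
        mrna_models = [g for g in genes if g.biotype == "protein_coding"
                       and g.gene_id in mrna_expr_ids]
        associations = lncrna.associate(
            lnc_models, mrna_models,
            expr_by_class["lncRNA"].subset([g.gene_id for g in lnc_models]),
            expr_by_class["mRNA"].subset([g.gene_id for g in mrna_models]),
            window=int(config.threshold("cis_window")),
            r_min=config.threshold("trans_r_min"))
        emit("lncrna_associations.tsv", lambda p: pd.DataFrame(
            [a.__dict__ for a in associations]).to_csv(p, sep="\t", index=False))

    # ---- two-step ceRNA screen and network
    triads: list = []
    network = None
    if "cerna" in config.stages and de_sets:
        triads = cerna.screen_triads(
            target_hits, de_sets, expr_by_class,
            rho_max=config.threshold("rho_max"),
            r_min=config.threshold("r_min"))
        network = cerna.build_network(triads)
        emit("cerna_triads.tsv",
             lambda p: cerna.triad_table(triads).to_csv(p, sep="\t", index=False))
        emit("cerna_network.graphml",
             lambda p: cerna.write_network(network, p,
                                           out / "network_nodes.tsv",
                                           out / "network_edges.tsv"))
        manifest["network_summary"] = network.summary()

    # ---- enrichment of the DE mRNA set
    enrichment_results: list = []
    if "enrich" in config.stages and de_sets.get("mRNA"):
        term_map = enrich.read_term_map(config.path("terms"))
        universe = set().union(*term_map.values()) | set(counts["mRNA"].gene_ids)
        enrichment_results = enrich.hypergeom_enrich(
            de_sets["mRNA"] & universe, term_map, universe,
            alpha=config.threshold("enrich_alpha"))
        emit("enrichment_de_mrna.tsv",
             lambda p: enrich.enrichment_table(enrichment_results).to_csv(
                 p, sep="\t", index=False))

    emit("manifest.json",
         lambda p: Path(p).write_text(json.dumps(manifest, indent=1, sort_keys=True)))
    return PipelineResult(
        de_tables=de_tables, de_sets=de_sets, expr_by_class=expr_by_class,
        target_hits=target_hits, junctions=junctions, associations=associations,
        triads=triads, network=network, enrichment=enrichment_results,
        profile_results=profile_results, manifest=manifest,
    )
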
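"""Synthetic staged-transcriptome scenarios with known ground truth.

One scenario emulates the study design every downstream stage expects:
an ordered series of stages (default 4, named after the albinism cycle
Bud/Alb/Med/Gre) with replicates (default 3), four RNA classes with
integer count matrices, a single random chromosome carrying the gene
models, transcript and miRNA sequences, back-splice-spanning reads, and
a term map -- plus a ground-truth record of everything planted:

* **ceRNA triads**: the ceRNA (lncRNA or circRNA, alternating) and the
  mRNA share strictly monotone stage means proportional to each other,
  while their miRNA's means run strictly monotone the opposite way, so
  at the mean level Spearman(miRNA, target) = -1 and
  Pearson(ceRNA, mRNA) = +1.  Exact reverse-complement binding sites of
  the miRNA are embedded in both targets at recorded positions.
* **DE genes**: a fraction of background mRNAs/lncRNAs/circRNAs/miRNAs
  get a fold-change step between the first and second half of the
  stages; all remaining background genes have stage-constant means, so
  spurious DE calls and triads can only arise from sampling noise.
* **back-splice junctions**: each circRNA is a genomic interval whose
  plus-strand flanks carry the canonical splice dinucleotides (GT after
  the donor, AG before the acceptor, reverse-complemented for minus
  strand), covered by the configured number of distinct junction-
  spanning reads.
* **an enriched term**: one term of the term map is loaded with planted
  DE mRNAs; the rest draw genes uniformly.

Counts are negative binomial with variance mu + d*mu^2 (d = 0 gives
Poisson); ``noise_free=True`` replaces sampling by rounded stage means.
Reads are error-free.  The same (config, seed) always reproduces
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._util import revcomp, spawn_rng
from .gffio import GeneModel, write_fasta, write_gff3

STAGE_NAMES_4 = ("Bud", "Alb", "Med", "Gre")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioConfig:
    seed: int
    n_stages: int = 4
    n_reps: int = 3
    n_mrna: int = 60
    n_lncrna: int = 24
    n_circrna: int = 12
    n_mirna: int = 16
    n_triads: int = 6
    nb_dispersion: float = 0.05
    fold_change: float = 4.0
    noise_free: bool = False
    read_length: int = 50
    junction_support: int = 5
    n_background_reads: int = 400
    de_fraction: float = 0.2     # fraction of background genes given a DE step
    n_terms: int = 15
    mirna_length: int = 21
    chrom_len: int | None = None  # None: sized automatically

    def __post_init__(self):
        if self.n_stages < 2 or self.n_reps < 2:
            raise ConfigurationError("need n_stages >= 2 and n_reps >= 2")
        if min(self.n_mrna, self.n_lncrna, self.n_circrna, self.n_mirna,
               self.n_triads) < 0:
            raise ConfigurationError("entity counts must be >= 0")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.fold_change <= 1:
            raise ConfigurationError("fold_change must be > 1")
        n_lnc_cer = (self.n_triads + 1) // 2
        n_circ_cer = self.n_triads // 2
        if (self.n_triads > self.n_mrna or self.n_triads > self.n_mirna
                or n_lnc_cer > self.n_lncrna or n_circ_cer > self.n_circrna):
            raise ConfigurationError("n_triads exceeds available molecules")

    @property
    def stage_names(self) -> tuple[str, ...]:
        if self.n_stages == 4:
            return STAGE_NAMES_4
        return tuple(f"S{i}" for i in range(self.n_stages))

    @property
    def sample_names(self) -> list[str]:
        return [f"{st}_{r + 1}" for st in self.stage_names
                for r in range(self.n_reps)]


@dataclass
class GroundTruth:
    planted_triads: list[tuple[str, str, str]]  # (ceRNA, miRNA, mRNA)
    planted_de: dict[str, dict[str, str]]       # gene -> contrast -> up/down
    planted_sites: list[tuple[str, str, int]]   # (miRNA, target, 1-based pos)
    planted_junctions: list[tuple[str, int, int, str]]  # chrom, acceptor0, donor0, strand
    enriched_terms: list[str]
    planted_profiles: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "planted_triads": [list(t) for t in self.planted_triads],
                "planted_de": self.planted_de,
                "planted_sites": [list(s) for s in self.planted_sites],
                "planted_junctions": [list(j) for j in self.planted_junctions],
                "enriched_terms": self.enriched_terms,
                "planted_profiles": self.planted_profiles,
            }, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            planted_triads=[tuple(t) for t in d["planted_triads"]],
            planted_de=d["planted_de"],
            planted_sites=[tuple(s) for s in d["planted_sites"]],
            planted_junctions=[tuple(j) for j in d["planted_junctions"]],
            enriched_terms=d["enriched_terms"],
            planted_profiles={k: int(v) for k, v in d["planted_profiles"].items()},
        )


# ---------------------------------------------------------------- geometry

_MRNA_EXON1 = 360
_MRNA_INTRON = 90
_MRNA_EXON2 = 210
_LNC_LEN = 420
_CIRC_HOST_LEN = 420
_CIRC_OFFSET = 80    # circle start within its host exon
_CIRC_LEN = 240
_GAP = 120
_SITE_OFFSET = 60    # site position within the first transcript exon (0-based)
_CIRC_SITE_OFFSET = 40


@dataclass
class _Layout:
    chrom: str
    chrom_len: int
    mrna: list[GeneModel]
    lnc: list[GeneModel]
    circ_host: list[GeneModel]
    circles: list[dict]  # circ_id, start/end (1-based), strand


def _build_layout(cfg: ScenarioConfig) -> _Layout:
    pos = 200  # 0-based cursor
    chrom = "chr1"
    mrna, lnc, hosts, circles = [], [], [], []
    for i in range(cfg.n_mrna):
        strand = "+" if i % 2 == 0 else "-"
        s = pos
        e1 = (s + 1, s + _MRNA_EXON1)
        e2 = (s + _MRNA_EXON1 + _MRNA_INTRON + 1,
              s + _MRNA_EXON1 + _MRNA_INTRON + _MRNA_EXON2)
        mrna.append(GeneModel(f"mrna_{i:04d}", chrom, e1[0], e2[1], strand,
                              "protein_coding", [e1, e2]))
        pos = e2[1] + _GAP
    for i in range(cfg.n_lncrna):
        strand = "+" if i % 2 == 0 else "-"
        s = pos
        lnc.append(GeneModel(f"lnc_{i:04d}", chrom, s + 1, s + _LNC_LEN, strand,
                             "lncRNA", [(s + 1, s + _LNC_LEN)]))
        pos = s + _LNC_LEN + _GAP
    for i in range(cfg.n_circrna):
        strand = "+" if i % 2 == 0 else "-"
        s = pos
        hosts.append(GeneModel(f"circhost_{i:04d}", chrom, s + 1,
                               s + _CIRC_HOST_LEN, strand, "protein_coding",
                               [(s + 1, s + _CIRC_HOST_LEN)]))
        c_start = s + _CIRC_OFFSET + 1  # 1-based
        circles.append({"circ_id": f"circ_{i:04d}", "chrom": chrom,
                        "start": c_start, "end": c_start + _CIRC_LEN - 1,
                        "strand": strand})
        pos = s + _CIRC_HOST_LEN + _GAP
    total = pos + 200
    if cfg.chrom_len is not None:
        if cfg.chrom_len < total:
            raise ConfigurationError(
                f"chrom_len {cfg.chrom_len} too small for layout ({total} bp)")
        total = cfg.chrom_len
    return _Layout(chrom, total, mrna, lnc, hosts, circles)


def _first_exon(gene: GeneModel) -> tuple[int, int]:
    """Genomic span of the transcript's first exon (rightmost for minus)."""
    exons = sorted(gene.exons)
    return exons[-1] if gene.strand == "-" else exons[0]


def _write_transcript_region(genome: np.ndarray, gene_strand: str,
                             region: tuple[int, int], t_offset: int,
                             site_dna: str) -> None:
    """Write ``site_dna`` (transcript sense) at transcript offset
    ``t_offset`` of an exon region (1-based inclusive span)."""
    s1, e1 = region
    k = len(site_dna)
    if gene_strand == "+":
        g0 = (s1 - 1) + t_offset
        genome[g0:g0 + k] = np.frombuffer(site_dna.encode(), dtype=np.uint8)
    else:
        g0 = (e1 - 1) - t_offset - (k - 1)
        genome[g0:g0 + k] = np.frombuffer(revcomp(site_dna).encode(), dtype=np.uint8)


def _extract(genome: np.ndarray, gene: GeneModel) -> str:
    parts = [genome[s - 1:e].tobytes().decode() for s, e in sorted(gene.exons)]
    seq = "".join(parts)
    return revcomp(seq) if gene.strand == "-" else seq


def _extract_span(genome: np.ndarray, start1: int, end1: int, strand: str) -> str:
    seq = genome[start1 - 1:end1].tobytes().decode()
    return revcomp(seq) if strand == "-" else seq


def _disrupt_orfs(genome: np.ndarray, gene: GeneModel,
                  protect: tuple[int, int] | None, max_codons: int = 100) -> None:
    """Mutate in-frame stop codons into long ORFs of a lncRNA transcript
    so it passes the non-coding filter, avoiding the protected
    transcript interval (a planted binding site)."""
    from .lncrna import STOP_CODONS, longest_orf_codons

    region = sorted(gene.exons)[0]
    for _ in range(20):
        seq = _extract(genome, gene)
        if longest_orf_codons(seq) <= max_codons:
            return
        # locate the longest ORF and stop it mid-way
        best = None
        s = seq
        for frame in range(3):
            i, open_start = frame, None
            while i + 3 <= len(s):
                codon = s[i:i + 3]
                if open_start is None and codon == "ATG":
                    open_start = i
                elif open_start is not None and codon in STOP_CODONS:
                    if best is None or (i - open_start) > best[1] - best[0]:
                        best = (open_start, i)
                    open_start = None
                i += 3
            if open_start is not None:
                end = frame + ((len(s) - frame) // 3) * 3
                if best is None or (end - open_start) > best[1] - best[0]:
                    best = (open_start, end)
        assert best is not None
        orf_s, orf_e = best
        placed = False
        for cod in range(orf_s + 3 * (max_codons // 2), orf_e - 2, 3):
            if protect and not (cod + 2 < protect[0] or cod > protect[1]):
                continue
            _write_transcript_region(genome, gene.strand, region, cod, "TAA")
            placed = True
            break
        if not placed:  # fall back to any in-frame codon after the start
            for cod in range(orf_s + 3, orf_e - 2, 3):
                if protect and not (cod + 2 < protect[0] or cod > protect[1]):
                    continue
                _write_transcript_region(genome, gene.strand, region, cod, "TAA")
                break


# ---------------------------------------------------------------- means

def _stage_profile(base: float, fc: float, n_stages: int, direction: str) -> np.ndarray:
    """Strictly monotone geometric stage means."""
    ramp = fc ** np.arange(n_stages, dtype=float)
    return base * (ramp if direction == "up" else ramp[::-1])


def _step_profile(base: float, fc: float, n_stages: int, direction: str) -> np.ndarray:
    half = n_stages // 2
    lo, hi = (base, base * fc) if direction == "up" else (base * fc, base)
    return np.array([lo] * half + [hi] * (n_stages - half), dtype=float)


def _sample_counts(means: np.ndarray, cfg: ScenarioConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """genes x (stages*reps) counts from per-stage means."""
    mu = np.repeat(means, cfg.n_reps, axis=1)
    if cfg.noise_free:
        return np.rint(mu).astype(int)
    d = cfg.nb_dispersion
    if d == 0:
        return rng.poisson(mu)
    n_param = 1.0 / d
    p_param = n_param / (n_param + mu)
    return rng.negative_binomial(n_param, p_param)


def _contrast_directions(means: np.ndarray, stages: tuple[str, ...]) -> dict[str, str]:
    """Contrasts (earlier vs later) where the planted |log2 ratio| > 1."""
    out = {}
    for i in range(len(stages)):
        for j in range(i + 1, len(stages)):
            if means[i] <= 0 or means[j] <= 0:
                continue
            lfc = np.log2(means[j] / means[i])
            if abs(lfc) > 1:
                out[f"{stages[i]}_vs_{stages[j]}"] = "up" if lfc > 0 else "down"
    return out


# ---------------------------------------------------------------- scenario

def simulate_scenario(config: ScenarioConfig,
                      out_dir: str | Path) -> tuple[dict[str, Path], GroundTruth]:
    """Generate a full dataset bundle under ``out_dir``.

    Returns ({artifact name: path}, GroundTruth).  Emitted files:
    genome.fa, annotation.gff3, transcripts.fa, mirnas.fa,
    counts_{mrna,lncrna,circrna,mirna}.tsv, reads.fa, terms.tsv,
    truth.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config
    layout = _build_layout(cfg)
    stages = cfg.stage_names

    rng_genome = spawn_rng(cfg.seed, "genome")
    genome = rng_genome.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8), size=layout.chrom_len)

    # canonical splice flanks for every circle
    for c in layout.circles:
        a0, d0 = c["start"] - 1, c["end"] - 1  # 0-based
        before, after = (("AG", "GT") if c["strand"] == "+" else ("AC", "CT"))
        genome[a0 - 2:a0] = np.frombuffer(before.encode(), dtype=np.uint8)
        genome[d0 + 1:d0 + 3] = np.frombuffer(after.encode(), dtype=np.uint8)

    # triad membership: ceRNA alternates lncRNA / circRNA
    mirna_ids = [f"mir_{i:04d}" for i in range(cfg.n_mirna)]
    rng_mir = spawn_rng(cfg.seed, "mirna-seqs")
    mirna_seqs = {
        mid: "".join(rng_mir.choice(list("ACGT"), size=cfg.mirna_length))
        for mid in mirna_ids
    }
    triads: list[tuple[str, str, str]] = []
    planted_sites: list[tuple[str, str, int]] = []
    site_protect: dict[str, tuple[int, int]] = {}
    for t in range(cfg.n_triads):
        mrna = layout.mrna[t]
        mir = mirna_ids[t]
        site = revcomp(mirna_seqs[mir])  # exact reverse complement, DNA letters
        if t % 2 == 0:
            cer_gene = layout.lnc[t // 2]
            cer_id = cer_gene.gene_id
            _write_transcript_region(genome, cer_gene.strand,
                                     _first_exon(cer_gene), _SITE_OFFSET, site)
            planted_sites.append((mir, cer_id, _SITE_OFFSET + 1))
            site_protect[cer_id] = (_SITE_OFFSET, _SITE_OFFSET + len(site) - 1)
        else:
            circle = layout.circles[t // 2]
            cer_id = circle["circ_id"]
            _write_transcript_region(
                genome, circle["strand"], (circle["start"], circle["end"]),
                _CIRC_SITE_OFFSET, site)
            planted_sites.append((mir, cer_id, _CIRC_SITE_OFFSET + 1))
        _write_transcript_region(genome, mrna.strand, _first_exon(mrna),
                                 _SITE_OFFSET, site)
        planted_sites.append((mir, mrna.gene_id, _SITE_OFFSET + 1))
        triads.append((cer_id, mir, mrna.gene_id))

    # lncRNAs must pass the non-coding filter (length > 200, ORF <= 100 codons)
    for gene in layout.lnc:
        _disrupt_orfs(genome, gene, site_protect.get(gene.gene_id))

    # ---------------- stage means and counts
    rng_means = spawn_rng(cfg.seed, "means")
    planted_de: dict[str, dict[str, str]] = {}

    def _class_means(ids: list[str], triad_role: dict[str, int],
                     n_bg_de: int) -> np.ndarray:
        means = np.zeros((len(ids), cfg.n_stages))
        bg_done = 0
        for i, gid in enumerate(ids):
            # integer bases keep noise-free rounded counts exactly
            # proportional across a triad (Pearson exactly +1)
            base = float(rng_means.integers(60, 141))
            if gid in triad_role:
                t = triad_role[gid]
                direction = "up" if t % 2 == 0 else "down"
                if gid.startswith("mir"):
                    direction = "down" if direction == "up" else "up"
                means[i] = _stage_profile(base, cfg.fold_change,
                                          cfg.n_stages, direction)
                planted_de[gid] = _contrast_directions(means[i], stages)
            elif bg_done < n_bg_de:
                direction = "up" if bg_done % 2 == 0 else "down"
                means[i] = _step_profile(base, cfg.fold_change,
                                         cfg.n_stages, direction)
                planted_de[gid] = _contrast_directions(means[i], stages)
                bg_done += 1
            else:
                means[i] = base
        return means

    mrna_ids = [g.gene_id for g in layout.mrna]
    lnc_ids = [g.gene_id for g in layout.lnc]
    circ_ids = [c["circ_id"] for c in layout.circles]
    triad_mrna = {m: t for t, (_, _, m) in enumerate(triads)}
    triad_cer = {c: t for t, (c, _, _) in enumerate(triads)}
    triad_mir = {m: t for t, (_, m, _) in enumerate(triads)}

    def n_bg(ids, role):
        return int(round(cfg.de_fraction * (len(ids) - len(set(ids) & set(role)))))

    means_by_class = {
        "mrna": _class_means(mrna_ids, triad_mrna, n_bg(mrna_ids, triad_mrna)),
        "lncrna": _class_means(lnc_ids, triad_cer, n_bg(lnc_ids, triad_cer)),
        "circrna": _class_means(circ_ids, triad_cer, n_bg(circ_ids, triad_cer)),
        "mirna": _class_means(mirna_ids, triad_mir, n_bg(mirna_ids, triad_mir)),
    }
    rng_counts = spawn_rng(cfg.seed, "counts")
    counts_by_class = {
        cls: _sample_counts(m, cfg, rng_counts) for cls, m in means_by_class.items()
    }

    # ---------------- reads
    h = cfg.read_length // 2
    reads: list[tuple[str, str]] = []
    junctions: list[tuple[str, int, int, str]] = []
    for c in layout.circles:
        t_seq = _extract_span(genome, c["start"], c["end"], c["strand"])
        junctions.append((c["chrom"], c["start"] - 1, c["end"] - 1, c["strand"]))
        for r in range(cfg.junction_support):
            shift = r % max(1, h - 20 + 1)  # keep both anchors within a segment
            left = h + shift
            read = t_seq[-left:] + t_seq[:cfg.read_length - left]
            reads.append((f"bs_{c['circ_id']}_{r}", read))
    rng_reads = spawn_rng(cfg.seed, "reads")
    for i in range(cfg.n_background_reads):
        p = int(rng_reads.integers(0, layout.chrom_len - cfg.read_length))
        seq = genome[p:p + cfg.read_length].tobytes().decode()
        if rng_reads.random() < 0.5:
            seq = revcomp(seq)
        reads.append((f"lin_{i:05d}", seq))

    # ---------------- term map: one enriched term over planted DE mRNAs
    rng_terms = spawn_rng(cfg.seed, "terms")
    de_mrnas = [g for g in mrna_ids if g in planted_de]
    term_rows: list[tuple[str, str]] = []
    enriched_genes = (list(rng_terms.choice(de_mrnas, size=min(12, len(de_mrnas)),
                                            replace=False))
                      if de_mrnas else [])
    for g in enriched_genes:
        term_rows.append(("term_enriched", g))
    for ti in range(cfg.n_terms):
        size = int(rng_terms.integers(6, 16))
        size = min(size, len(mrna_ids))
        for g in rng_terms.choice(mrna_ids, size=size, replace=False):
            term_rows.append((f"term_{ti:04d}", g))

    # ---------------- planted trend profiles of triad targets
    from .trends import TrendConfig, TrendVector, _assign_matrix, generate_model_profiles

    planted_profiles: dict[str, int] = {}
    if cfg.n_triads:
        tc = TrendConfig(T=cfg.n_stages)
        profs = generate_model_profiles(tc)
        models = np.array([p.model for p in profs], dtype=float)
        flat_id = next(i for i, p in enumerate(profs)
                       if all(v == 0 for v in p.model))
        rows, row_genes = [], []
        for cls, ids in (("mrna", mrna_ids), ("lncrna", lnc_ids),
                         ("circrna", circ_ids)):
            for i, gid in enumerate(ids):
                if gid in triad_mrna or gid in triad_cer:
                    v = means_by_class[cls][i]
                    u = np.zeros(cfg.n_stages)
                    u[1:] = np.log2((v[1:] + 1.0) / (v[0] + 1.0))
                    rows.append(u)
                    row_genes.append(gid)
        if rows:
            assign = _assign_matrix(np.array(rows), models, flat_id)
            planted_profiles = {g: profs[a].profile_id
                                for g, a in zip(row_genes, assign)}

    # ---------------- emit files
    bundle: dict[str, Path] = {}

    def _p(name: str) -> Path:
        bundle[name] = out_dir / name
        return bundle[name]

    write_fasta({layout.chrom: genome.tobytes().decode()}, _p("genome.fa"))
    write_gff3(layout.mrna + layout.lnc + layout.circ_host,
               _p("annotation.gff3"), circ_features=layout.circles)
    transcripts = {g.gene_id: _extract(genome, g)
                   for g in layout.mrna + layout.lnc}
    transcripts.update({c["circ_id"]: _extract_span(genome, c["start"], c["end"],
                                                    c["strand"])
                        for c in layout.circles})
    write_fasta(transcripts, _p("transcripts.fa"))
    write_fasta(mirna_seqs, _p("mirnas.fa"))
    sample_cols = cfg.sample_names
    for cls, ids in (("mrna", mrna_ids), ("lncrna", lnc_ids),
                     ("circrna", circ_ids), ("mirna", mirna_ids)):
        df = pd.DataFrame(counts_by_class[cls], index=ids, columns=sample_cols)
        df.to_csv(_p(f"counts_{cls}.tsv"), sep="\t", index_label="gene_id")
    write_fasta(dict(reads), _p("reads.fa"))
    pd.DataFrame(term_rows).to_csv(_p("terms.tsv"), sep="\t", header=False,
                                   index=False)
    truth = GroundTruth(
        planted_triads=triads,
        planted_de=planted_de,
        planted_sites=planted_sites,
        planted_junctions=junctions,
        enriched_terms=["term_enriched"] if enriched_genes else [],
        planted_profiles=planted_profiles,
    )
    truth.to_json(_p("truth.json"))
    (out_dir / "config.json").write_text(json.dumps(asdict(cfg), indent=1))
    bundle["config.json"] = out_dir / "config.json"
    return bundle, truth


# ---------------------------------------------------------------- recovery

@dataclass
class RecoveryReport:
    precision: float
    recall: float
    precision_undefined: bool
    n_true: int
    n_predicted: int
    n_hit: int
    hit_table: pd.DataFrame  # per true triad: recovered yes/no
    spurious: list[tuple[str, str, str]]


def _canon(triad) -> tuple[str, str, str]:
    if hasattr(triad, "key"):
        return tuple(triad.key)
    return tuple(triad)


def evaluate_recovery(predicted: Iterable, truth: GroundTruth) -> RecoveryReport:
    """Precision/recall of predicted triads against the planted set.

    Precision is flagged undefined (reported as 0) when nothing was
    predicted but true triads exist.
    """
    pred = {_canon(t) for t in predicted}
    true = {_canon(t) for t in truth.planted_triads}
    hit = pred & true
    recall = len(hit) / len(true) if true else 1.0
    undefined = len(pred) == 0 and len(true) > 0
    precision = 0.0 if undefined else (len(hit) / len(pred) if pred else 1.0)
    table = pd.DataFrame(
        [{"cerna_id": c, "mirna_id": m, "mrna_id": g, "recovered": (c, m, g) in hit}
         for c, m, g in sorted(true)])
    return RecoveryReport(
        precision=precision, recall=recall, precision_undefined=undefined,
        n_true=len(true), n_predicted=len(pred), n_hit=len(hit),
        hit_table=table, spurious=sorted(pred - true),
    )
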
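"""Back-splice junction detection from reads, RPM quantification, and
junction context classification.

The caller follows the anchor strategy for head-to-tail reads: the two
``anchor_len`` ends of each read must each map uniquely and exactly to
the reference, with the tail anchor landing genomically *upstream* of
the head anchor (the reverse of a linear read).  The anchors are then
extended toward the read interior; the breakpoint must reconstruct the
complete read with zero mismatches and place canonical GU/AG splice
dinucleotides (GT/AG in genomic plus-strand letters) at the flanks.
Reads with no such breakpoint, or with ambiguous/missing anchor hits,
are skipped.  A junction is reported only with at least ``min_support``
unique supporting reads ("unique" = distinct read ids by default; a
flag switches to distinct read sequences).

Coordinates are 0-based internally.  ``acceptor_pos``/``donor_pos`` are
the genomic start/end of the circle in the plus-strand frame, so
``acceptor_pos < donor_pos`` always holds; for minus-strand junctions
the genomic plus-strand flanks are the reverse complement (CT upstream
... AC downstream) and the recorded splice signal stays "GTAG" in
transcript sense.  When several zero-mismatch GT/AG-consistent
breakpoints exist the leftmost donor coordinate wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

from ._util import revcomp
from .gffio import GeneModel


@dataclass
class BackspliceJunction:
    chrom: str
    acceptor_pos: int  # 0-based genomic start of the circle
    donor_pos: int     # 0-based genomic end of the circle
    strand: str
    splice_signal: str = "GTAG"  # transcript-sense donor + acceptor dinucleotides
    support: int = 0
    read_ids: set[str] = field(default_factory=set)
    rpm: float = float("nan")
    circ_type: str = ""

    def __post_init__(self):
        if self.acceptor_pos >= self.donor_pos:
            raise ValueError("acceptor_pos must precede donor_pos")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.acceptor_pos, self.donor_pos, self.strand)


def _load_reads(reads) -> list[tuple[str, str]]:
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
        parsed = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), fmt)]
        if not parsed:
            raise ValueError(f"{path}: no reads parsed (malformed or empty)")
        return parsed
    return [(rid, seq.upper()) for rid, seq in reads]


def _load_reference(reference) -> dict[str, str]:
    if isinstance(reference, (str, Path)):
        return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(reference), "fasta")}
    return {k: v.upper() for k, v in reference.items()}


def _unique_locus(genome: Mapping[str, str], kmer: str) -> tuple[str, int] | None:
    """Exactly one exact-match locus across all chromosomes, else None."""
    found: tuple[str, int] | None = None
    for chrom, seq in genome.items():
        start = seq.find(kmer)
        while start != -1:
            if found is not None:
                return None
            found = (chrom, start)
            start = seq.find(kmer, start + 1)
    return found


# genomic plus-strand flank dinucleotides by strand: (after donor, before acceptor)
_FLANKS = {"+": ("GT", "AG"), "-": ("CT", "AC")}


def _breakpoint(genome_seq: str, seq: str, head_pos: int, tail_pos: int,
                anchor_len: int, strand: str) -> tuple[int, int] | None:
    """Find the leftmost-donor zero-mismatch breakpoint with correct flanks.

    ``seq`` is the read in the plus-strand frame; its prefix extends
    from ``head_pos`` (downstream segment, ending at the donor) and its
    suffix ends at ``tail_pos + anchor_len - 1`` (upstream segment,
    starting at the acceptor).
    """
    L = len(seq)
    tail_end = tail_pos + anchor_len - 1
    want_donor_flank, want_acc_flank = _FLANKS[strand]
    for k in range(anchor_len, L - anchor_len + 1):
        donor = head_pos + k - 1
        acceptor = tail_end - (L - k) + 1
        if acceptor >= donor:
            continue
        if acceptor - 2 < 0 or donor + 3 > len(genome_seq):
            continue
        if genome_seq[head_pos:head_pos + k] != seq[:k]:
            continue
        if genome_seq[acceptor:tail_end + 1] != seq[k:]:
            continue
        if genome_seq[donor + 1:donor + 3] != want_donor_flank:
            continue
        if genome_seq[acceptor - 2:acceptor] != want_acc_flank:
            continue
        return acceptor, donor
    return None


def detect_backsplice(reads, reference, anchor_len: int = 20,
                      min_support: int = 2,
                      unique_by: str = "id") -> list[BackspliceJunction]:
    """Call back-splice junctions from error-free reads.

    ``reads``: FASTA/FASTQ path or iterable of (read_id, sequence);
    ``reference``: FASTA path or {chrom: sequence}.  Returns junctions
    with >= ``min_support`` unique supporting reads, deterministically
    ordered; the result is invariant to the read input order.
    """
    if unique_by not in ("id", "sequence"):
        raise ValueError("unique_by must be 'id' or 'sequence'")
    genome = _load_reference(reference)
    read_list = _load_reads(reads)
    agg: dict[tuple[str, int, int, str], set[str]] = {}
    for rid, rseq in read_list:
        if len(rseq) < 2 * anchor_len:
            continue
        for strand in "+-":
            seq = rseq if strand == "+" else revcomp(rseq)
            head = _unique_locus(genome, seq[:anchor_len])
            if head is None:
                continue
            tail = _unique_locus(genome, seq[-anchor_len:])
            if tail is None:
                continue
            chrom_h, head_pos = head
            chrom_t, tail_pos = tail
            # back-splice geometry: same chromosome, tail anchor upstream
            if chrom_h != chrom_t or tail_pos >= head_pos:
                continue
            bp = _breakpoint(genome[chrom_h], seq, head_pos, tail_pos,
                             anchor_len, strand)
            if bp is None:
                continue
            acceptor, donor = bp
            key = (chrom_h, acceptor, donor, strand)
            agg.setdefault(key, set()).add(rid if unique_by == "id" else rseq)
            break  # one junction per read
        else:
            logger.debug("read %s: no unique back-splice placement", rid)
    junctions = []
    for (chrom, acceptor, donor, strand), members in sorted(agg.items()):
        if len(members) < min_support:
            continue
        junctions.append(BackspliceJunction(
            chrom=chrom, acceptor_pos=acceptor, donor_pos=donor, strand=strand,
            splice_signal="GTAG", support=len(members), read_ids=members,
        ))
    return junctions


def quantify_junctions(junctions: list[BackspliceJunction],
                       total_mapped_reads: int) -> list[BackspliceJunction]:
    """RPM = support * 1e6 / total mapped reads (in place; returns list)."""
    if total_mapped_reads < 1:
        raise ValueError("total_mapped_reads must be >= 1")
    for j in junctions:
        assert j.support >= 1, "junction without read support"
        j.rpm = j.support * 1e6 / total_mapped_reads
    return junctions


def classify_junction(junction: BackspliceJunction,
                      genes: Iterable[GeneModel]) -> str:
    """Classify a junction's genomic context against gene models.

    Same-strand overlapping gene: both breakpoints in one exon ->
    ``one_exon``; touching >= 2 exons (or exonic otherwise) ->
    ``exonic``; inside the gene without exon overlap -> ``intronic``.
    Otherwise opposite-strand overlap -> ``antisense``; no overlap ->
    ``intergenic``.  Fills and returns ``circ_type``.
    """
    # junction span in 1-based inclusive coordinates to match GFF3 models
    s1, e1 = junction.acceptor_pos + 1, junction.donor_pos + 1
    same, opposite = [], []
    for g in genes:
        if g.chrom != junction.chrom or g.end < s1 or g.start > e1:
            continue
        (same if g.strand == junction.strand else opposite).append(g)
    label = ""
    for g in same:
        exons = sorted(g.exons) or [(g.start, g.end)]
        n_touched = sum(1 for (xs, xe) in exons if xe >= s1 and xs <= e1)
        within_one = any(xs <= s1 and e1 <= xe for (xs, xe) in exons)
        if within_one:
            return _set_type(junction, "one_exon")
        if n_touched >= 2:
            label = label or "exonic"
        elif n_touched == 1:
            label = label or "exonic"
        elif g.start <= s1 and e1 <= g.end:
            label = label or "intronic"
    if label:
        return _set_type(junction, label)
    if opposite:
        return _set_type(junction, "antisense")
    return _set_type(junction, "intergenic")


def _set_type(junction: BackspliceJunction, label: str) -> str:
    junction.circ_type = label
    return label


def junction_table_rows(junctions: list[BackspliceJunction]) -> list[dict]:
    """1-based inclusive output rows for the junction TSV."""
    return [
        {"chrom": j.chrom, "acceptor": j.acceptor_pos + 1,
         "donor": j.donor_pos + 1, "strand": j.strand,
         "signal": j.splice_signal, "support": j.support,
         "rpm": j.rpm, "circ_type": j.circ_type}
        for j in junctions
    ]
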
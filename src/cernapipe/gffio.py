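"""GFF3 and FASTA I/O.

Gene models are held in a light dataclass; reading goes through
``gffutils`` (in-memory sqlite DB), FASTA through Biopython.  Writing
GFF3 is a plain line formatter because the emitted feature sets are
built de novo rather than edited from an existing database.

Coordinates follow GFF3: 1-based, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class GeneModel:
    """A gene with its exon structure (1-based inclusive coordinates)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.start > self.end:
            raise ValueError(f"start > end for {self.gene_id}")

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end

    def exon_union_length(self) -> int:
        """Total bp covered by the union of this gene's exons.

        Used as the gene length for FPKM/TPM normalization.
        """
        ivs = sorted(self.exons) or [(self.start, self.end)]
        total, cur_s, cur_e = 0, ivs[0][0], ivs[0][1]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        return total + (cur_e - cur_s + 1)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models (with exons) from a GFF3 file."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = sorted(
            (e.start, e.end) for e in db.children(g, featuretype="exon")
        )
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand,
                biotype=g.attributes.get("biotype", ["protein_coding"])[0],
                exons=exons,
            )
        )
    return genes


def read_circ_features(path: str | Path) -> list[dict]:
    """Read circRNA catalog entries (feature type ``circRNA``) from GFF3."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out = []
    for f in db.features_of_type("circRNA"):
        out.append(
            {
                "circ_id": f.id,
                "chrom": f.seqid,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
            }
        )
    return out


def write_gff3(genes: Iterable[GeneModel], path: str | Path,
               circ_features: Iterable[dict] = ()) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tcernapipe\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};biotype={g.biotype}\n"
            )
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tcernapipe\ttranscript\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(sorted(g.exons), 1):
                fh.write(
                    f"{g.chrom}\tcernapipe\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )
        for c in circ_features:
            fh.write(
                f"{c['chrom']}\tcernapipe\tcircRNA\t{c['start']}\t{c['end']}\t.\t"
                f"{c['strand']}\t.\tID={c['circ_id']}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> ordered {id: uppercase sequence}."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")
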
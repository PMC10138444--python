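"""lncRNA candidate filtering and lncRNA-mRNA association rules.

Candidate lncRNAs must be longer than 200 bp and carry no open reading
frame longer than 100 codons (ATG to stop, any forward frame of the
transcript) -- an explicit length + ORF heuristic.

Associations with mRNAs, a pair may carry several:

* ``antisense``: >= 1 bp genomic overlap on opposite strands;
* ``cis``: gene spans within 100 kb of each other (strand-agnostic,
  closest-end distance; overlapping same-strand pairs count as 0);
* ``trans``: expression Pearson correlation >= 0.999 over all samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .expression import ExpressionMatrix
from .gffio import GeneModel

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class LncRNAAssociation:
    lncrna_id: str
    mrna_id: str
    mechanism: str  # antisense | cis | trans
    distance_bp: int | None = None
    pearson_r: float | None = None


def longest_orf_codons(seq: str, require_stop: bool = False) -> int:
    """Longest ORF in codons (ATG..stop, forward frames; start codon
    counted, stop codon not).  Open-ended ORFs run to the sequence end
    unless ``require_stop``."""
    s = seq.upper().replace("U", "T")
    best = 0
    for frame in range(3):
        i = frame
        open_start = None
        while i + 3 <= len(s):
            codon = s[i:i + 3]
            if open_start is None and codon == "ATG":
                open_start = i
            elif open_start is not None and codon in STOP_CODONS:
                best = max(best, (i - open_start) // 3)
                open_start = None
            i += 3
        if open_start is not None and not require_stop:
            best = max(best, (i - open_start) // 3)
    return best


def filter_noncoding(transcripts: Mapping[str, str], min_len: int = 200,
                     max_orf_codons: int = 100) -> set[str]:
    """ids of transcripts with length > min_len and longest ORF <= max_orf_codons."""
    kept = set()
    for tid, seq in transcripts.items():
        if len(seq) > min_len and longest_orf_codons(seq) <= max_orf_codons:
            kept.add(tid)
    return kept


def span_distance(a: GeneModel, b: GeneModel) -> int | None:
    """Gap in bp between two gene spans (0 if they overlap or abut);
    None on different chromosomes."""
    if a.chrom != b.chrom:
        return None
    if a.end < b.start:
        return b.start - a.end - 1
    if b.end < a.start:
        return a.start - b.end - 1
    return 0


def _overlap(a: GeneModel, b: GeneModel) -> bool:
    return a.chrom == b.chrom and a.start <= b.end and b.start <= a.end


def associate(lnc_annot: Sequence[GeneModel], mrna_annot: Sequence[GeneModel],
              lnc_expr: ExpressionMatrix | None = None,
              mrna_expr: ExpressionMatrix | None = None,
              window: int = 100_000, r_min: float = 0.999,
              ) -> list[LncRNAAssociation]:
    """Assign antisense/cis/trans lncRNA-mRNA associations.

    Expression matrices are only needed for the trans rule; omitting
    them skips it.  ``cis`` uses a strict < ``window`` distance.
    """
    out: list[LncRNAAssociation] = []
    for ln in lnc_annot:
        for mr in mrna_annot:
            if _overlap(ln, mr) and ln.strand != mr.strand:
                out.append(LncRNAAssociation(ln.gene_id, mr.gene_id, "antisense",
                                             distance_bp=0))
            d = span_distance(ln, mr)
            if d is not None and d < window:
                out.append(LncRNAAssociation(ln.gene_id, mr.gene_id, "cis",
                                             distance_bp=d))
    if lnc_expr is not None and mrna_expr is not None:
        if lnc_expr.columns != mrna_expr.columns:
            raise ValueError("trans rule needs matching sample sets")
        L = lnc_expr.values - lnc_expr.values.mean(axis=1, keepdims=True)
        M = mrna_expr.values - mrna_expr.values.mean(axis=1, keepdims=True)
        ln_norm = np.linalg.norm(L, axis=1)
        mr_norm = np.linalg.norm(M, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            R = (L @ M.T) / np.outer(ln_norm, mr_norm)
        for i, lid in enumerate(lnc_expr.gene_ids):
            for j, mid in enumerate(mrna_expr.gene_ids):
                r = R[i, j]
                if np.isfinite(r) and r >= r_min:
                    out.append(LncRNAAssociation(lid, mid, "trans",
                                                 pearson_r=float(r)))
    out.sort(key=lambda a: (a.lncrna_id, a.mrna_id, a.mechanism))
    return out
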
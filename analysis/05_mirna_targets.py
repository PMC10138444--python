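"""Scan all transcripts for miRNA binding sites.

Penalty scoring: Watson-Crick 0, G:U wobble 0.5, mismatch 1, gap 2,
doubled at miRNA positions 2-13, cutoff 4.0.  circRNAs are scanned as
circles.  Every planted site (an exact reverse complement) must surface
as a penalty-0 hit at its recorded position.
"""

import pandas as pd

from _common import ensure_bundle, results_path
from cernapipe import gffio
from cernapipe.targeting import scan_targets

bundle, truth = ensure_bundle()
transcripts = gffio.read_fasta(bundle["transcripts.fa"])
mirnas = gffio.read_fasta(bundle["mirnas.fa"])
circ_ids = {c["circ_id"] for c in gffio.read_circ_features(bundle["annotation.gff3"])}

linear = {k: v for k, v in transcripts.items() if k not in circ_ids}
circular = {k: v for k, v in transcripts.items() if k in circ_ids}
mrna = {k: v for k, v in linear.items() if k.startswith("mrna_")}
lnc = {k: v for k, v in linear.items() if k.startswith("lnc_")}

hits = (scan_targets(mirnas, mrna, "mRNA")
        + scan_targets(mirnas, lnc, "lncRNA")
        + scan_targets(mirnas, circular, "circRNA", circular=True))

pd.DataFrame([
    {"mirna_id": h.mirna_id, "target_id": h.target_id, "class": h.target_class,
     "start": h.start, "penalty": h.penalty}
    for h in hits
]).to_csv(results_path("05_target_hits.tsv"), sep="\t", index=False)

found = {(h.mirna_id, h.target_id, h.start) for h in hits if h.penalty == 0}
planted = set(map(tuple, truth.planted_sites))
print(f"{len(hits)} hits at penalty <= 4.0 "
      f"({len(mirnas)} miRNAs x {len(transcripts)} transcripts)")
print(f"planted sites recovered at penalty 0: "
      f"{len(found & planted)}/{len(planted)}")
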
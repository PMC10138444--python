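"""Detect back-splice junctions from reads and quantify them as RPM.

Head-to-tail anchor mapping with zero-mismatch extension; junctions
need canonical GU/AG flanks and >= 2 unique supporting reads.  Every
planted junction should be recovered exactly, with no false calls.
"""

import pandas as pd

from _common import ensure_bundle, results_path
from cernapipe import backsplice, gffio

bundle, truth = ensure_bundle()
junctions = backsplice.detect_backsplice(bundle["reads.fa"], bundle["genome.fa"])
n_reads = sum(1 for line in open(bundle["reads.fa"]) if line.startswith(">"))
backsplice.quantify_junctions(junctions, n_reads)
genes = gffio.read_gff3(bundle["annotation.gff3"])
for j in junctions:
    backsplice.classify_junction(j, genes)

pd.DataFrame(backsplice.junction_table_rows(junctions)).to_csv(
    results_path("06_junctions.tsv"), sep="\t", index=False)

got = {(j.chrom, j.acceptor_pos, j.donor_pos, j.strand) for j in junctions}
want = set(truth.planted_junctions)
types = pd.Series([j.circ_type for j in junctions]).value_counts().to_dict()
print(f"{len(junctions)} junctions from {n_reads} reads "
      f"(recall {len(got & want)}/{len(want)}, "
      f"false positives {len(got - want)})")
print(f"junction context: {types}")
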
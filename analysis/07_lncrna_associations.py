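"""Filter lncRNA candidates and assign antisense/cis/trans mRNA partners.

Candidates must exceed 200 bp with no ORF over 100 codons; cis pairs lie
within 100 kb, antisense pairs overlap on opposite strands, trans pairs
correlate at Pearson >= 0.999.
"""

import pandas as pd

from _common import ensure_bundle, results_path
from cernapipe import expression, gffio, lncrna

bundle, _ = ensure_bundle()
genes = gffio.read_gff3(bundle["annotation.gff3"])
transcripts = gffio.read_fasta(bundle["transcripts.fa"])
lengths = {g.gene_id: g.exon_union_length() for g in genes}

lnc_genes = [g for g in genes if g.biotype == "lncRNA"]
kept = lncrna.filter_noncoding(
    {g.gene_id: transcripts[g.gene_id] for g in lnc_genes})

lnc_counts = expression.read_counts(bundle["counts_lncrna.tsv"])
mrna_counts = expression.read_counts(bundle["counts_mrna.tsv"])
lnc_fpkm = expression.normalize(lnc_counts, lengths, "fpkm")
mrna_fpkm = expression.normalize(mrna_counts, lengths, "fpkm")

lnc_models = [g for g in lnc_genes if g.gene_id in kept]
mrna_models = [g for g in genes if g.gene_id in set(mrna_counts.gene_ids)]
assoc = lncrna.associate(
    lnc_models, mrna_models,
    lnc_fpkm.subset([g.gene_id for g in lnc_models]),
    mrna_fpkm.subset([g.gene_id for g in mrna_models]))

pd.DataFrame([a.__dict__ for a in assoc]).to_csv(
    results_path("07_lncrna_associations.tsv"), sep="\t", index=False)

by_mech = pd.Series([a.mechanism for a in assoc]).value_counts().to_dict()
print(f"{len(kept)}/{len(lnc_genes)} lncRNAs pass the non-coding filter")
print(f"{len(assoc)} lncRNA-mRNA associations: {by_mech}")
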
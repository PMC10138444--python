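"""Normalize counts (FPKM/TPM) and check replicate agreement.

Replicates of the same stage should correlate at r >= 0.8 on the
log2(FPKM+1) scale; the PCA should separate stages along PC1.
"""

from _common import ensure_bundle, results_path
from cernapipe import expression, gffio

bundle, _ = ensure_bundle()
genes = gffio.read_gff3(bundle["annotation.gff3"])
lengths = {g.gene_id: g.exon_union_length() for g in genes}

counts = expression.read_counts(bundle["counts_mrna.tsv"], annotation=genes)
fpkm = expression.normalize(counts, lengths, "fpkm")
fpkm.write_tsv(results_path("02_fpkm_mrna.tsv"))

qc = expression.replicate_qc(fpkm, k=3)
qc.pearson.round(4).to_csv(results_path("02_qc_pearson.tsv"), sep="\t")
qc.pca_scores.round(4).to_csv(results_path("02_qc_pca_scores.tsv"), sep="\t")

print(f"{counts.n_genes} mRNAs x {counts.n_samples} samples -> FPKM")
print(f"low-correlation replicate pairs (r < 0.8): {len(qc.low_pairs)}")
print("PC variance fractions:",
      [round(float(v), 3) for v in qc.pca_variance_fraction])
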
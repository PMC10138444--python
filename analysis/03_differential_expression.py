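"""Class-specific differential expression over all six stage contrasts.

mRNAs/lncRNAs are called at FDR < 0.05 and |log2FC| > 1; circRNAs and
miRNAs at raw p < 0.05 and |log2FC| > 1.  The planted DE genes should
be recovered with few spurious calls.
"""

import pandas as pd

from _common import ensure_bundle, results_path
from cernapipe import diffexpr, expression

bundle, truth = ensure_bundle()

rows = []
for cls, key in (("mRNA", "counts_mrna.tsv"), ("lncRNA", "counts_lncrna.tsv"),
                 ("circRNA", "counts_circrna.tsv"), ("miRNA", "counts_mirna.tsv")):
    counts = expression.read_counts(bundle[key])
    table = diffexpr.run_contrasts(counts, cls)
    table.to_csv(results_path(f"03_de_{cls.lower()}.tsv"), sep="\t", index=False)
    de = diffexpr.de_gene_set(table)
    planted = {g for g in truth.planted_de if g in set(counts.gene_ids)}
    rows.append({
        "class": cls, "n_genes": counts.n_genes, "n_de": len(de),
        "planted": len(planted), "recovered": len(de & planted),
        "spurious": len(de - planted),
    })
    print(f"{cls}: {len(de)} DE genes "
          f"({len(de & planted)}/{len(planted)} planted recovered, "
          f"{len(de - planted)} spurious)")

pd.DataFrame(rows).to_csv(results_path("03_de_summary.tsv"), sep="\t",
                          index=False)
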
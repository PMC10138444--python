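"""Cluster DE mRNAs into the 26 model expression trajectories.

Each DE gene's stage means are reduced to (0, log2(v1/v0), ...,
log2(v3/v0)) and assigned to the best-correlated model profile;
profile enrichment is a 1000-round permutation test with Bonferroni
correction over the 26 profiles.
"""

import numpy as np

from _common import SEED, ensure_bundle, results_path
from cernapipe import diffexpr, expression, gffio, trends

bundle, truth = ensure_bundle()
genes = gffio.read_gff3(bundle["annotation.gff3"])
lengths = {g.gene_id: g.exon_union_length() for g in genes}

counts = expression.read_counts(bundle["counts_mrna.tsv"])
fpkm = expression.normalize(counts, lengths, "fpkm")
de = sorted(diffexpr.de_gene_set(diffexpr.run_contrasts(counts, "mRNA")))

cfg = trends.TrendConfig(seed=SEED)
vectors = trends.vectors_from_stage_means(fpkm.subset(de).stage_means())
assignments, profiles = trends.assign_and_enrich(vectors, cfg)
assignments.to_csv(results_path("04_trend_assignments.tsv"), sep="\t",
                   index=False)
trends.profile_table(profiles).to_csv(results_path("04_trend_profiles.tsv"),
                                      sep="\t", index=False)

sig = [p for p in profiles if p.significant]
print(f"{len(de)} DE mRNAs assigned over {len(profiles)} model profiles")
print(f"significantly enriched profiles: "
      f"{[(p.profile_id, p.observed) for p in sig]}")

# planted triad/step genes must land on a profile trending in their
# planted direction (FPKM library scaling bends the curvature, so the
# exact model may differ from the one fit on raw means; the sign is the
# scale-free part of the trajectory)
models = {p.profile_id: p.model for p in profiles}
assigned = assignments.set_index("gene_id").profile_id
agree = total = 0
for g, prof in truth.planted_profiles.items():
    if g not in set(de):
        continue
    total += 1
    planted_dir = np.sign(sum(models[prof]))
    got_dir = np.sign(sum(models[int(assigned[g])]))
    agree += planted_dir == got_dir
print(f"planted trend-direction agreement: {agree}/{total}")
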
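"""Hypergeometric term enrichment of the DE mRNA set.

Upper-tail hypergeometric test of each term against the annotated
universe (p < 0.05, no multiplicity correction, matching the
genome-background convention).  The planted term should rank first.
"""

from _common import ensure_bundle, results_path
from cernapipe import diffexpr, expression
from cernapipe.enrich import enrichment_table, hypergeom_enrich, read_term_map

bundle, truth = ensure_bundle()
counts = expression.read_counts(bundle["counts_mrna.tsv"])
de = diffexpr.de_gene_set(diffexpr.run_contrasts(counts, "mRNA"))
term_map = read_term_map(bundle["terms.tsv"])
universe = set().union(*term_map.values()) | set(counts.gene_ids)

results = hypergeom_enrich(de & universe, term_map, universe)
enrichment_table(results).to_csv(results_path("09_enrichment.tsv"), sep="\t",
                                 index=False)

sig = [r for r in results if r.significant]
print(f"{len(de)} DE mRNAs against {len(term_map)} terms: "
      f"{len(sig)} enriched at p < 0.05")
print(f"top term: {results[0].term_id} (p = {results[0].p:.3g}); "
      f"planted enriched term: {truth.enriched_terms}")
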
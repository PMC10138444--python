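# cernapipe

Inference of competing endogenous RNA (ceRNA) networks from staged bulk
transcriptomes of four RNA classes: mRNA, lncRNA, circRNA and miRNA.

## The problem

In plants, temperature-dependent developmental series — such as the
periodic albinism cycle of white-leaf tea cultivars, sampled at four
stages (Bud, Alb, Med, Gre) with three biological replicates — produce
coordinated expression changes across coding and non-coding RNAs.
Under the ceRNA hypothesis, lncRNAs and circRNAs that carry miRNA
response elements sequester miRNAs away from their mRNA targets, so a
sponge and its protected mRNA rise and fall together while both run
opposite to the shared miRNA.

`cernapipe` implements the full inference chain that turns per-class
count matrices, annotations, sequences and reads into a
mRNA–miRNA–lncRNA/circRNA regulatory network:

1. **Normalization & QC** — FPKM/TPM; replicate Pearson matrix (pairs
   with r < 0.8 flagged) and covariance PCA on log2(x+1) columns.
2. **Differential expression** — an explicit negative-binomial Wald
   test over all pairwise stage contrasts with
   Benjamini–Hochberg adjustment. Class rules: mRNA/lncRNA need
   FDR < 0.05 and |log2FC| > 1; circRNA/miRNA need raw p < 0.05 and
   |log2FC| > 1 (all strict).
3. **Trend profiles** — DE genes are reduced to
   (0, log2(v1/v0), …, log2(v_{T−1}/v0)) and assigned by Pearson
   correlation to 26 model trajectories; profile enrichment by a
   permutation test with Bonferroni correction.
4. **miRNA target scanning** — plant-style complementarity penalties
   (Watson–Crick 0, G:U wobble 0.5, mismatch 1, gap 2; doubled at
   miRNA positions 2–13; ≤ 1 gap; cutoff 4.0). circRNAs are scanned as
   circles.
5. **circRNA detection** — a back-splice caller: head-to-tail anchor
   mapping, zero-mismatch breakpoint extension, canonical GU/AG flanks,
   ≥ 2 unique supporting reads, RPM quantification, junction-context
   classification (one_exon / exonic / intronic / antisense /
   intergenic).
6. **lncRNA associations** — length > 200 bp + ORF ≤ 100 codons
   non-coding filter; antisense (opposite-strand overlap), cis
   (< 100 kb) and trans (Pearson ≥ 0.999) mRNA partners.
7. **The two-step ceRNA screen** — among DE molecules with predicted
   sites, keep miRNA–target pairs with Spearman ρ < −0.3, join on the
   shared miRNA, and keep triads whose ceRNA–mRNA Pearson r > 0.5;
   assemble the bipartite network (every edge touches exactly one
   miRNA) and label component topology.
8. **Enrichment** — upper-tail hypergeometric term enrichment
   (p < 0.05) against a user-supplied term map.

A first-class synthetic-data generator (`cernapipe.simulate`) emits
complete dataset bundles — genome, GFF3, transcript/miRNA FASTA, count
matrices, junction-spanning reads, term map — with planted triads, DE
genes, binding sites, GT/AG junctions and an enriched term, plus the
ground truth needed to measure recovery.

## Worked example

```
cernapipe simulate --seed 3 --outdir bundle --n-mrna 30 --n-lncrna 12 \
    --n-circrna 6 --n-mirna 8 --n-triads 3
cernapipe run-all --bundle bundle --outdir out --seed 3
```

Or in Python, mirroring `analysis/08_cerna_network.py`:

```python
from cernapipe.pipeline import PipelineConfig, run_pipeline
from cernapipe.simulate import ScenarioConfig, simulate_scenario, evaluate_recovery

bundle, truth = simulate_scenario(ScenarioConfig(seed=2026), "bundle/")
result = run_pipeline(PipelineConfig.from_bundle("bundle/", "out/", seed=2026))
report = evaluate_recovery(result.triads, truth)
```

On the default scenario (60 mRNAs, 24 lncRNAs, 12 circRNAs, 16 miRNAs,
6 planted triads, NB dispersion 0.05, fold change 4) the numbered
drivers under `analysis/` print:

```
mRNA: 17 DE genes (17/17 planted recovered, 0 spurious)
12 junctions from 460 reads (recall 12/12, false positives 0)
planted sites recovered at penalty 0: 12/12
screen kept 6 triads (recall 1.00, precision 1.00, 0 spurious)
top term: term_enriched (p = 4.42e-09)
```

i.e. every planted sponge triad survives the two-step screen, every
planted junction is called exactly, and the planted annotation term
ranks first in the enrichment — with no spurious calls at the default
thresholds. Each driver writes its tables under `results/`.

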
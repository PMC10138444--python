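# Methods

This note documents the models, parameter choices and numerical
conventions behind `cernapipe`, and what the synthetic benchmarks do
and do not establish.

## Study design and data model

The pipeline assumes an ordered series of T stages (default 4, named
Bud/Alb/Med/Gre after the tea-leaf albinism cycle that motivates the
design) with r ≥ 2 replicates per stage, and four RNA classes measured
as integer count matrices over the same 12 samples. Counts are modeled
as negative binomial with variance μ + d·μ² (d = dispersion; d = 0
degenerates to Poisson).

## Normalization and QC

FPKM_ij = c_ij·10⁹/(L_i·N_j) with N_j the column sum; TPM_ij =
10⁶·(c_ij/L_i)/Σ_g(c_gj/L_g), so every nonzero TPM column sums to 10⁶
exactly. Gene length L is the union of exon lengths from the GFF3.
All-zero columns yield zero columns plus a warning rather than NaN.

Replicate QC computes the sample–sample Pearson matrix and a PCA, both
on log2(x+1)-transformed columns (the input transform is the package's
choice; covariance-based PCA with samples as observations). Within-
stage pairs with r < 0.8 (strict) are flagged; flagging is report-only
— excluding samples is an analyst decision, mirroring practice where a
deviating replicate may still be retained.

## Differential expression

For a contrast (A → B), counts are scaled by **median-of-ratios size
factors** (each column's factor is the median over all-positive genes
of count/row-geometric-mean, normalized to geometric mean 1, with a
total-count fallback below 10 usable genes). Column-sum scaling was
considered and rejected: when a block of genes trends strongly across
stages, column sums absorb the composition shift and constant genes
acquire a systematic fold change (≈1.5 log2 units, >50% spurious calls
in our benchmarks); ratio medians are robust to this, which is why
DESeq2 uses them.

log2FC = log2((mean_B+ε)/(mean_A+ε)) with ε = 0.5. The per-gene
dispersion is the pooled within-group moment estimate
d = (s² − μ)/μ², **moderated** toward the matrix-wide median dispersion
with a prior weight of 10 df and floored at 0.01. The Wald statistic
(log-mean difference over its delta-method standard error under NB
variance, Var(log mean) ≈ (1/μ + d)/n) is referred to Student-t with
(n_A + n_B − 2) + 10 df. Moderation and the matching t reference are
required for calibration: with 3 replicates a raw moment dispersion
under a normal reference rejects ~11% of true nulls at α = 0.05, while
an unmoderated t reference loses a quarter of genuine 4-fold changes;
the moderated test measures a null rejection rate of ~0.05 with full
recovery of planted 4-fold effects. This is the same device as limma's
moderated t and edgeR's squeezed dispersions.

BH adjustment is the step-up q_(i) = min_{j≥i} p_(j)·n/j, capped at 1,
applied within each contrast. Class rules (all strict inequalities):
mRNA/lncRNA significant iff FDR < 0.05 and |log2FC| > 1; circRNA/miRNA
iff raw p < 0.05 and |log2FC| > 1. All T·(T−1)/2 pairwise contrasts are
produced; a molecule counts as DE if significant in **any** contrast
(the network pools all stages, and per-contrast correlation at n = 3 is
not meaningful).

## Trend profiles

Candidate model profiles are all integer trajectories of length T
starting at 0 with steps in [−c, c] (27 for T = 4, c = 1); m = 26 are
kept by greedy max-min Euclidean selection seeded with the flat
profile, ties broken by enumeration order — deterministic. Genes enter
as (0, log2((v_i+1)/(v_0+1))) vectors of FPKM stage means (pseudocount
1) and are assigned to the profile maximizing Pearson correlation of
the 0-prefixed length-T series; all-zero vectors go to the flat profile
by convention, correlation ties to the lowest profile id. Profiles are
clustered on DE sets only.

Significance: each gene's stage series is permuted B = 1000 times
(permutation re-anchored at the new first stage, which is equivalent to
permuting the stage means), genes are reassigned, and profile k is
enriched when p_perm·m < α with p_perm the fraction of permutations
whose count reaches the observed one (Bonferroni over the m profiles).
On permutation-null data this flags ≤ 1 profile on average.

Note that library-size normalization bends trajectory *curvature*: a
gene planted with geometric means can be assigned to a neighboring
model of the same direction once FPKM scaling is applied. The sign of
the trajectory is the scale-free part; the analysis drivers therefore
report direction agreement for planted genes.

## miRNA target scanning

Penalty scheme per alignment column (miRNA reversed against the site,
antiparallel): Watson–Crick 0, G:U wobble 0.5 (both G·U and U·G),
mismatch 1.0, gap 2.0; penalties at miRNA positions 2–13 from the 5′
end are doubled; at most one gap; cutoff 4.0. This is the established
plant-target scoring convention (psRNATarget-style) and is a documented
stand-in — the scheme is explicit and oracle-checkable rather than a
reproduction of any specific external tool's settings.

Gap conventions (fixed here, mirrored by the brute-force oracle in the
tests): an unpaired miRNA base (site m−1 nt) is penalized at its own
position and may sit at either end; a bulged target base (site m+1 nt)
must be internal and takes the position of the alignment column it
occupies. Site windows of length m−1, m, m+1 are all scored; hits of
one (miRNA, target) pair whose windows overlap collapse to the
minimum-penalty window (ties: leftmost, then shortest). circRNAs are
scanned with the sequence doubled and hits deduplicated modulo the
length, so junction-spanning sites are found. For speed, transcripts
are concatenated with an `N` sentinel (penalized beyond any cutoff) and
each miRNA is scanned once over the concatenation with vectorized
prefix/suffix penalty sums.

## Back-splice detection

Anchors of 20 nt from both read ends must each map uniquely and exactly
to the reference with the tail anchor genomically upstream of the head
anchor (head-to-tail geometry). Breakpoints are found by exhaustive
split search: the complete read must reconstruct with zero mismatches
and canonical splice flanks — GT after the donor and AG before the
acceptor in plus-strand letters, CT/AC for minus-strand junctions.
Among multiple valid breakpoints the leftmost donor wins. A junction
needs ≥ 2 unique supporting reads; "unique" means distinct read ids by
default, with a flag for distinct sequences. RPM = support·10⁶/total
mapped reads.

Coordinates: acceptor_pos/donor_pos are the genomic start/end of the
circle in the plus-strand frame (so acceptor < donor always), with the
splice signal recorded in transcript sense ("GTAG"). Exact-match
anchor lookup over the in-memory reference replaces an external
aligner; with error-free reads exact matching is sufficient. Junction
context uses five labels (one_exon, exonic, intronic, antisense,
intergenic), precedence in that order for same-strand overlaps.

## lncRNA filtering and association

Non-coding candidates: length > 200 bp (strict) and longest ORF ≤ 100
codons (ATG→stop, any forward frame, start codon counted, stop not;
open-ended ORFs run to the sequence end). This explicit heuristic
stands in for coding-potential classifiers and can be bypassed by
supplying a pre-filtered list. Associations: antisense = ≥ 1 bp
opposite-strand genomic overlap; cis = closest-end span distance
< 100 kb, strand-agnostic (span-to-span, since "upstream or downstream"
fixes no anchor point); trans = Pearson ≥ 0.999 across all samples.
A pair may carry several mechanisms. Trans pairs annotate lncRNA–mRNA
relations; they do not feed the ceRNA screen (the screen is driven by
predicted miRNA sites).

## The two-step ceRNA screen

Candidate (miRNA, target) pairs come from the target map restricted to
DE molecules (circRNAs additionally restricted to detection-validated
junctions in the pipeline). Step 1 keeps pairs with Spearman ρ < −0.3
(average ranks, strict); step 2 joins on the shared miRNA and keeps
triads with ceRNA–mRNA Pearson r > 0.5 (strict). Correlations use all
samples. Pairwise correlations are computed as dot/√(ss_a·ss_b) on
centered vectors — not via pre-normalized rows — so boundary values
such as an exact −0.3 survive floating point and the strict comparison
behaves as stated. Undefined (constant-vector) correlations drop the
pair with a log entry rather than counting as 0. Output triads are
deduplicated and ordered (ceRNA, miRNA, mRNA) lexicographically.

The network places one node per molecule and one edge per
(miRNA, mRNA) and (miRNA, ceRNA) relation, so it is bipartite by
construction. Component topology labels are package definitions (the
source taxonomy is verbal): A if the component's best-connected miRNA
has degree ≥ 10 (hub-centred), B if ≥ 2 mRNAs each touch ≥ 2 miRNAs
(multi-miRNA coupling), else C; both thresholds configurable.

## Enrichment

Exact upper-tail hypergeometric P(X ≥ k) per term; k = 0 reports p = 1;
raw p < 0.05 calls enrichment (an optional BH switch exists but is off,
matching the genome-background convention). The universe defaults to
the term map's gene union and is configurable.

## Synthetic data: what it emulates and what it does not

The generator plants, on a single random chromosome: two-exon mRNA
genes, single-exon lncRNA genes, and circRNA intervals inside host
genes with canonical splice flanks written into the genome; exact
reverse-complement miRNA sites at recorded transcript positions; and
NB counts from per-stage means. Triad members get strictly monotone
geometric mean trajectories (base·fc^i for targets, reversed for the
miRNA, integer bases so noise-free rounded counts stay exactly
proportional), guaranteeing Spearman −1 / Pearson +1 at the mean level.
A configurable fraction (default 20%) of background genes receives a
half-series fold-change step; all other genes are stage-constant, so
spurious calls can only arise from sampling noise. Back-splice reads
tile the junction at varying offsets with ≥ 20 nt on both sides; a
configurable number of error-free linear background reads is added.
One term of the term map is loaded with planted DE mRNAs. lncRNA
sequences are post-edited (in-frame stops inserted outside planted
sites) until they pass the non-coding filter. Identical (config, seed)
reproduces byte-identical bundles.

Not emulated: realistic genome composition, isoform complexity,
sequencing error, batch effects, multi-sample circRNA libraries, or
library-size variation beyond what NB sampling induces. Passing the
benchmarks therefore demonstrates algorithmic correctness and
calibration under the stated noise model, not performance on real
sequencing data.

## Problem sizes and tolerances

The study-scale benchmark uses 4 stages × 3 replicates, 30 planted
triads over 530 mRNAs / 100 lncRNAs / 50 circRNAs / 50 miRNAs,
dispersion 0.05, fold change 4 — sizes chosen so the full pipeline
runs in well under a minute while keeping hundreds of null genes per
class for false-positive estimation. Back-splice exactness is measured
over 20 small scenarios; DE calibration on 2000 null genes at
dispersion 0.1; the trend permutation null on 500 genes × 1000
permutations. Oracle-equivalence checks compare implementations to
independent brute-force enumerations (≤ 1-gap alignments, min-over-
suffix BH, triple-loop screening with scipy correlations, exhaustive
hypergeometric draws) at tolerance 10⁻¹² or exact equality.

## Known limitations

* The NB test is a self-contained Wald test; it does not reproduce
  DESeq2/edgeR numerics (no shrinkage of fold changes, no exact tests).
* Model-profile identities follow the greedy max-min construction and
  are not claimed to match any external tool's profile numbering.
* The antisense rule is purely positional; no hybridization energetics.
* The back-splice caller requires exact anchor matches and is intended
  for error-free or pre-corrected reads.
* Correlation screening uses fixed thresholds on coefficients, not
  p-values; no multiplicity control is applied at the screening stage.
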
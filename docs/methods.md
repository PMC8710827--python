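# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions. Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Genome-size estimation

Distinct canonical k-mers (a k-mer and its reverse complement are one key;
`k` must be odd to avoid palindromic ambiguity, default 17) are tabulated by
sequencing depth. After moving-average smoothing (window 3), the first local
minimum after depth 1 is the error trough and the argmax beyond it the main
peak; a heterozygous peak is reported when the largest local maximum within
[0.4, 0.6]× the main depth reaches 10% of the main-peak height. The
estimator is `size = total k-mer instances / main peak depth`. "Instances"
means Σ depth × count — the convention that reproduces survey-sequencing
arithmetic such as 57 879 333 379 / 52 ≈ 1113 Mb. `raw` mode (default)
divides the full total; `error_filtered` first removes instances below the
error trough, which matters at high error rates (error k-mers inflate the
numerator but not the peak). Smoothing window and the 10% prominence
threshold are robustness choices for low-coverage simulated histograms.

The k-mer simulator has two modes. `mixture` composes the expected
histogram analytically: homozygous k-mers Poisson-distributed around the
effective depth `c = coverage · (1−e)^k · (L−k+1)/L` (read length L,
error rate e), heterozygous k-mers — a fraction `1−(1−h)^k` of loci, twice
as many distinct keys — around `c/2`, and error k-mers at depth 1. `reads`
mode actually draws reads from a random diploid genome, injects errors and
counts k-mers; it is the assumption-free cross-check and is restricted to
sub-megabase genomes. Neither mode models repeats, so histograms have no
high-copy tail; the size-recovery tests therefore validate the estimator,
not its behaviour on repeat-rich genomes.

## Homology search and collinear blocks

`find_homologs` delegates the all-against-all protein comparison to NCBI
BLAST+ and applies the two retention filters: E-value ≤ 1e-5 and aligned
length ≥ 50% of the shorter protein. Hits carry per-query ranks by
descending bit score (ties broken by subject id, for a deterministic output
contract). Intra-genome searches drop self-hits, mirror duplicates, and
anchors within 5 gene positions of the self-diagonal.

`chain_anchors` is a longest-chain dynamic programme over anchors
(order-index pairs) per chromosome pair: an anchor extends a chain iff both
order-index increments lie in [1, max_gap] (axis b decreasing for inverted
chains). Both orientations are searched; the best chain is extracted, its
anchors removed, and the search repeated while chains reach
`min_block_pairs`. Defaults: `max_gap = 50` genes (the collinearity
criterion of the motivating analysis) and `min_block_pairs = 5` (the
conventional MCScanX minimum). Chains are scored by anchor count only; no
block-level significance test is applied. On instances of ≤12 anchors the
extracted optimum is verified against exhaustive enumeration in the tests.

## Orthology classification and syntenic multiplicity

Blocks against the reference genome are labelled from their pairs' hit
ranks. An isolated block is orthologous iff >50% of its pairs are rank 1.
Blocks competing over the same reference span (reciprocal overlap ≥ 50%,
grouped transitively) are compared by mean rank: those at or below the
group mean are orthologous. The group rule matters because the two homeolog
copies produced by a lineage-specific WGD are statistically equidistant
from the reference — rank 1 splits roughly evenly between their two blocks,
so a strict per-block majority would misread about half of the true
ortholog blocks. Relative mean rank separates the ortholog pair (mean
≈ 1.5) cleanly from outparalog blocks (mean ≈ 3.5). A group containing only
equally ranked blocks degenerates to "all orthologous", which is the
correct reading when no better-matched competitor exists.

Orthologous blocks are projected onto reference gene order, grouped by
focal chromosome, and merged when they overlap reciprocally by ≥50% *or*
lie within 50 genes of each other on the reference axis — fractionation
breaks one orthologous region into collinear fragments, and without gap
merging each fragment would count as a separate region. Regions need
≥10 supporting pairs (`min_region_pairs`); the threshold keeps retention
0.5 simulations clean. The modal region count over chromosomes is the
multiplicity; ties resolve to the larger value and are flagged, and log2 of
a power-of-two mode is reported as the number of lineage-specific WGDs.

## Ka/Ks and peak detection

`estimate_ks` implements NG86: per-codon synonymous site fractions from the
standard code (changes to stop codons count nonsynonymous), sites averaged
over the two sequences, differences averaged over all minimal mutational
pathways with stop-crossing pathways excluded (if every pathway is blocked,
all are kept), and Jukes–Cantor correction `d = −¾ ln(1 − 4p/3)` with a
saturation flag when the log argument is non-positive. Gapped codons are
dropped; ≥30 ungapped codons are required (relaxable for toy alignments).
Back-translation of protein alignments to codon alignments validates that
each protein is the exact translation of its CDS and names the first
discordant codon otherwise. YN00 is not implemented: at the divergence
depths of interest (Ks ≲ 0.6) the peak locations differ from NG86 by less
than a mixture component's spread, and NG86 is exactly checkable against
pathway enumeration (the tests do so on all 61×61 sense-codon pairs, and
cross-check whole-sequence values against an independent NG86
implementation).

Peak analysis operates on block-average Ks: per-block arithmetic means over
unsaturated pairs within (0, 2] (synonymous sites saturate beyond ~2),
requiring ≥3 usable pairs per block. Because Ks is right-skewed and
multiplicative, Gaussian mixtures with 1–4 components are fitted on log Ks
and selected by BIC; each component's mode is back-transformed as
`exp(μ − σ²)`. A kernel-density mode finder (Gaussian kernel, Silverman-type
bandwidth) runs as a cross-check and peaks deviating >25% from their nearest
KDE mode are flagged. At least 50 block means are required.

Dating is proportional: `age = age_cal × mode / ks_cal`, default calibration
Ks 0.6 ≙ 96 Ma (the WGD shared by all grasses). Both calibration fields are
configurable because published grass datings are not mutually consistent
under a single rate; under the default, a Ks 0.15 peak maps to 24 Ma. No
absolute molecular clock or Bayesian node dating is attempted.

## Ancestral-karyotype painting

Each gene carries an ancestral protochromosome label (an input map, not
inferred). A sliding majority vote over 15-gene windows smooths sporadic
mislabels; consecutive same-label windows merge into segments; segments
below 5 genes are absorbed into the larger neighbour. A chromosome is a
fusion iff ≥2 distinct labels survive with ≥5 supporting genes each.
Recovery of planted fusion counts is exact in simulation when fused arms
are at least twice the minimum segment size.

## Differential expression and duplicate-pair fates

Size factors are median-of-ratios against the geometric-mean reference
(all-positive genes only). Per-gene NB dispersion is estimated by the
method of moments, pooled across the two groups of a contrast, and the
working dispersion is the *maximum* of the gene-wise estimate and a fitted
mean–dispersion trend `α(μ) = a + b/μ` (robust soft-L1 fit) — the
conservative sharing rule, chosen so that noisy four-replicate moment
estimates cannot understate the variance and inflate the test. The Wald
statistic is the log fold change (pseudo-count 0.5 on normalised group
means) over a delta-method standard error with NB variance `μ + αμ²`.
Benjamini–Hochberg correction is applied within each (tissue, time)
contrast over genes with any count in that contrast; all-zero genes are
excluded from the family. A DEG requires |log2FC| ≥ 1 and FDR < 0.05.
This stage is deliberately self-contained rather than bound to an external
DE package: every step is explicit and oracle-testable (type-I control on
null simulations, ≥80% power at planted four-fold changes at μ = 100,
α = 0.1, 4 vs 4).

Paralog pairs are two focal copies collinear in an intra-focal block
attributed to the lineage-specific WGD — block mean Ks below the midpoint
of the two youngest focal Ks peaks (or an explicit threshold) — with both
copies orthologous to the same reference gene; reference genes with more
than two focal copies are excluded and pairs deduplicated.

Fate classification collapses time points by union: a copy's signature is
the set of (tissue, direction) over its DEG calls, so a copy up at 6 h and
down at 24 h in one tissue carries both directions (which can push a pair
into III/IV; such conflicts are preserved, not resolved). For both-DEG
pairs: identical signatures → I; any opposite-direction co-occurrence with
identical tissue sets → III; opposite directions with differing tissue sets
→ IV; otherwise (tissue divergence, compatible directions) → II. The
opposite-direction test spans all signature entries, not only shared
tissues, so an up-in-root vs down-in-shoot pair reads IV (the combined
divergence), not II. Reported percentages round half-up to two decimals;
note that this arithmetic can disagree with figures derived by
complementing to 100% (e.g. 402/6796 = 5.9152% → 5.92).

## Synthetic data: what it does and does not emulate

`simulate_wgd_genome` builds an ancestral gene order, applies a shared WGD
(pairwise dS target 0.6), a speciation split (ortholog dS 0.45), and one or
more stacked focal-lineage WGDs (dS 0.15), then fractionation (independent
per-copy Bernoulli survival, default retention 0.7), end-to-end fusions
(always across distinct ancestral chromosomes, so painting can see them)
and Poisson-many segmental inversions. CDS evolve along the implied gene
tree under a per-site Poisson substitution process with synonymous events
at rate dS per NG86 synonymous site and nonsynonymous events at ω·dS
(default ω = 0.2); every change is a single-nucleotide swap into a
synonymous or sense nonsynonymous neighbour, so stop codons never arise and
realised divergence is exactly checkable by NG86 counting. Event counts per
branch are drawn from branch-start site counts (a first-order approximation
to the full chain; the residual bias is ~2% at dS 0.15 and covered by the
estimator-consistency tests). The divergence targets are the Ks depths of
the motivating grass system. Deliberately not modelled: indels, gene
conversion, tandem duplication, biased (subgenome-dominant) fractionation —
loss is independent per copy — transposons and intergenic sequence. Passing tests therefore establish
correctness of the inference chain under clean WGD histories, not
robustness to assembly artefacts or gene-family turnover in real genomes.

`simulate_counts` draws NB counts (variance μ + αμ², default α = 0.1) from
log-normal baselines (ln-mean 4.0, ln-sd 1.2), log-normal library factors
(sd 0.15), and plants (tissue, direction) effects of |log2FC| = 2 at both
6 and 24 h. Pair fates are planted with category proportions
(78.68 / 15.41 / 5.91)% and pattern proportions (64.18 / 26.86 / 2.49 /
6.47)% — the proportions observed in the motivating study — and the design
is root/shoot × 0/6/24 h × 4 replicates; an option drops one shoot-24 h
replicate to mirror a discarded outlier sample (default keeps all). Planted
effects are constant across time points, so the union collapse in fate
classification is exact for planted truth.

All generators are driven by a single integer seed and are byte-identical
across runs with the same seed.

## Problem sizes used in tests and the acceptance script

The acceptance script simulates 200 + 200 blocks of five 300-codon pairs —
enough for mixture modes stable to ±0.005 across seeds. The multiplicity
check uses 5 reference chromosomes × 200 genes at retention 0.7; module
tests use 2 × 60–80 gene scenarios. These sizes are desk-scale choices:
they are far below real gene counts but large enough that every statistical
check operates away from its small-sample regime.

## Known limitations

- The NG86/JC model ignores transition/transversion and codon-usage bias;
  on real sequences Ks peaks can shift by more than the simulator suggests.
- Proportional Ks dating inherits any error in the calibration anchor and
  assumes rate constancy across lineages and time.
- The multiplicity readout assumes the reference genome truly lacks the
  focal lineage's extra WGD and has largely intact chromosome-scale synteny.
- Tandem arrays are not collapsed before chaining (the simulator produces
  none); on real annotations they can inflate intra-genome blocks.
- The NB Wald test is moment-based; it is conservative at low counts and
  does not shrink fold changes.
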
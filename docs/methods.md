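# Methods

This note documents the models, the parameters that matter, the synthetic
data the package validates itself on, and the numerical and design choices
made where the construction was genuinely open.

## Catalogs and coordinates

Mutations are 1-based (VCF convention); every interval type — regions,
timing bins, gene models, CNV segments — is 0-based half-open (BED
convention). The conversion happens at exactly one point, where a
position is tested against an interval. SNVs are classified into the 96
strand-collapsed categories; purine-reference records are mapped by
reverse complement of the full trinucleotide (flanks swap and complement),
so the catalog is invariant under re-reporting a variant on the other
strand (tested by full enumeration of the 192 flank/allele combinations).
Column order is substitution-class major (C>A, C>G, C>T, T>A, T>C, T>G),
flank-lexicographic minor, matching published reference-signature tables
so they load without permutation. Mutations whose context contains an
ambiguous base are dropped and counted, not errored. Filters: immune
hypermutated regions are excluded by interval overlap (the region file is
a user input, padded ±50 kb via `RegionSet.extend`); the clonality filter
keeps strictly VAF > 0.9.

## NMF extraction and rank selection

The inner solver is coordinate-descent NMF with Frobenius loss
(scikit-learn), wrapped in a best-of-`n_restarts` layer (default 20;
analysis runs use 8–10) with per-restart seeds fanned out from one
pipeline seed. Signature rows are normalized to 1 with the scale absorbed
into exposures, so an exposure reads as a number of mutations. Rank
selection is explicit because the upstream tool this mirrors defers to
package defaults: scanning k upward, a rank is accepted while (i) restart
stability — mean cosine of optimally matched signatures between each
restart and the best run — is ≥ 0.9 and (ii) the relative reconstruction
error still falls by ≥ 5% of the previous rank's error. On planted
five-signature cohorts at the validation scale (200 samples × ~500
mutations) the elbow is sharp (error gain 22% at k = 5, 1.3% at k = 6).
At much smaller cohort sizes sampling noise flattens the elbow and the
rule can overshoot; rank diagnostics are always returned so the curve can
be inspected.

Exposure fitting against fixed signatures is per-sample non-negative least
squares; attribution follows the posterior formula in the README, with
argmax ties broken toward the earlier signature id (ties are measure-zero
on real data). Mutations in categories impossible under every active
signature of their sample get an all-NaN attribution row and are excluded
from attribution-based analyses.

## Rearrangement signatures and clustered breakpoints

SVs are classified into 32 categories: clustered status × {DEL, DUP, INV
in five half-open log-spaced size bins (1–10 kb, 10–100 kb, 100 kb–1 Mb,
1–10 Mb, > 10 Mb); TRA unbinned}. Sub-1 kb events fall into the smallest
bin and are tallied. "Clustered" is defined per sample: all breakends are
pooled per chromosome; the sample's expected spacing is genome size
divided by total breakend count; a maximal run of adjacent gaps each below
one tenth of that expectation, spanning at least 8 breakends, marks a
cluster, and an event is clustered if any of its breakends lies in one.
The one-tenth ratio and 8-breakend minimum follow the field-standard
construction and are configurable. Using the genome-wide expected spacing
(rather than the mean adjacent gap) is what makes a tight run on an
otherwise empty genome detectable. RS extraction reuses the NMF core on
the 32-category space.

## Regional normalization

Opportunities V live on the 32 pyrimidine-collapsed context classes,
shared across the three alternate alleles of a context; U lives on the 96
categories. Every unambiguous position contributes to its collapsed
class — a purine-centered position is a genuine opportunity via the
reverse complement, which is required for consistency with the
strand-collapsed catalog (a G>A call is a C>T-class mutation). U_norm is
computed per tumor, never pooled, and rounded half away from zero.
Realizing a non-integer-free normalized count: when U_norm < U the
category's mutations are subsampled uniformly with the pipeline seed; when
U_norm > U existing mutations are upweighted by U_norm/U rather than
fabricating records. The larger region is always designated X, so
swapping argument order reproduces the same Q values (tested). Contrasts
compare per-sample *proportional* contributions (each region's signature
mass over its total) by paired Wilcoxon, BH-corrected within the signature
family; raw sums are also reported and conserve the (normalized) mutation
count.

The driver contrast compares attributed probabilities of mutations in a
gene against all other mutations (Wilcoxon rank-sum, BH over the gene ×
signature family), with an `exclude_recurrent` mode that first drops
positions mutated in more than one tumor. Because a single gene's few kb
of sequence has its own trinucleotide composition, this contrast can flag
composition effects as well as process enrichment — visible in the
analysis scripts, where recurrently hit genes show flags under a
process-neutral simulation; the planted-contrast and null-calibration
tests characterize both behaviors.

## Replication timing, strand asymmetry, expression

Deciles partition the binned genome into ten near-equal bp-mass strata of
the timing signal (higher = earlier; decile 1 earliest; masses within 2%).
The slope test regresses rate on decile index and permutes the decile
labels (default 10,000 times); the empirical P uses the add-one form
(1 + exceedances)/(1 + permutations), which never returns zero and matches
the printed-bound convention "P < 10⁻⁴" at 10⁴ permutations. Fork
polarity: the signal is smoothed with a 5-bin moving average and the local
gradient sign gives fork direction (origins at peaks, forks running toward
valleys); bins at extrema are unassigned. For a right-moving fork the
plus strand is replicated as leading, and a mutation sits on the strand
carrying its pyrimidine base — a global strand flip of the reference flips
every call (tested). Asymmetry per signature counts each mutation toward
its argmax process, tests per-sample strand counts by paired Wilcoxon, and
flags significance only when the pooled imbalance |n₁ − n₂|/(n₁ + n₂)
exceeds 0.30 and BH-adjusted Q < 0.05; the imbalance formula is our
explicit rendering of a ">30% imbalance" rule stated without one.

Expression pentiles are per tumor (five near-equal bins of FPKM rank, ties
ordered stably by value then gene name, bin sizes within one), after
removing immunoglobulin genes and the translocation-upregulated set
(CCND1, CCND3, FGFR3, MMSET, MAF, MAFB, MYC). Rates are per-Mb of gene
length per pentile, averaged across tumors with normal-approximation 95%
CIs; zero-length genes are excluded with a log.

## Kataegis

A window of ≥ 6 consecutive mutations qualifies when the mean of its
adjacent gaps is ≤ 1 kb (inclusive). Foci are connected components of
the union of all qualifying windows — equivalently, what an exhaustive
oracle that scores every contiguous window and merges overlapping maximal
ones reports; this makes maximality well-defined where greedy extension is
ambiguous, guarantees foci never share a mutation, and is verified by
exact set equality against the brute-force oracle on random instances. A
merged component can, in adversarial configurations, have an overall mean
gap slightly above 1 kb even though every covering window qualifies; n and
the member list are stored so both statistics are recomputable. Runs are
bounded per chromosome. Enrichment compares focus mutations against (i)
other mutations in kataegis-positive tumors and (ii) mutations in
kataegis-negative tumors, BH within each; "consistent" enrichment requires
both at Q < 0.05 with the focus mean on top. SV co-localization reports
both directional fractions at a 10 kb window.

## Karyotype and subgroups

Hyperdiploidy: ≥ 2 autosomes with ≥ 90% of their length covered by
segments at log2 ≥ 0.1613 (amplified intervals are merged first, so calls
are invariant to segment splitting). Arm events: segments strictly longer
than 1 Mb with |log2| ≥ 0.1613 of the locus-appropriate sign overlapping
one of the five prognostic cytobands (coordinates are an input fixture;
the bundled set is synthetic, matched to the generator's compact
chromosome model). Both calls are verified against per-base brute-force
tallies including the exact threshold boundaries. Translocation labels
are input metadata, never inferred. Enrichment: signature activity is
binarized at ≥ 5% normalized exposure (configurable; the dichotomization
is ours, stated because the source analysis never specifies one), then
two-tailed Fisher per (signature, subgroup) with BH over the whole family;
subgroups under 5 samples are tested but flagged low-n.

## Consensus clustering and survival staging

Features are per-sample proportions of de novo rearrangement signatures
plus major SNV signatures (> 1% mean contribution). For each candidate k
the cohort is subsampled (default 80%, 1,000 resamples; analysis and
validation runs use 100–250 as a problem-size choice) and clustered by
average-linkage hierarchical clustering on Euclidean distances; the
consensus matrix is the fraction of co-subsampled runs in which a pair
co-clustered. Final labels cluster 1 − consensus. k is selected by the
consensus-CDF area criterion: A(k) = 1 − mean pairwise consensus, with k
accepted while its relative area gain over k − 1 is ≥ 0.1. A plain
mean-intra-consensus score cannot be used: on hierarchically structured
data a merge of two genuine clusters is itself perfectly stable, so
under-splitting looks flawless; the area criterion detects that genuine
new splits keep appearing until the true k and only arbitrary splits
appear beyond it. If every pair co-clusters the model collapses to one
cluster with a warning. Labels are deterministic per seed, renamed A, B,
… by decreasing size.

Survival: global k-group log-rank; multivariate Cox (lifelines) with Wald
CIs, refusing constant covariates and surfacing non-convergence; risk
delineation orders clusters by Kaplan–Meier median survival, BH-corrects
all pairwise log-rank tests, and cuts at the largest adjacent median gap
whose across-boundary pair is significant — clusters below the cut are
high-risk. With no significant boundary all clusters form one (low) tier.

## Synthetic cohorts

The generator emulates: per-sample Dirichlet signature mixing (default α
= 0.5, sparse, five block-structured signatures at pairwise cosine ≈ 0.2);
Poisson mutation burdens (default 300–500 per sample); genomic placement
conditioned on each mutation's trinucleotide context via a genome-wide
context index, with per-signature exponential tilts over timing deciles
and lagging-strand preference applied at position choice; VAF mixtures
straddling the 0.9 clonality cut; kataegis foci whose positions are
weighted by the generating signature's context-class marginal (so focus
catalogs match the generating profile, as for a motif-directed mutator)
and whose records stay consistent with the emitted genome sequence; SV
category draws from planted RS mixtures with all clustered draws of a
sample walking one tight breakpoint window so genuine runs materialize;
CNV plans realizing hyperdiploidy and arm events; categorical
translocation labels; and exponential proportional-hazards survival with
independent censoring. One global seed spawns named substreams (genome,
mutations, kataegis, sv, cnv, clinical, expression) in a fixed order, so
adding draws to one component never shifts another; two runs at one seed
are byte-identical.

What the generator does *not* emulate: real human sequence (contigs are
i.i.d. bases at a target GC), linkage between CNV and expression,
signature bleed between similar profiles (planted profiles are
well-separated), indel processes, and realistic SV size/recurrence
landscapes. Passing tests therefore demonstrate correctness of the
machinery and recoverability under the stated statistical structure, not
performance on the harder identifiability problems real cohorts pose
(e.g. flat-signature ambiguity, which the flat-collapse operation exists
to sidestep).

Default study conditions used by the validation harnesses follow the
documented checks: 200 samples × ~500 mutations for signature recovery;
1,000 random instances for the kataegis oracle; 1,000 replicates × 1,000
permutations for slope-test calibration; 50 samples × ~500 mutations with
a 70/30 lagging bias for asymmetry; 500 random segment sets for the
karyotype oracle; and 20 replicates of an n = 800, four-cluster cohort
with one group at hazard ratio 2 and ~30% censoring for the
cluster/survival chain. The analysis cohort (scripts 01–07) uses 60
samples × ~400 mutations on a 4 Mb genome — large enough that background
inter-mutation spacing (~10 kb) sits far above the 1 kb kataegis scale, as
in real genomes.

## Numerical choices and degenerate inputs

Rounding in U_norm is half away from zero. Signature rows and attribution
vectors are validated to sum to 1 within 1e-8. Empirical permutation P
values lie in [1/(n_perm + 1), 1]. Wilcoxon signed-rank tests degenerate
to P = 1 when all paired differences are zero or fewer than three pairs
exist. Fisher odds ratios of degenerate tables are reported as
infinity. Kaplan–Meier medians that are never reached order as +∞ in the
risk-tier rule. Zero-vector cosine similarity, chromosomes missing from
the reference, category-space mismatches, overlapping contrast regions,
missing cytobands, constant Cox covariates, and infeasible NMF or
clustering ranks all raise immediately with named offenders.

## Known limitations

Exposure-space rank selection and signature assignment inherit NMF's
rotational near-degeneracy for flat profiles; the flat-signature collapse
(summing signatures 3, 5, 8 of a standard reference) is the supported
mitigation. Exome-to-genome opportunity rescaling between reference
catalogs is out of scope. The per-gene driver contrast does not
re-normalize composition within genes (see above). The Cox hazard-ratio
recovery band at the validation scale is approximately a 92% interval per
replicate (SE of log HR ≈ 0.09 at ~165 vs ~420 events), so its
20-replicate pass fraction hovers at its nominal 0.9 requirement; the
estimator itself is unbiased (median HR ≈ 1.97 across replicates).
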
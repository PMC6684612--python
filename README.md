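# myelosig

Mutational-process analysis for multiple myeloma genomes: a Python package
and analysis pipeline that extracts single-nucleotide-variant (SNV) and
structural-rearrangement signatures, attributes individual mutations to
processes, contrasts genomic regions with explicit trinucleotide
normalization, tests replication- and transcription-strand asymmetries,
detects kataegis, calls karyotype subgroups, and stages patients by
consensus clustering of signature activities with survival models.

It is written for cancer-genomics analysts who have somatic calls in hand
(SNVs, SVs, CNV segments, expression, clinical endpoints) and want the
downstream mutational-process analyses as tested, seedable library code.
Because the motivating cohort data are controlled-access, the package
ships a first-class synthetic-cohort generator that plants every
statistical structure the pipeline assumes — signature mixtures,
timing-dependent rates, strand biases, kataegis foci, SV category
mixtures, karyotype plans, proportional-hazards survival — so the whole
chain is validated against known ground truth.

## The core models

**Signature deconvolution.** Somatic SNVs are classified into the 96
strand-collapsed categories (6 pyrimidine substitution classes × 16
flanking-base pairs). The samples × categories count matrix *M* is
factorized by non-negative matrix factorization, *M* ≈ *E S*, with
signature rows of *S* normalized to probability distributions and
activities *E* on the mutation-count scale. The rank is chosen by an
explicit reconstruction-error elbow plus restart-stability rule. De novo
signatures are assigned to a reference catalogue when cosine similarity
exceeds 0.75 (most similar wins); exposures against a fixed reference are
fit per sample by non-negative least squares. Each mutation of category
*c* in sample *j* is attributed to process *s* with posterior probability

    P(s | c, j) = E_js · S_sc / Σ_t E_jt · S_tc .

**Regional normalization.** Comparing signature activity between regions
*X* and *Y* requires correcting for trinucleotide composition: the
observed count *U* of category *C* in the larger region *X* is rescaled to

    U_norm(C, X) = U(C, X) · V(C, Y) · W(X) / ( V(C, X) · W(Y) ),

rounded to the closest integer, where *V* counts positions at which a
category-*C* mutation can occur and *W* is region size (bp). The rescaled
counts are realized per tumor by seeded subsampling (U_norm < U) or
upweighting (U_norm > U) before paired Wilcoxon tests across samples.

**Kataegis.** A focus is six or more consecutive mutations with mean
inter-mutation distance ≤ 1 kb (boundary inclusive); reported foci are
maximal and non-overlapping, and the detector is verified against an
exhaustive window-scoring oracle.

**Replication and transcription.** A binned replication-timing track
yields equal-mass deciles (mutation rate per Mb per decile, with a
10,000-permutation slope test) and fork polarity from signal peaks, giving
leading/lagging assignments; gene strand gives transcribed/non-transcribed
assignments. Per-signature asymmetry is significant when the pooled
imbalance |n₁ − n₂|/(n₁ + n₂) exceeds 0.30 with BH-adjusted Q < 0.05.

**Subgroups and survival.** Hyperdiploidy is ≥ 90% amplification of ≥ 2
autosomes; prognostic arm events are > 1 Mb segments with |log2| ≥ 0.1613
at 1p12, 1p32.3, 1q21.1, 1q23.3, 17p13. Signature × subgroup enrichment
uses two-tailed Fisher tests with BH correction. Patients are staged by
consensus hierarchical clustering of combined SNV + rearrangement
signature proportions, with log-rank tests, multivariate Cox models and a
pairwise-test-based low/high-risk delineation.

## Worked example

The numbered scripts under `analysis/` run the full chain on a synthetic
60-sample cohort (4 Mb genome, five planted SNV signatures, an APOBEC-like
signature S2 with a 70/30 lagging-strand bias that also seeds kataegis,
one early-replicating signature S4, three rearrangement signatures):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_extract_signatures.py
...
python analysis/08_cluster_survival.py
```

Script 02 prints, for this cohort:

```
selected rank k=5 (diagnostics in results/signatures/rank_diagnostics.tsv)
  N1 -> S3 (cosine 0.993)
  N2 -> S1 (cosine 0.987)
  N3 -> S5 (cosine 0.991)
  N4 -> S2 (cosine 0.992)
  N5 -> S4 (cosine 0.987)
major signatures (>1% mean contribution): ['S1', 'S2', 'S3', 'S4', 'S5']
```

i.e. the rank-selection rule recovers the five planted processes and every
de novo signature is assigned to its generating profile at cosine ≥ 0.987.
Script 05 recovers the planted replication structure — every process is
late-replicating (permutation P = 2 × 10⁻⁴ at 10⁴ permutations) except the
planted early signature S4 (negative slope), and only S2 is flagged for
replicative strand asymmetry. Script 06 rediscovers 20/20 injected
kataegis foci and finds S2 consistently enriched at foci; script 08
recovers the four planted patient groups (k = 4, adjusted Rand index
0.993), separates their survival (log-rank P = 4 × 10⁻¹⁵), estimates the
planted hazard ratio as 2.11 [1.76, 2.53] against HR = 2.0, and stages the
planted cluster as the only high-risk group. Tables land under
`results/`.

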
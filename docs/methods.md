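# Methods

## The analysis

`mitoscan` implements haplotype-network association scanning ("tree
scanning") for case-control cohorts typed on the mitochondrial genome.
Because mtDNA is haploid and non-recombining, every subject carries exactly
one haplotype, and the haplotypes are related by a single genealogy. Rather
than testing variants one at a time, the scan tests *branches*: each branch
of the haplotype network splits the haplotypes into two clades, pooling
evolutionarily related haplotypes into a two-level factor (there is no
heterozygote class). A mutation with a phenotypic effect is expected to sit
on some branch of the network, so the branch family is both exhaustive and
far more structured than a per-variant scan.

The pipeline stages are:

1. **Variants to haplotypes.** Per-subject variant lists in 1-based
   reference coordinates (m-dot notation). Heteroplasmic sites are resolved
   to the majority allele; ties go to the reference allele (deterministic,
   conservative). Subjects with identical variant sets collapse into one
   haplotype. Indels are left-normalised against the reference and count as
   a single mutational step regardless of length.
2. **Imputation along matrilines.** An unbroken maternal line shares one
   mtDNA haplotype, barring germline mutation. Every ungenotyped member of
   a matriline with exactly one observed haplotype receives that haplotype
   (flagged `imputed`); discordant matrilines are handled per the
   `conflict` policy (abort / majority / leave missing) and always logged.
   Maternal mutation within a matriline is assumed absent, which matches a
   design with a single sequenced representative per matriline.
3. **Network construction.** Edges represent one mutational step. Pairs of
   haplotypes are connected in nondecreasing step distance (symmetric
   difference of variant sets); a pair at distance d is admitted whenever
   its endpoints were in different connected components before any
   distance-d connection was made. This is the union-of-all-minimum-
   spanning-trees rule: genuinely tied alternative connections are all
   retained and appear as loops (reticulations), exactly where the data are
   ambiguous about the mutational route. Pairs at d > 1 are joined through
   d - 1 inferred intermediate haplotypes. Chains are routed through the
   two endpoints' shared variant set, stripping private variants
   rarest-first (carrier frequency is a proxy for mutation age): on
   homoplasy-free data the waypoints are ancestral haplotypes, so chains
   from different pairs meet at shared inferred nodes instead of spawning
   parallel routes. On infinite-sites simulations this recovers the true
   genealogy exactly (zero loops, one edge per mutation).
4. **Branch partitions.** In a tree-resolved component, removing a branch
   bipartitions the observed haplotypes. Maximal chains through inferred
   degree-2 nodes form one multi-segment branch whose defining variants are
   all the segment labels. Components with loops are resolved into each
   spanning tree; distinct partitions are deduplicated and each records how
   many resolutions support it (`n_resolutions`). Enumeration is capped at
   10,000 spanning trees per component; synthetic and tree-like real
   networks stay far below the cap.
5. **Branch tests.** A branch is eligible when both allelic classes contain
   at least `min_class_size` (default 5) phenotyped subjects. The statistic
   is the likelihood-ratio test for the branch allele in a logistic model
   of case status on allele + covariates. The default flavor penalizes the
   likelihood with Firth's Jeffreys-prior term, so a clade containing no
   cases (complete separation) still yields a finite, rankable statistic;
   the plain LRT flavor exists for closed-form cross-checks. Asymptotic
   p-values are never used for inference - permutation supplies it.
6. **Permutation inference.** Each permutation shuffles the
   subject-to-haplotype assignment across all subjects; phenotypes and
   covariates stay attached to subjects, so their joint distribution is
   preserved under the null of no haplotype effect. All eligible branch
   statistics are recomputed per permutation, preserving the inter-branch
   correlation. Nominal p-values use the add-one convention (b+1)/(B+1).
   Familywise correction is step-down minP: order branches by nominal p,
   compare each to the permutation distribution of the minimum
   per-permutation p-value over the not-yet-rejected branches, and enforce
   monotonicity. Per-permutation p-values are self-inclusive rank counts
   over the same B permutations, which puts observed and permuted p-values
   on one scale (both floor at 1/(B+1)). For tiny cohorts an exhaustive
   mode enumerates all n! assignments and reports exact p = #{stat >=
   observed}/n!.
7. **Conditional rounds.** After a significant branch, a second round adds
   that branch's observed allele as a fixed subject-level covariate and
   rescans; branches collinear with the conditioning allele are reported
   degenerate. Rounds repeat until no new branch is significant. The
   conditioning allele is computed from the observed assignment and does
   not permute - the round-2 null is "no haplotype effect beyond the
   conditioned branch".
8. **Familial risk.** For each subject, the coefficient-of-relationship
   (r = 2 x kinship) weighted sum of affected relatives divided by the
   r-weighted sum of at-risk-cohort relatives. Kinship uses the standard
   recursive algorithm on the pedigree. Subjects with no at-risk relatives
   score 0 and carry a missing-indicator column so they are not dropped
   from regression. Affected relatives count only if they are also cohort
   members (the denominator's sampling frame).

## Covariate encodings

Sex enters as a male indicator; age in years at blood draw; APOE as two
allele-dosage terms (epsilon-4 count, epsilon-2 count); familial risk as the
score plus its missing indicator. All models include an intercept.

## The synthetic cohort generator

`simulate_cohort` emulates the statistical structure the analysis assumes,
with defaults mirroring a matrilineal cohort of 1007 subjects:

| parameter | default | meaning |
|---|---|---|
| `H` | 274 | genealogy tips, one per matriline (identical tips merge) |
| `theta` | 1125 | scaled mutation rate (with growth: ~900 segregating sites) |
| `growth_rate` | 200 | exponential growth; star-like genealogy as in expanding human mtDNA |
| `n_subjects` / `n_matrilines` | 1007 / 274 | cohort size and matriline count |
| `male_fraction` | 442/1007 | exact male count via random allocation |
| `age_mean` / `age_sd` / `age_min` | 75.64 / 7.50 / 65 | truncated normal age (years) |
| `apoe4_freq` / `apoe2_freq` | 0.15 / 0.06 | allele frequencies for dosage draws |
| `baseline_case_rate` | 101/733 | case fraction among phenotyped (intercept calibrated) |
| `missing_phenotype_rate` | 274/1007 | exact missing count via random allocation |
| `beta_age`, `beta_male`, `beta_apoe4`, `beta_apoe2` | 0.10, -0.20, 1.20, -0.50 | log-odds covariate effects |
| `beta` | 0 | planted clade log-odds; `-inf` = fully protective |
| `het_rate` | 0.01 | per-variant heteroplasmy probability (minor fraction < 0.5) |
| `ref_length` | 2000 | toy reference length (16,569 for the study-scale coordinate system) |

The genealogy is a neutral coalescent (msprime) with infinite-sites
mutations at unique integer positions of a seeded toy reference. At
`growth_rate` 0 the expected segregating-site count is Watterson's
theta x sum 1/i; the default strong growth shifts variation onto terminal
branches, which is what lets ~274 tips carry ~240-250 *distinct*
haplotypes and ~900 sites simultaneously, as in real expanding mtDNA
populations. Matriline sizes are geometric (adjusted to the exact cohort
size); each matriline is a three-generation maternal pedigree whose cohort
members form sibling groups under full-sister mothers, so the cohort
contains sib pairs (r = 1/2) and first cousins (r = 1/8). Exactly one
cohort member per matriline is "sequenced"; everyone else is imputable.
Case status is a logistic model on the covariates with the intercept
calibrated by root-finding so the realized mean case probability equals
`baseline_case_rate`; a planted clade (an internal node of the genealogy,
restricted to haplotype-closed tip sets) shifts carriers by `beta`.
Age/sex/APOE margins and missingness are drawn to exact counts where the
emulated table pins integers.

What the generator does *not* emulate: recurrent/back mutation (networks
are loop-free by construction; loop handling is exercised by hand-built
homoplasy fixtures), indels (all simulated variants are SNVs), real mtDNA
haplogroup structure or allele spectra, within-matriline phenotype
clustering beyond the covariates, and age-structured pedigrees. Mean
variants per subject (~15-20) is below typical human mtDNA (~25) because a
single-parameter coalescent cannot match site count, haplotype count and
per-subject load at once; the first two drive the scan and were matched.

## Numerical choices

* Firth/ML logistic fits use hand-rolled Newton iteration with Cholesky
  factorization (numba-compiled): design matrices are tall and narrow, and
  the permutation scan performs millions of fits. Convergence is declared
  when the largest coefficient update falls below `tol` (default 1e-5;
  log-likelihood error is then O(tol^2)); steps larger than 5 per
  coefficient are damped (plain-ML separation drift); the iteration cap
  (default 25) marks non-converged fits, which are excluded from the
  step-down family and logged.
* Permuted/observed statistic comparisons use an absolute tie slack of
  1e-7, far below the spacing of distinct contingency configurations and
  above solver noise.
* A branch whose genotype is constant in a given permutation after listwise
  deletion scores 0 for that permutation.
* Heteroplasmy ties (fraction exactly 0.5) resolve to the reference allele.
* Equal-distance connection ties in network construction are ordered by
  (higher carrier count, lexicographic id) - deterministic without a seed.

## Problem sizes for the statistical test batteries

The distributional checks run at fixed, seeded sizes chosen as the package's
own test design: familywise type-I calibration uses 200 null cohorts of 400
subjects (110 matrilines, 40-tip genealogies) at B = 500; planted-clade
recovery uses study-structure cohorts (1007 subjects, 274 matrilines) with
a fully protective ~38-phenotyped-carrier clade at B = 1000 over 6
replicates; conditional-scan behaviour is additionally exercised at a
deliberately detectable configuration (40-tip family, ~90-phenotyped-carrier
protective clade, B = 2000), where the minP significance floor K/B lies
below 0.05.

### A note on detectability of small zero-case clades

Under assignment permutation, the nominal p-value of any branch is bounded
below by the probability that a random re-assignment reproduces an equally
extreme case split. For a clade of ~53 carriers in a cohort with 101 cases
among 733 phenotyped, the all-control atom alone has probability ~0.0035,
so a fully protective 38-phenotyped-carrier clade cannot reach nominal
p ~ 1e-4, and after step-down minP over a ~165-branch family its corrected
p is typically ~0.9. Detection at corrected p < 0.05 requires either a
substantially larger protected clade or a much smaller branch family; the
recovery battery reports the measured detection rate rather than assuming
one.

## Known limitations

* The network builder targets homoplasy-poor mtDNA-scale data; heavily
  reticulate inputs fall back to capped spanning-tree enumeration.
* Conditional rounds condition on observed alleles; a fully permutation-
  consistent conditional null (re-deriving the conditioning allele per
  permutation) is not implemented.
* The packaged 16,569 bp reference is a synthetic stand-in carrying the
  documented bases only at the positions the worked examples use; analyses
  of real data should supply the true NC_012920 FASTA.
* `--threads` is accepted but the scan kernel is single-threaded.
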
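# Methods

## Model overview

`hivesim` simulates a closed honeybee breeding population with a constant
census of N breeding queens per year over a fixed horizon (default 100
years).  Queens are diploid; drones are haploid single gametes of their
mother and, for breeding-value arithmetic, are treated as diploid but
homozygous (allele counts twice the haplotype).  Worker groups — the bees
that express the direct effect of a colony's performance — are daughters of
the colony's queen by her twelve stored mates.

### Trait architecture

A selection trait is governed by N_l unlinked, purely additive, biallelic
loci.  Base-population allele frequencies are i.i.d. Beta(0.5, 0.5)
(U-shaped; draws within 1e-6 of the boundary are resampled so 2p(1−p) > 0).
Each locus carries a (maternal, direct) substitution-effect pair drawn from
an equal-weight mixture of a bivariate Laplace and a bivariate Normal
distribution with covariance Σ_A/N_l, then a single 2×2 transform (Cholesky
of the target times the inverse Cholesky of the achieved matrix) makes

    sum_l 2 p_l (1 − p_l) e_l e_l' = Σ_A

hold to machine precision.  Two choices here were genuinely open:

* *Mixture weights* (0.5/0.5): post-correction fixes the base covariance
  regardless, so the weights only shape effect-size kurtosis.
* *Per-locus scaling*: effect sizes are drawn independently of allele
  frequency.  The alternative — scaling each locus by 1/√(2p(1−p)) so every
  locus contributes equal variance — gives rare alleles enormous effects and,
  under directional selection, produces a transient *increase* of genetic
  variance and implausibly large long-term gain (several times the
  selection-response range reported for such schemes).  Frequency-independent
  effects behave like a neutral quantitative-genetic architecture and were
  adopted as the default; they are not revisited.

Default parameters: σ²_A,m = 1, σ²_A,d = 2, σ_A,md = −0.75 (r_md = −0.53) or
−1.25 (r_md = −0.88), σ²_E = 1, N_l = 200 or 400.  The derived inheritance
criterion SD is σ_A,IC = √(σ²_m + σ²_d + 2σ_md) = 1.22 resp. 0.71.

### Breeding scheme and calendar

A queen born in year t is performance-tested in year t (one record per
colony), is a dam candidate in t+2, and a station-founder candidate in t+3,
which realizes the 2-year maternal and 3-year paternal generation intervals
(average 2.5).  Each year:

1. genetic parameters are re-estimated if due (years 5, 10, 15, …);
2. BLUP runs on the full pedigree and all historical records;
3. the best ⌊N/k_d⌋ two-year-olds (maternal+direct EBV, ties by id) become
   dams with quota k_d; the N mod k_d remainder offspring get dams drawn
   uniformly *with replacement* from the selected set;
4. the best round(N·k_s/100) three-year-olds (min 1) each found one mating
   station with 8 drone-producing queens (DPQs), Mendelian daughters via the
   founder's stored mates;
5. the N virgin daughter queens (each fathered by one of her dam's twelve
   mates, drawn uniformly) are assigned to stations uniformly at random and
   mate with 12 drones each (per drone: DPQ uniform among the 8, one fresh
   gamete);
6. apiaries: each daughter keeps her dam's apiary with probability 0.7, else
   uniform among the 7N/100 apiaries (≈14.3 colonies per apiary);
7. records y = maternal TBV + worker-group direct TBV + N(0, σ²_E) are
   generated, with the worker group modeled as the expectation over an
   infinite worker cohort with equal patriline shares.

The base population consists of three unrelated founder cohorts (so years
1–3 already have 1-, 2-, and 3-year-old candidates), each queen mated to 12
drones of 12 distinct unrelated queens outside the recorded population.

### Inbreeding

Individual inbreeding is exact on the realized drone-level pedigree: F of a
queen is the coancestry of her dam and her actual father drone, where a
drone's kinship with himself is 1 and with anything else equals his
mother's.  The simulator maintains this recursion on a sliding window of the
last four birth cohorts (parents always lie within three years), with an
explicit correction of (1 − F_M)/8 for every pair of offspring sharing the
same father drone; the window is verified against the full memoized
recursion, and the recursion against gene dropping.  The generational rate
is ΔF = 1 − (1 − F₁₀₀)^{2.5/99} from the mean F of the year-100 *birth
cohort* (the alternative reading — all queens alive in year 100 — mixes
cohorts and was not used).

### Evaluation model

The mixed model per record: one fixed effect per year×apiary combination and
a (maternal, direct) random-effect pair per evaluation entity, with
Var(u) = A ⊗ Σ̂_A.  Entities are queens, worker groups, and pseudo-sires
(one per mating station: the pooled drone production of the 8 DPQs, whose
genetic value is the DPQ mean, so every parent link is an exact ½/½
average).  The average relationship matrix A treats each offspring's
paternal gamete as an independent draw from the (infinite) station pool;
with that convention A = T·D·T′ holds exactly with closed-form Mendelian
sampling coefficients

    queen          d = 1 − (a_pp + a_ss)/4
    station pool   d = (1 − (a_pp + a_ss)/4) / 8
    worker group   d = (2 − a_ss)/48
    base queen     d = 1;   base pool of 12 unrelated queens  d = 1/12

(a_pp, a_ss: parent diagonal entries).  The within-mating probability of 1/12
that two offspring share a father drone is represented in the realized
pedigree but deliberately **not** in A — a diagonal Mendelian-sampling
decomposition cannot carry that covariance — so A is the evaluator's
(station-level) expectation, as in practical honeybee genetic evaluation
where individual paternity is unobservable.  A dense pair-recursive
implementation of the same expectation serves as the oracle for the sparse
construction.

The equations are solved by conjugate gradients with a 2×2 block-Jacobi
preconditioner, warm-started from the previous year, to relative residual
1e-8 (sparse LU available as `solver="direct"`).  Empty fixed-effect levels
cannot arise (levels are created from records); a non-convergent solve
raises with diagnostics.

### Variance re-estimation

Every five years (years 5, 10, …) the evaluator's Σ̂_A is re-estimated from
the within-family (Mendelian-sampling) variance to avoid Bulmer-effect bias:
the most recent cohort's N queens each produce 100 *virtual* drones,
δ = TBV(queen) − TBV(drone), and

    Σ̂_A = (100N − 1)^{-1} Σ_i (1 − F_i)^{-1} Σ_j δ_ij δ_ij'.

Queens with F within 1e-6 of 1 are excluded with a warning; a non-PSD
estimate (possible at small N) is projected by eigenvalue clipping at 1e-8.
Years 1–4 use the exact base parameters.  The estimator is unbiased on a
known architecture (checked by Monte Carlo).  The cohort supplying the
virtual drones is the most recently tested one; nothing in the breeding
calendar pins this choice down further.

## Scheme-level analysis

Gain, inheritance variance (relative to the exact base value σ²_A,IC),
ΔF, FAO classification (boundary-inclusive at 0.5% and 1%), and the
competitive-breeding-scheme rule (gain within 5% of the cell's best,
compared only within one population-size/trait cell) live in
`hivesim.analysis`; `run_grid` sweeps k_d×k_s with independent
`SeedSequence`-derived replicate streams and aggregates a Table-style cell
summary.  Wright's ΔF ≈ (F+M)/(8MF) is provided as a heuristic comparator
only.

## Problem sizes and reproducibility

The full original design (N up to 1000, 10×10 schemes × 4 traits × 24
replicates) is cluster-scale.  This package's tests and the acceptance
script use N = 200 with 1–3 replicates per scheme, 100-year horizons for the
long-term quantities and 15-year horizons for the short-term comparison —
sizes chosen so a complete run fits on a single CPU in minutes while keeping
the per-scheme Monte-Carlo error near the published replicate SDs (0.08
percentage points for ΔF, 0.54 units for 100-year gain).  Contrasts between
schemes (short-term gain ratios, grid monotonicities) are evaluated with
common random numbers — the schemes being compared run on the same trait
architecture and seed stream — which removes architecture-sampling noise
from the comparison without touching the marginal distributions.  Every random
stream descends from one master seed; identical configuration and seed give
bit-identical summaries and pedigrees.

## Known limitations

* No mutation, linkage, dominance/epistasis, or csd sex-locus genetics; no
  imports, colony losses, or within-family selection variants.
* Worker groups are infinite expectations; finite-worker sampling noise is
  treated as part of σ²_E.
* The evaluator's relationship coefficients are this package's own
  derivation under the independent-pool-draw convention.  The companion
  coefficients used by established honeybee evaluations differ in
  conventions that are not recoverable here (finite drones per DPQ,
  within-mating paternity terms).  Long-term generational inbreeding rates
  are sensitive to such conventions: with this model they come out
  ~0.7–0.85× the published Table-2 values at N=200 while reproducing
  retained-variance levels, grid monotonicities (ΔF rising in k_d, falling
  and convex in k_s), the inverted-U of gain versus ΔF, and the short-term
  gain ordering.  The synthetic-data generator is therefore suitable for
  comparing schemes, which is its purpose; absolute ΔF levels should be read
  with that margin in mind.
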
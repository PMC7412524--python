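# hivesim

Agent-level simulation of closed honeybee (*Apis mellifera*) breeding
populations under yearly BLUP-based truncation selection.

Honeybee breeding programs for small, endangered subspecies must trade
genetic gain against inbreeding and loss of genetic variance.  The levers are
the **sister-group size** k<sub>d</sub> (each selected dam raises k<sub>d</sub>
daughter queens, so ⌊N/k<sub>d</sub>⌋ of the N yearly queens become dams) and
the **sire rate** k<sub>s</sub> (the k<sub>s</sub>% best three-year-old queens
each found an isolated mating station whose eight drone-producing colonies
are daughters of the founder).  `hivesim` simulates this system closed over a
century, queen by queen and drone by drone, and reports for every scheme
S<sup>k<sub>s</sub></sup><sub>k<sub>d</sub></sub>:

* the **performance criterion** — cohort mean of queen maternal plus
  worker-group direct true breeding values (genetic gain over the base
  population),
* the **inheritance criterion** variance — the selectable variance
  var(maternal + direct) left among queens,
* the **generational inbreeding rate**
  ΔF = 1 − (1 − F₁₀₀)<sup>2.5/99</sup> from exact drone-level pedigree
  inbreeding (generation interval 2.5 years: two on the maternal and three on
  the paternal path), with N<sub>e</sub> = 1/(2ΔF) and the FAO sustainability
  thresholds ΔF ≤ 0.5%/1%.

The genetic model is a finite-locus architecture: N<sub>l</sub> unlinked
biallelic additive loci, Beta(0.5, 0.5) base allele frequencies, maternal and
direct effect pairs from a Laplace/Normal mixture post-corrected so the base
additive covariance Σ_A is exact.  Colony records are
`y = queen maternal TBV + worker-group direct TBV + N(0, σ²_E)`, evaluated
with a honeybee mixed model: year×apiary fixed effects, a (maternal, direct)
effect pair per entity, and a sparse inverse of the bee-specific relationship
matrix in which a mating station's pooled drones act as the *pseudo-sire*.
Genetic parameters used by the evaluator are re-estimated every five years
from the Mendelian-sampling variance of simulated drones, var(δ_D) = (1−F_Q)·Σ_A.

## Worked example

```bash
python examples/single_scheme.py
```

runs N=60 queens/year with k_d=3, k_s=10 for 20 years and ends with

```
generation-rate summary after 20 years:
  genetic gain (criterion units): 3.39
  variance retained vs base:      75.6%
  generational inbreeding rate:   0.77%
```

i.e. the cohort of year 20 is 3.4 criterion units (≈2.8 genetic SD) above the
base population, three quarters of the selectable variance remains, and
inbreeding accumulates at 0.77% per generation (N<sub>e</sub> ≈ 65) — above
the strict FAO threshold, as expected for so small a population.  The other
examples cover the trait architecture, haplodiploid kinship (super-sister
relationship 3/4), and a small scheme-comparison grid with the
competitive-breeding-scheme rule (within 5% of the best gain).

A thin CLI wraps the same library:

```bash
hivesim simulate --n 200 --kd 3 --ks 10 --years 100 --reps 3 --seed 42 --out out/
hivesim grid --n 200 --kd 2,4,6 --ks 5,10 --reps 3 --seed 42 --out grid/
hivesim selftest
```

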
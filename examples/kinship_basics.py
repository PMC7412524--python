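"""Haplodiploid kinship: super sisters, half sisters, and inbreeding rates.

Queens are diploid, drones are single gametes of their mother.  Two queens
sharing dam AND father drone ("super sisters") have additive relationship
3/4; with father drones from unrelated queens it drops to 1/4.  The recursion
is cross-checked by gene dropping, and Wright's idealized-population formula
is shown as the heuristic comparator for inbreeding rates.
"""

import numpy as np

from hivesim import Pedigree, delta_f, effective_population_size, wright_delta_f

ped = Pedigree()
for q in ("dam", "m1", "m2"):
    ped.add_queen(q)
ped.add_drone("d1", "m1")
ped.add_drone("d2", "m2")
ped.add_queen("x", "dam", "d1")
ped.add_queen("y", "dam", "d1")  # same father drone -> super sisters
ped.add_queen("z", "dam", "d2")  # different drone source -> half sisters

print(f"super-sister additive relationship: {ped.relationship('x', 'y'):.3f}  (3/4)")
print(f"half-sister additive relationship:  {ped.relationship('x', 'z'):.3f}  (1/4)")

est = ped.gene_drop([("x", "y"), ("x", "z")], 50_000, np.random.default_rng(1))
print(f"gene-dropping estimates (50k drops): "
      f"f(x,y)={est[('x', 'y')]:.4f} (0.375), f(x,z)={est[('x', 'z')]:.4f} (0.125)")

# the generational rate transform and FAO benchmarks
f100 = 0.224
rate = delta_f(f100)
print(f"\nmean inbreeding 0.224 after 100 years -> dF = {100 * rate:.2f}% per generation")
print(f"equivalent effective population size Ne = {effective_population_size(rate):.0f}")
print(f"Wright comparator for 50 sires x 165 dams per generation: "
      f"{100 * wright_delta_f(50, 165):.2f}%")
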
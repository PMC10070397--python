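"""Critical driver-mutation numbers across the hierarchy.

Each driver mutation shifts a cell's division balance toward self-renewal by
S*Delta*R_k.  The critical mutation number is the smallest count of generic
drivers (on top of *BCR::ABL1*) that makes a cell self-sustainable at its
level.  Pool-I levels share one threshold (4 generics at strength 0.67, by
construction of the generic strength); committed pool-II levels, which start
with zero self-renewal, need far more — this is why the leukemic clone
expands inside pool I.
"""

from cmlsim import EvolutionParams, HierarchyConfig, build_level_rates
from cmlsim.mutation import UNREACHABLE, critical_mutation_number, delta_fraction

rates = build_level_rates(HierarchyConfig(hsc_divisions_per_year=1.18))
params = EvolutionParams(mu=9e-4, s_bcrabl=0.67, m_cap=40)
delta = delta_fraction(rates)

print(f"gamma_I = {rates.gamma_pool1:.3f}  ->  Delta = {delta:.4f}")
print(f"generic strength = {params.s_generic:.4f}\n")
print("level  pool  critical generics (with BCR::ABL1)")
for k in range(20):
    crit = critical_mutation_number(k, rates, params, has_bcrabl=True)
    label = "unreachable" if crit == UNREACHABLE else str(crit)
    pool = "I " if k < rates.pool2_start else "II"
    print(f"{k:>5}  {pool}    {label}")
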
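"""Build the default healthy blood-production hierarchy and print its table.

The hierarchy spans 21 levels: 10^4 HSCs at level 0, 5x10^11 mature cells in
the bone marrow at level 20, and 10^11 cells/day of mature-cell output.  The
printed table lists, per level, the cell number N_k, the differentiation
output delta_k (cells/day), the amplification factor gamma_k, and the
per-cell self-renewal, symmetric-differentiation and total division rates
(1/day).  The final lines report the pool-I (blast) fraction of the marrow —
physiologically 0-3% — and the solved pool-I amplification factor.
"""

from cmlsim import HierarchyConfig, build_level_rates

config = HierarchyConfig(hsc_divisions_per_year=1.18)
rates = build_level_rates(config)

table = rates.describe()
print(table.to_string(index=False,
                      float_format=lambda x: f"{x:.4g}"))

blast_pct = 100 * rates.N[:config.pool2_start].sum() / rates.N.sum()
print(f"\npool-I cell-number ratio : {config.pool1_number_ratio:.4f}")
print(f"solved pool-I gamma      : {rates.gamma_pool1:.4f}")
print(f"marrow blast fraction    : {blast_pct:.2f}% (healthy range 0-3%)")
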
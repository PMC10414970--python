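"""Mesh-penetration efficiency normalized to a reference variant.

Counts of roots crossing nylon meshes of different pore sizes are
normalized, per replicate, to the wild-type reference at the largest
pore size; the reference itself is normalized to its across-replicate
mean, so its average is 1.0 by construction.
"""

import pandas as pd

import rootph as rp

table = pd.DataFrame({
    "genotype":     ["Col-0", "Col-0", "mutant", "mutant"] * 2,
    "pore_size_um": [139.0, 109.0, 139.0, 109.0] * 2,
    "n_penetrated": [8, 5, 4, 1, 5, 4, 4, 0],
    "n_total":      [10] * 8,
    "replicate":    [1, 1, 1, 1, 2, 2, 2, 2],
})

result = rp.penetration_efficiency(table, reference=("Col-0", 139.0))
print(result.to_string(index=False))
print("\nthe mutant penetrates the 139 um mesh at "
      "%.0f%% of the wild-type efficiency"
      % (100 * result[(result.genotype == "mutant")
                      & (result.pore_size_um == 139.0)].efficiency_mean.iloc[0]))
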
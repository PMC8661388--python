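"""Pearson correlations between trait means with Holm adjustment.

Mirrors a leaf-trait correlation analysis: a carbon-isotope-like trait
weakly correlated (rho = 0.18) with one element, uncorrelated with the
rest. Pairs are computed on pairwise-complete observations and p-values
adjusted by Holm's step-down method across all off-diagonal pairs.
"""

import numpy as np
import pandas as pd

import namqtl as nq

rng = np.random.default_rng(7)
n = 500
d13c = rng.normal(size=n)
mo = 0.18 * d13c + np.sqrt(1 - 0.18**2) * rng.normal(size=n)  # weak, real
traits = pd.DataFrame(
    {
        "genotype": [f"ril{i:03d}" for i in range(n)],
        "d13C": d13c,
        "SLA": rng.normal(size=n),
        "Mo": mo,
        "Fe": rng.normal(size=n),
        "Zn": rng.normal(size=n),
    }
)
# some genotypes lack element measurements
traits.loc[traits.sample(40, random_state=1).index, "Mo"] = np.nan

result = nq.pearson_matrix(traits)
print(result.to_long().round(4).to_string(index=False))
print("\nAfter Holm adjustment only the simulated d13C-Mo association "
      "stays significant at 0.05; its r is near the simulated 0.18.")
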
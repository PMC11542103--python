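"""Compare a phenotypic correlation matrix with a 'genetic' one.

Genetic correlation matrices normally arrive as external tables (from
LD-score regression); here a noisy, slightly inflated copy of the phenotypic
matrix stands in (synthetic), so the paired statistics have a known
direction: d > 0 and a high correlation-of-correlations.
"""

import numpy as np
import pandas as pd

from retvasc.stats import (CorrelationMatrix, compare_correlation_sets,
                           correlation_matrix)

rng = np.random.default_rng(0)
n, k = 500, 17
latent = rng.standard_normal((n, 3))
loadings = rng.normal(0, 1, (3, k))
table = pd.DataFrame(latent @ loadings + rng.standard_normal((n, k)),
                     columns=[f"idp_{i}" for i in range(k)])
rp = correlation_matrix(table, kind="phenotypic")

g = rp.values.to_numpy().copy()  # synthetic genetic matrix: inflate + noise
iu = np.triu_indices(k, 1)
g[iu] = np.clip(g[iu] * 1.1 + rng.normal(0.03, 0.05, iu[0].size), -1, 1)
g[(iu[1], iu[0])] = g[iu]
rg = CorrelationMatrix(pd.DataFrame(g, index=rp.labels, columns=rp.labels),
                       kind="genetic")

cmp_ = compare_correlation_sets(rg, rp, n_perm=10_000, seed=1)
print(f"{cmp_.n_pairs} phenotype pairs "
      f"(17 phenotypes -> 17*16/2 = 136)")
print(f"Cohen's d (genetic minus phenotypic) = {cmp_.d:.3f}")
print(f"paired t({cmp_.df}) = {cmp_.t:.2f}, p = {cmp_.p:.2e}")
print(f"corr(r_g, r_p) = {cmp_.corr_of_corr:.3f}, "
      f"permutation p = {cmp_.permutation_p:.1e} "
      f"({cmp_.n_permutations} permutations)")
# d > 0 means genetic correlations run higher on average; the permutation p
# tests whether the two matrices share structure beyond chance pairing.
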
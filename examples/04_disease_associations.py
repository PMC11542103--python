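"""Phenotype-disease association battery with Bonferroni tiers.

Simulates prepared (z-scored, residualized) phenotypes for 2000 subjects and
two traits with known effects — one continuous (linear model), one binary
(logistic) — plus pure-noise traits to show the multiple-testing control.
"""

import numpy as np
import pandas as pd

from retvasc.stats import association_battery

rng = np.random.default_rng(5)
n = 2000
idps = pd.DataFrame(rng.standard_normal((n, 5)),
                    columns=["v_std_diameter", "a_tortuosity",
                             "bifurcations", "a_vascular_density",
                             "ratio_central_retinal_eq"])

traits = pd.DataFrame({
    "systolic_bp": 0.3 * idps["v_std_diameter"] + rng.standard_normal(n),
    "noise_trait": rng.standard_normal(n),
})
linear = association_battery(idps, traits, model="linear")
print("linear battery (standardized beta per SD):")
print(linear[["idp", "trait", "beta", "p", "tier"]].to_string(index=False))

logit_p = 1 / (1 + np.exp(-(0.6 * idps["a_tortuosity"] - 1.5)))
disease = pd.DataFrame({"hypertension": rng.binomial(1, logit_p)})
logistic = association_battery(idps, disease, model="logistic")
print("\nlogistic battery (odds ratio per SD):")
print(logistic[["idp", "trait", "effect", "p", "tier"]].to_string(index=False))
# Tiers: '*' p < 0.05/N_tests, '**' p < 0.001/N_tests with
# N_tests = N_phenotypes x N_traits; 'ns' otherwise.
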
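"""Semiparametric GWPR with adaptive-bandwidth selection.

Generates a cohort whose built-environment coefficient follows an east-west
gradient, selects the adaptive neighbour count by AICc, fits the
semiparametric GWPR (environmental coefficients local, individual ones
fixed), and prints the bandwidth trace, the MAICE comparison against the
global model and the distribution of local odds ratios.
"""

import numpy as np
import pandas as pd

from gwcommute import (
    KernelSpec,
    SemiparametricSpec,
    bandwidth_search,
    compare_models,
    discretize_outcome,
    fit_poisson_glm,
    summarize_local,
)
from gwcommute.synthetic import generate_cohort, scenario_g1

cohort = generate_cohort(scenario_g1(n=1000, seed=1))
y = discretize_outcome(cohort.hours)
X_local, X_global = cohort.env_design(), cohort.individual_design()

spec = SemiparametricSpec(
    local_columns=tuple(X_local.columns),
    global_columns=tuple(X_global.columns),
    kernel=KernelSpec("bisquare", "adaptive", neighbor_count=100),
)
search = bandwidth_search(y, X_local, X_global, cohort.points, spec,
                          grid=[100, 200, 400, 800])
print("AICc trace over candidate neighbour counts:")
print(search["trace"].round(1).to_string(index=False))

gwpr = search["fit"]
glm = fit_poisson_glm(
    y, pd.concat([pd.Series(1.0, index=X_local.index, name="Intercept"),
                  X_local, X_global], axis=1))
verdict = compare_models(gwpr, glm, names=("GWPR", "GPR"))
print(f"\nselected N = {search['selected']}, "
      f"delta AICc (GWPR - GPR) = {verdict['delta_aicc']:.1f}, "
      f"substantial = {verdict['substantial']}, preferred = {verdict['preferred']}")

print("\nlocal estimate summary (per locally varying term):")
print(summarize_local(gwpr).round(3))

j = gwpr.local_labels.index("env_built")
r = np.corrcoef(cohort.true_beta["env_built"], gwpr.local_coefficients[:, j])[0, 1]
print(f"\ncorrelation of fitted env_built surface with the generative truth: r = {r:.3f}")

# A substantial negative delta AICc says the local model earns its extra
# effective parameters; the OR range per term shows how much the
# association varies across the region (range 0 would be stationarity).
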
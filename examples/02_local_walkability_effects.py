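"""Fit geographically weighted regression and summarize the local effects.

One weighted regression per neighbourhood (adaptive bisquare kernel, 50
nearest neighbours) yields a local coefficient, t value and R-squared at
every site; the summary table shows how much each effect varies over space.
"""

import numpy as np

from gwrflow import CityConfig, KernelSpec, fit_gwr, generate_city, summarize_gwr
from gwrflow.preprocess import DEFAULT_COVARIATES, build_model_table

city = generate_city(CityConfig(seed=42, noise_sd=10.0))
table, _ = build_model_table(city.table)

fit = fit_gwr(table, "normalized_obese", DEFAULT_COVARIATES, KernelSpec("adaptive", 50))
summary = summarize_gwr(fit)

print(f"local regressions: {summary.n_regressions}, bandwidth: {summary.bandwidth} neighbours")
print(f"local R^2: min {summary.local_r2_min:.2f}, mean {summary.local_r2_mean:.2f}, max {summary.local_r2_max:.2f}")
print(summary.coefficients.round(2))

true = city.true_surfaces.set_index("id").loc[table["id"], "beta_obese_walkscore"]
corr = np.corrcoef(true, fit.local["beta_walkscore"])[0, 1]
print(f"\ncorrelation of estimated vs true walkscore surface: {corr:.2f}")
print(
    "-> the walkscore row's wide range (strongly negative minimum) is the\n"
    "   spatially varying effect; the correlation shows the kernel recovered\n"
    "   the generator's hidden coefficient surface."
)
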
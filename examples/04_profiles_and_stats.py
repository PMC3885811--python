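"""Along-tract profiles and varying-coefficient statistics on a cohort.

Generates a synthetic cohort whose FA profiles carry a known age effect,
fits the varying-coefficient model, runs the wild-bootstrap global test and
the FDR-corrected local tests, and prints where the effect is found.
"""

import numpy as np

import tractokit as tk
from tractokit.stats import VCModelSpec, export_stats_csv, run_stats
from tractokit.synthetic import CohortSpec, simulate_profile_cohort

effect = lambda s: 0.015 * np.exp(-((s - 5.0) / 5.0) ** 2)
spec = CohortSpec(n_subjects=20, noise_sd=0.008,
                  beta_functions={"age": effect}, seed=3)
profiles, covariates, true_betas = simulate_profile_cohort(spec)
print(f"cohort: {len(covariates)} subjects, age "
      f"{covariates['age'].min()}-{covariates['age'].max()} weeks")

model = VCModelSpec(covariates=["age"], n_resamples=500, seed=1)
results = run_stats(profiles, covariates, model)
res = results["age"]
print(f"global age effect: p = {res.p_global:.4f}")
sig_at = res.grid[res.significant]
print(f"FDR-significant bins at arclength {sig_at} mm")
# The significant bins concentrate around s = 5 mm where the effect peaks.

peak_est = np.nanmax(np.abs(res.beta))
print(f"estimated peak |beta_age| = {peak_est:.4f} FA/week "
      f"(planted 0.0150)")

table = export_stats_csv(results)
print(f"stats table columns: {list(table.columns)}")
# The CSV (arclength first) feeds merge_stats_with_fibers for rendering.
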
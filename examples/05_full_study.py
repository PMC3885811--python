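"""The complete end-to-end study on a synthetic cohort.

Cohort generation -> DWI simulation and QC -> tensor estimation -> unbiased
DTI atlas -> label-map tractography -> cleaning -> origin-plane arclength
parameterization -> per-subject profiles in original space via the Global
Displacement Fields -> varying-coefficient statistics with FDR -> statistics
mapped back onto the fiber bundle.

Takes several minutes: the atlas build dominates.
"""

import numpy as np

from tractokit.workflow import run_study

result = run_study(seed=1)
print(f"fibers tracked on the atlas: {result.n_fibers}")
print(f"atlas sharpness progression: "
      f"{ {k: round(v, 3) for k, v in result.sharpness.items()} }")
print(f"global age-effect p-value: {result.p_global:.4f}")
print(f"FDR-significant bins: {int(result.significant_mask.sum())}")
print(f"overlap with the planted effect support (Jaccard): "
      f"{result.jaccard:.2f}")
# A Jaccard well above zero means the pipeline localized the planted
# age-FA interaction at the right stretch of the tract; the merged bundle
# (result.merged_bundle) carries the corrected p-values as point data,
# ready for any VTK viewer.
print(f"timings (s): { {k: round(v) for k, v in result.timings.items()} }")
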
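"""Central composite design and response-surface analysis of casing
modification.

Generates the 5-factor half-fraction CCD (alpha = 2, 6 center replicates,
32 runs), simulates pH responses from the built-in published quadratic
surface plus noise, refits the 21-term model and prints the ANOVA
decomposition with its lack-of-fit test.
"""

import numpy as np

from hsiph import (anova_quadratic, evaluate_surface, fit_quadratic_surface,
                   generate_ccd, generate_rsm_responses, preset_surface)

design = generate_ccd(seed=7)  # randomized run order
print(f"design: {design.n_runs} runs "
      f"({design.run_type.count('factorial')} factorial, "
      f"{design.run_type.count('axial')} axial, "
      f"{design.run_type.count('center')} center)")

truth = preset_surface()
print(f"surface at the uncoded origin: "
      f"{evaluate_surface(truth, [0, 0, 0, 0, 0]):.4f}")

y = generate_rsm_responses(truth, design, noise_sd=0.3, seed=7)
fitted = fit_quadratic_surface(design, y)
pred_err = [abs(evaluate_surface(fitted, run) - evaluate_surface(truth, run))
            for run in design.uncoded]
print(f"noisy refit: max |surface error| over the design = {max(pred_err):.3f} pH")

anova = anova_quadratic(design, y)
keep = ["Model", "Linear", "Square", "2-Way Interaction", "Error",
        "Lack of Fit", "Pure Error", "Total"]
print(anova[anova.source.isin(keep)].to_string(
    index=False, float_format=lambda v: f"{v:.3f}"))
# A nonsignificant lack of fit (p > 0.05) indicates the quadratic model is
# adequate relative to center-replicate noise.
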
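"""Detect a small-island effect by piecewise species-area regression.

Simulates an archipelago whose richness follows a three-segment
species-area relationship -- a near-flat small-island regime, an
extinction/immigration regime of moderate slope, and a steep
large-island regime -- then fits all five candidate forms and ranks
them by AIC.
"""

import numpy as np

from islesar import ModelForm, SARParams, SARSimConfig, run_sie_analysis, simulate_sar

truth = SARParams(
    intercepts=(0.244, 0.280, 0.031),
    slopes=(0.080, 0.297, 0.421),     # z1 near zero = weak area dependence
    thresholds=(-0.603, 0.946),       # log10 km^2 break points
)

data = simulate_sar(SARSimConfig(
    n_islands=500,
    true_form=ModelForm.THREE_SLOPE,
    true_params=truth,
    noise_sd=0.05,
    seed=42,
))

table = run_sie_analysis(data)
with np.printoptions(precision=3):
    print(table.to_frame().round(3).to_string(index=False))

best = table.fits[table.best]
print(f"\nbest model: {table.best.value} (Akaike weight {table.weight[table.best]:.3f})")
print(f"estimated break points (log10 km^2): {[round(t, 3) for t in best.params.thresholds]}")
print("\nThe first break point delimits the small-island effect: below it,")
print("richness is almost independent of area.  The second marks where the")
print("slope steepens, the regime where in situ speciation dominates.")
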
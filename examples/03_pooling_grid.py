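"""Computational pooling: simulate mixtures without new experiments.

Pools two simulated one-state cultures (75% and 40% light-sugar usage)
channel-by-channel at several ratios, fits the two-state model to each
pool, and scores the inference error against the known pool composition.
"""

import numpy as np

from isopop import (
    BiochemParams,
    FitOptions,
    MeasurementModel,
    PopulationModel,
    PopulationState,
    fit_model,
    pooling_grid,
)

biochem = BiochemParams(ap=0.9, rev=0.5, ppp=0.5, co2=0.1)
mm = MeasurementModel()

library = [
    (mm.predict(PopulationModel.one_state(PopulationState(u, biochem)), f"u{u:g}"), u)
    for u in (0.75, 0.40)
]
grid = pooling_grid(library, p_a_values=(0.25, 0.5, 0.75), pairs=[(0, 1)])

print("pool_A  true_minor  delta_usage  inferred_pA  inferred_usages")
for meas, spec in grid:
    fit = fit_model(meas, 2, FitOptions(multistart=6, seed=3), mm)
    (w_a, s_a), (_, s_b) = fit.model.states
    print(
        f"{spec.p_a:6.2f}  {spec.min_population:10.2f}  {spec.delta_usage:11.2f}"
        f"  {w_a:11.3f}  ({s_a.usage12c:.3f}, {s_b.usage12c:.3f})"
    )

print(
    "\nWith a 35-point usage difference the pool ratio and both usages are"
    "\nrecovered to ~0.01 on noise-free inputs; accuracy degrades as the"
    "\nusage difference between the two subpopulations shrinks."
)
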
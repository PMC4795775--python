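"""Carbon-shift time course: growth dilution and its correction.

Simulates a switch from a light to a heavy sugar monitored over several
doublings.  Uncorrected fits see the pre-shift amino acids as a decaying
"old" subpopulation (2^-doublings of the pool); after subtracting the
diluted previous time point, the fits report only what was synthesized in
each interval — a single population on the new sugar.
"""

from isopop import FitOptions, MeasurementModel, ScenarioSpec, TimeCourse, make_scenario, shift_analysis

mm = MeasurementModel()
spec = ScenarioSpec(
    "shift_timecourse", stamps=(0.9, 2.0, 4.5, 9.0), n_replicates=1, seed=5
)
samples = [m for m, _ in make_scenario(spec, mm)]

report = shift_analysis(TimeCourse(samples), FitOptions(multistart=3, seed=2), mm)
cols = ["doublings", "corrected", "chosen_states", "p_a", "usage_a", "usage_b"]
print(report[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))

print(
    "\nUncorrected rows track the old population decaying as 2^-doublings"
    "\n(0.536 at 0.9 doublings, 0.044 at 4.5) until it falls below ~5% and"
    "\nbecomes undetectable; corrected rows are one-state with usage_a ~ 0,"
    "\ni.e. ~100% heavy-sugar usage, at every interval."
)
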
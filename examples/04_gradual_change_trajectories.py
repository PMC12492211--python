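"""Gradual snowmelt advance: trajectories for the hybrid-zone population.

Snowmelt advances 0.20 d/yr from 2023; baseline fitness, selection strength
and the fitness-trait slope all track the snowmelt day (the printed
site-level regressions).  Four deterministic scenarios are compared.
"""

from evorescue import hybrid_params, run_gradual_model


def report(label, **flags):
    traj = run_gradual_model(hybrid_params(**flags.pop("params", {})), **flags)
    year = traj.extinction_year()
    if year is None:
        print(f"{label:35s} persists (min N = {traj.n.min():.1f})")
    else:
        print(f"{label:35s} extinct in {year} (generation {traj.extinction_step()})")


report("no evolution:", evolution=False)
report("evolution (h2 = 0.10):", evolution=True)
report("evolution (h2 = 0.30):", evolution=True, params={"h2": 0.30})
report("evolution + plasticity:", evolution=True, plasticity=True)
print()
print("Under the realistic gradual trend, field-strength evolution alone")
print("only postpones extinction; adaptive plasticity (1.323 cm^2/g per")
print("snowmelt day) tips the hybrid population into rescue.")
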
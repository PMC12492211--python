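"""Rescue probability under full stochasticity, both populations.

Adds year-to-year snowmelt noise (SD 11.4 d) and Poisson demographic
stochasticity on top of selection and plasticity, and asks how often each
population escapes functional extinction by 2400.
"""

from evorescue import aggregata_params, hybrid_params, rescue_probability

for params in (hybrid_params(), aggregata_params()):
    res = rescue_probability(params, n_reps=200, seed=11)
    print(f"{params.site:10s} rescued fraction = {res.fraction:.2f} "
          f"(95% Wilson CI {res.ci_low:.2f}-{res.ci_high:.2f}, "
          f"{res.n_rescued}/{res.n_reps} replicates)")
print()
print("The hybrid population is rescued in most runs (the year growth turns")
print("positive varies hugely with the snowmelt noise); the I. aggregata")
print("population, with weaker snowmelt-sensitive selection, is not.")
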
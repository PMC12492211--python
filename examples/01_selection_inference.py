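"""Estimate phenotypic selection on SLA from a plant-level survival table.

Generates a synthetic single-year panel (400 plants, two sites) whose true
standardized differential is about -0.23, then runs the full inference
pipeline: standardize the trait, relativize fitness, estimate the
differential by least squares with a site factor, and test it with a
binomial GLM.
"""

from evorescue import (
    SyntheticTruth,
    estimate_quadratic_gradient,
    estimate_selection_differential,
    generate_trait_fitness,
    relative_fitness,
    standardize_trait,
)

table = generate_trait_fitness(SyntheticTruth(seed=42))
prepared = relative_fitness(standardize_trait(table))

est = estimate_selection_differential(prepared)
quad = estimate_quadratic_gradient(prepared)

print(f"plants: {est.n}, mean survival: {table['survival'].mean():.3f}")
print(f"true S' (in-table oracle):  {table.attrs['true_sprime']:+.3f}")
print(f"estimated S':               {est.estimate:+.3f} (SE {est.se:.3f}, "
      f"GLM p = {est.p_value:.2g})")
print(f"quadratic gradient:         {quad.estimate:+.3f} (SE {quad.se:.3f})")
print()
print("A negative S' means thicker leaves (lower SLA) survive better; the")
print("estimate should sit within ~2 SE of the oracle, and the quadratic")
print("gradient near zero (the generating fitness surface is monotone).")
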
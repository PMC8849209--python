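"""How much must a donor food group scale to replace removed meat?

Uses a tuned synthetic world in which, after removing all meat, closing the
vitamin B12 gap requires exactly tripling dairy production or quadrupling
fish production.  The multiplier is solved in closed form from the gap
identity and verified by applying the scenario and re-measuring the gap.
"""

from nutriflow import synthetic
from nutriflow.scenario import (
    ScenarioSpec,
    apply_scenario,
    nutrient_gaps,
    replacement_multiplier,
)

bundle = synthetic.make_b12_replacement_world()

for donor in ("dairy", "fish_seafood"):
    m = replacement_multiplier(
        bundle, donor, synthetic.MEAT_GROUPS, "vitamin_b12"
    )
    closed = apply_scenario(
        bundle,
        ScenarioSpec(
            removals=frozenset(synthetic.MEAT_GROUPS), scalings={donor: m}
        ),
    )
    gap = nutrient_gaps(closed).set_index("nutrient_id").at[
        "vitamin_b12", "gap_percent"
    ]
    print(f"donor={donor}: multiplier={m:.6f}, residual gap={gap:.2e}%")

print()
print(
    "A multiplier of 3.0 means the donor's entire supply chain must triple "
    "to deliver enough bioaccessible vitamin B12 once meat is gone; the "
    "residual gap of ~0 confirms the closed-form solution round-trips "
    "through the full model."
)
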
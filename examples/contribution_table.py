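"""Decompose global nutrient availability into food-group contributions.

Builds the fixed global-2018-like fixture (meat groups hold 316 Mt of food
mass, ~7% of the food system, population 7.53e9) and prints the
contribution table: each cell is the percentage of the global availability
of a nutrient supplied by a food group, with protein and the indispensable
amino acids on a bioavailability-adjusted basis.  Cells in (0, 0.5)% print
"<0.5"; exact zeros print "No contribution".
"""

from nutriflow import pipeline, synthetic

bundle = synthetic.make_global_2018_world()
result = pipeline.run(bundle, focus_groups=synthetic.MEAT_GROUPS)

print("headline summary")
print("----------------")
print(pipeline.format_summary(result.summary))
print()
print("contribution table (rows: food groups, % of global availability)")
print(result.contributions.display().T.to_string())
print()
print(
    "The meat rows dominate vitamin B12 and contribute nothing to fiber; "
    "the mass decomposition above matches the 23/34/32/2/9 split of the "
    "316 Mt meat food supply."
)
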
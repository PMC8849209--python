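# nutriflow

A global food-system mass-balance model of nutrient availability.

`nutriflow` answers questions of the form *"what share of the world's
supply of nutrient X comes from food group G, and what happens if G is
removed or scaled?"*. It is aimed at researchers in sustainable-nutrition
and food-systems modelling who work with Food Balance Sheet (FBS) style
commodity accounts and food-composition tables, and who need a transparent,
fully testable pipeline from supply-side mass ledgers to per-capita
bioavailable nutrient supply.

## The model

For each commodity $c$ the supply-side ledger (tonnes, one reference year)
is reduced to the mass available as food:

$$
F_c = P_c + I_c - E_c - \text{feed}_c - \text{seed}_c - \text{other}_c -
\text{losses}_c - \text{proc}_c
$$

Commodity-tree processing first redistributes each parent's processing
input to child commodities with extraction rates $r_{p \to c}$ (e.g. a
slaughter stream yielding separated offal and fats); rates compose along
multi-level chains, and the residual $1 - \sum_c r_{p\to c}$ leaves the food
system. Inedible portions $\iota_c$ (by commodity) and in-home waste
$\omega_c$ (by region, population-weighted to a global value) then reduce
available food mass to consumed mass:

$$
C_c = F_c\,(1 - \iota_c)(1 - \omega_c)
$$

Consumed mass is converted to 29 nutrients via composition per 100 g edible
portion, $q_{c,n}$:

$$
A_{c,n} = C_c \cdot 10^4 \cdot q_{c,n}, \qquad
A^{\mathrm{bio}}_{c,n} = \beta_{c,n} A_{c,n}
$$

where the bioavailability coefficient $\beta_{c,n} \in (0,1]$ applies to
protein and the seven indispensable amino acids only (all other nutrients
are reported gross). Group contributions are percentages of the global
total, $100\,A_{g,n}/\sum_{g'} A_{g',n}$; per-capita daily supply is
$A_n / (365\,\mathrm{pop})$; and a nutrient gap against a per-capita daily
reference value $R_n$ is $\max(0,\,100\,(1 - a_n/R_n))$.

Scenarios perturb the bundle declaratively: remove food groups, scale all
supply-side flows of a group by a multiplier, change the target year or
population. The replacement multiplier — the smallest $m \ge 1$ scaling a
donor group so a nutrient meets its requirement with other groups removed —
is solved in closed form as $m = (R_n \cdot \mathrm{pop} \cdot 365 -
A_{\text{other}})/A_{\text{donor}}$ and verified by round-tripping through
the scenario engine.

## Worked example

```sh
python examples/contribution_table.py
```

builds a fixed synthetic world shaped like the 2018 global food system and
prints, among other output:

```
food mass share of total: 7.0%
per-capita availability: 115.0 g/person/day
share of global energy: 10%
share of global fat: 37%
share of global protein: 22%
subgroup shares of focus food mass:
  ruminant_meat: 23%
  poultry_meat: 34%
  pig_meat: 32%
  other_meat: 2%
  offal_and_fats: 9%
```

The five meat groups hold 316 Mt of food mass — about 7% of the food
system — which at a population of 7.53 billion is ~115 g per person per
day; the subgroup lines decompose that mass. The full contribution table
(29 nutrients × food groups) is printed alongside, using the display
convention that values in (0, 0.5)% render `<0.5` and exact zeros render
`No contribution` (e.g. every meat group's fiber cell).

Other examples: `no_meat_scenario.py` (remove all meat, scale the rest by
1.2, report per-nutrient gaps), `replacement_multiplier.py` (a tuned world
where dairy must triple, or fish quadruple, to close the vitamin B12 gap
once meat is removed), and `generate_and_verify_world.py` (seeded world
generation checked bitwise against a brute-force oracle).

There is also a thin CLI over the same library:

```sh
nutriflow generate --out world/ --seed 5     # write a synthetic bundle
nutriflow validate world/
nutriflow run world/ --out results/
nutriflow scenario world/ --scenario no_meat.yaml --out scen/
```

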
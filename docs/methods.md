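# Methods

## Model and assumptions

`nutriflow` is a single-reference-year, global mass-balance model of the
food system. Its inputs mirror the structure (not the content) of the
standard public sources: Food Balance Sheet-style commodity ledgers in
tonnes, a commodity tree with extraction rates, nutrient composition per
100 g edible portion, inedible-portion and in-home-waste fractions,
bioavailability coefficients for protein and seven indispensable amino
acids, population counts, and per-capita daily nutrient reference values.
The model is deliberately global: there is one aggregate consumer, trade
must net out worldwide, and distributional questions (who actually eats
what) are outside its scope. Stock variation, bilateral trade, intra-year
seasonality, diet-level nutrient interactions and mineral bioavailability
are likewise out of scope. Multi-year inputs are not smoothed or
extrapolated; the bundle carries exactly one balance year.

The pipeline stages and their contracts:

1. **Processing** distributes each parent commodity's `processing_input`
   to children as `rate × throughput`; the residual share leaves the food
   system. Parents are visited in (lexicographic) topological order and a
   child's processed inflow is forwarded into its own `processing_input`
   when the child has outgoing rules, so extraction rates compose along
   chains (animal → carcass → cuts gives the product of the two rates). A
   consequence is that pure intermediates net to zero food mass; to model
   partial direct consumption of an intermediate, route an explicit rate to
   a leaf child instead.
2. **Net supply** subtracts feed, seed, other uses, losses and processing
   input from production plus net trade. Negative results are clamped to
   zero with a warning (real ledgers contain stock changes this model
   omits). In `strict_zero` trade mode, |imports − exports| greater than
   10⁻⁶ × production is an error: at global scope trade must cancel, and
   the tolerance is there purely for float safety.
3. **Inedible, then waste.** Edible mass is `available × (1 − inedible)`;
   consumed mass is `edible × (1 − waste)`. The two orders differ
   numerically; inedible-first is fixed because the inedible portion is a
   property of the item while in-home waste acts on what reaches the
   kitchen. The result fields are derived subtractively so the
   conservation identities (`available = edible + inedible_mass`,
   `edible = consumed + wasted`) hold exactly, not to rounding.
4. **Nutrients.** `gross = consumed × 10⁴ × per-100 g amount` (1 t = 10⁴
   hundred-gram portions); bioavailable = gross × coefficient for protein
   and the seven amino acids, gross otherwise. Energy is an ordinary
   composition column in kcal, not derived from macronutrients. Missing
   composition cells contribute zero and are logged, never silently
   imputed.
5. **Contributions** divide group totals by the total over *all* groups in
   the bundle, so columns close to 100 by construction; a nutrient with
   zero global availability is marked undefined (NaN / `n/a`), not 0.
   Because bioavailable equals gross outside protein/IAA, the default
   `bioavailable` basis *is* the mixed reporting convention (digestibility-
   adjusted amino acids, gross everything else).
6. **Scenarios** scale every supply-side flow of a commodity uniformly, so
   a group's food fraction is invariant under scaling and availability is
   linear in the multiplier — except where a group receives processing
   inflow from a differently-scaled parent, in which case it is affine.
   The replacement multiplier is therefore solved from two pipeline
   evaluations (donor zeroed vs baseline), which equals the closed form
   `(R·P·365 − A_other)/A_donor` in the linear case and remains exact in
   the affine case; `inf` marks a donor that cannot close the gap.
   Removal drops processing rules whose child group is removed (that mass
   leaves the food system) and zeroes the ledgers of removed commodities.

## Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| masses | tonnes | t | FBS convention (reported in 1000 t) |
| composition | per 100 g edible | registry unit | food-composition convention |
| tonne→100 g factor | 10⁴ | — | single explicit constant |
| days per year | 365 | d | per-capita daily quantities |
| meat waste range | 0.02–0.11 | — | regional in-home waste spread for meat |
| meat inedible range | 0.08–0.43 | — | by meat type (poultry high: bone/skin) |
| bioavailability range | 0.68–1.0 | — | digestibility span, offal at the low end |
| trade-netting tolerance | 10⁻⁶ × production | — | float-safe equality |
| extraction-sum slack | 10⁻¹² | — | float-safe ≤ 1 check |

The unit registry (29 nutrients) defaults to kcal for energy, g for
macronutrients and amino acids, mg/µg for micronutrients (selenium, vitamin
A, B9 and B12 in µg), and is configurable via `units.csv` because published
reference tables disagree on µg-vs-mg conventions for several vitamins.
Vitamin A is one aggregated column; retinol and pro-vitamin A are not
separated. Per-capita reference values are single global adult-level
figures; demographic stratification is out of scope.

Regional waste fractions are collapsed to one global fraction per commodity
by a population-weighted mean. A mass-weighted mean would be preferable in
principle, but a global bundle carries no regional food masses; population
weighting is equivalent under equal per-capita supply, and a GLOBAL row
always wins outright.

Display rounding is half-up to integer percent (ties like 20.5 → 21,
implemented in decimal arithmetic to avoid binary-float tie artifacts);
raw unrounded values are always carried alongside in outputs.

## The synthetic-data generator

`generate_world` emulates the *structure* of real inputs: five meat-like
groups plus non-meat groups, a processing chain producing an offal-like
child, full 29-nutrient composition grids with configurable sparsity,
meat fractions drawn inside the ranges above, and populations of global
scale. It makes no attempt at statistical realism of real FBS time series,
country-level resolution, or correlated composition profiles; passing
tests on these worlds demonstrates the correctness of the accounting, not
the realism of any particular magnitude.

Two numerical choices matter. First, every sampled quantity sits on a
dyadic grid (integer masses; fractions in 64ths; coefficients in 32nds;
extraction rates that are powers of two; composition amounts as an integer
multiple ≤ 64 of a per-nutrient power-of-two quantum). The grids are sized
so that every product and every partial sum the pipeline forms is exactly
representable in float64, which makes summation order irrelevant and lets
the test suite demand *bitwise* equality between the vectorised pipeline
and the naive per-record oracle — a far stronger check than a tolerance.
Second, the generator uses one explicit seeded `numpy` Generator per world
and no global state, so equal seeds give byte-identical bundles.

The fixed fixtures are synthetic constructions, not data: the
"paper-like" world hard-codes a 316 Mt meat food supply split 23/34/32/2/9
across the five meat groups (offal arriving via the processing chain),
meat at ~7% of total food mass, and a 7.53 × 10⁹ population (≈115 g
meat/person/day); the B12 replacement world is built by inverting the
replacement closed form so that dairy must scale ×3 (fish ×4) to close the
vitamin B12 gap once meat is removed, with a gap-free baseline. Their
decimal magnitudes are not dyadic, so oracle comparisons on these fixtures
use a 10⁻¹² relative tolerance instead of bitwise equality.

## Degenerate inputs and tie-breaks

Zero global availability of a nutrient → undefined contribution cells,
never 0/0. Zero population is a domain error. Commodities without
bioavailability records default to a coefficient of 1.0 with one logged
warning. Missing fraction records default to 0. Negative net supply clamps
to zero (warned). Processing cycles and extraction-rate sums above 1 are
validation errors. In lenient reads, absent composition cells become
explicit missing markers; in strict reads they are errors — strictness
changes error handling only, never numbers.

## Known limitations

- Single global region and single reference year; no trend estimation
  across input years.
- Uniform scaling of a whole group ledger cannot express substitution
  within a group or price/land feasibility of large multipliers; the
  replacement multiplier is a nutritional statement only, solved one
  nutrient at a time (joint feasibility is reported as the max).
- Bioavailability applies to protein and seven amino acids only; mineral
  absorption effects (phytates, haem vs non-haem iron) are not modelled.
- The contribution denominator is the bundle's food set: leaving a food
  group out of the bundle inflates every other group's percentages.
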
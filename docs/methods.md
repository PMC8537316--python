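# Methods

## The model

`sustainaswap` models a deliberately small intervention: replacing one
serve of a reference food (beef, in the bundled data) with a portion of a
more environmentally sustainable alternative, either once per week over a
270-day pregnancy or once per day, and asks two questions — what happens
to nutrient provision, and what happens to the environmental footprint of
the diet. The answer is computed at three scales: per serve, per
pregnancy, and across a cohort of individual intake records.

### Portion matching

The alternative's portion is scaled so that it carries exactly the same
energy (isoenergetic basis) or the same protein (protein basis) as one
standard serve of the reference food:

    scale = ref_energy / alt_energy      (energy basis)
    scale = ref_protein / alt_protein    (protein basis)

All nutrients, the cooked weight and the retail weight of the alternative
scale linearly by this factor; a `fixed` basis uses the alternative's own
standard serve unscaled (needed for fixed-portion swaps such as a daily
glass of milk for soy milk). Matching is by the alternative's own
nutrient density; the scale is never rounded to kitchen-realistic
portions. Reports round weights to whole grams, which is why the familiar
figures ("94 g of firm tofu matches a 65 g beef serve") look tidy while
the internal numbers are not.

### Absorbed iron

Total iron understates the nutritional difference between animal and
plant foods because heme iron (animal flesh only) is absorbed much more
efficiently than non-heme iron. The model assumes:

- plant foods: 100% of iron is non-heme;
- animal foods: 40% heme, 60% non-heme;
- absorption in a mixed diet: 25% of heme iron, 16.8% of non-heme iron.

This gives a single multiplier per origin: 0.168 for plants and
0.6·0.168 + 0.4·0.25 = 0.2008 for animal foods. All three proportions are
parameters of `IronAbsorptionParams`; the defaults are conservative for
pregnancy, during which non-heme absorption is upregulated. Enhancer and
inhibitor effects (vitamin C, the meat factor) are out of scope: they are
real but not quantified in this model.

### Environmental footprint

Each food carries five production intensities per kg of retail weight:
GHG (kg CO₂ eq), land occupation (m²·yr), acidifying emissions
(g SO₂ eq), eutrophying emissions (g PO₄³⁻ eq) and stress-weighted water
use (L), taken from global life-cycle-assessment means. A serve's
footprint is intensity × retail weight of the (scaled) portion; a habit's
footprint multiplies by the number of serves — 270/7 ≈ 38.571 for a
weekly serve over a 270-day pregnancy (the fractional count matters: an
integer week count would visibly misstate the totals), or 270 for a daily
one.

GHG totals are translated into "km driven by an average passenger car"
using 0.400 kg CO₂ eq per mile (the US EPA typical-vehicle figure) and a
1.61 km/mile conversion. The rounded 1.61 — rather than 1.60934 — is
deliberate: it is the convention under which the published
serve-to-distance figures in this literature reproduce exactly
(372.2 kg → 1498 km, 363 kg → 1461 km, 383.8 kg → 1545 km,
138.9 kg → 559 km). Both factors are parameters of `VehicleEquivalence`.
A swap that *increases* GHG reports a km-equivalent of 0 with a warning,
never a negative distance.

### Swap deltas

A swap's result is the componentwise difference (alternative − reference)
of the two matched serves' nutrient profiles, absorbed iron, and per-serve
and per-pregnancy footprints. Deltas are computed from unrounded values
and rounded only in reports: nutrients to 1 dp, absorbed iron to 2 dp,
footprints to 1 dp, distances to whole km, all half-up (ties away from
zero; Python's built-in banker's rounding would disagree on .5
boundaries).

### Cohort modelling

An intake record is one person's FFQ-derived daily nutrient intake plus
their weekly consumption of the reference food. A weekly swap perturbs
daily intake by delta/7. Two application modes exist because they answer
different questions:

- **per_individual** (default): only records meeting an eligibility rule
  (≥ 1 reference-food serve/week, comparator configurable) are shifted.
  The population mean then moves by eligible_fraction × delta/7. This is
  the realistic model of who can actually make the swap.
- **uniform**: every record is shifted. Summary statistics translate
  rigidly — mean, median and all quantiles move by exactly delta/7, and
  the SD and IQR width are invariant. Published before/after summary
  tables whose SDs are identical in both columns were produced this way,
  and this mode reproduces them.

The eligibility comparator defaults to ≥ 1 serve/week even though the
source description says "> 1"; with integer serve counts the two
comparators differ, the published 65.5% eligible fraction is treated as
an empirical quantity either way, and ≥ is the reading consistent with
"consumes the food weekly". Shifted intakes are clipped at zero.

Compliance with a Nutrient Reference Value is intake ≥ threshold; an
Adequate Intake (AI, used for fiber) is scored identically to an
Estimated Average Requirement (EAR). Summaries report mean, SD (n−1
denominator), median and the 25th/75th percentiles using linear
interpolation between order statistics (numpy's default), so IQR columns
are reproducible; a single-record cohort reports SD 0 with a warning.
Iodine and saturated fat carry no NRV here and flow through deltas only.

## Synthetic cohorts

Individual-level intake data from the motivating study population is not
publicly available, so the generator emulates its statistical structure:

- **Marginals**: log-normal per nutrient, chosen because FFQ-derived
  intake distributions are right-skewed (the observed medians sit below
  the means for every nutrient). Parameters are moment-matched so the
  *arithmetic* mean and SD hit the targets: σ² = ln(1 + s²/m²),
  µ = ln m − σ²/2. Default targets are the observed means/SDs of a
  171-woman Australian pregnancy cohort (e.g. iron 14.2 ± 6.9 mg/day,
  calcium 984.1 ± 332.9 mg/day).
- **Dependence**: a Gaussian copula — a latent multivariate normal pushed
  through each marginal. The latent correlation is exchangeable at 0.3 by
  default: nutrient intakes co-vary because overall food volume does, but
  the true correlation structure is unknowable from published summaries,
  so the coefficient is exposed in the configuration (a full matrix is
  accepted; PSD is validated, and a semi-definite matrix is factored by
  eigendecomposition rather than Cholesky).
- **Reference-food serves**: a zero-inflated Poisson (rate 2 serves/week
  before inflation) with the inflation set so P(serves ≥ 1) equals the
  configured eligible fraction, 0.655 by default. Only eligibility
  matters downstream; the count distribution is plausibility dressing.

What the generator does *not* emulate: food-level (96-item FFQ) intakes,
reporting error, day-to-day variance, or any true nutrient–nutrient
correlation structure. Consequently, passing cohort tests demonstrates
that the *machinery* (shift laws, compliance counting, summary
invariances) is correct, not that the synthetic cohort reproduces the
study population's compliance counts — those depend on the restricted
raw data and are excluded from exact checks. The generator-based checks
are instead: parameter recovery at n = 10⁵ (means within 1%, SDs within
3%), the uniform-shift invariances, exhaustive hand counts on toy
cohorts, and the per-individual mean-shift law at n = 10⁴. These sizes
run in seconds on one CPU.

## The bundled food table

The fixture covers beef and its thirteen lower-emission comparison
foods. Each food's *standard serve* is defined as its isoenergetic serve
(471 kJ, the energy of one 65 g cooked beef serve), with nutrients as
published per that serve; energy matching therefore yields scale 1 and
the published serve weights exactly, and protein matching scales from
there (firm tofu: 94 × 20.2/11.3 ≈ 168 g).

Retail serve weights are not published. They are derived per food from
the GHG identity retail = per-serve GHG / GHG intensity, where the
unrounded per-serve footprint is recovered from the published
weekly-serve pregnancy total divided by 270/7 (that block is printed at
higher effective precision than the per-serve block), and GHG intensity
per kg comes from the published text where stated (beef 99.5 — with
beef's retail weight fixed at the implied 0.100 kg — chicken 9.9, white
fish 13.6) and from global LCA means otherwise. The remaining four
intensities per food are back-derived as per-serve value / retail
weight, making the fixture exactly self-consistent: serve- and
pregnancy-scale footprints reproduce the published cells to their
printed precision, with one known exception (mixed nuts' per-serve water
rounds to 2597 L from the pregnancy total but is printed 2598 L — the
two printed cells are mutually inconsistent) and one 1-km report
difference (lamb's pregnancy distance computes to 423 km from the 1-dp
GHG total, printed 424). Neither is forced.

Two published cells disagree with the package's own arithmetic and are
documented rather than reconciled:

- **Absorbed iron**: applying the absorption model to the 1-dp printed
  iron values reproduces the published 2-dp absorbed-iron cells for
  silken tofu, pork, lamb, white fish, egg and lentils, but lands 0.01
  off for beef, chicken, salmon, mixed beans, chickpeas, baked beans,
  firm tofu and mixed nuts — the published cells were evidently computed
  from unrounded composition data. `audit_absorbed_iron` flags every
  disagreeing cell; the model's output is never overridden to match.
- **The iron delta** for beef → firm tofu: table arithmetic gives
  2.7 − 1.7 = +1.0 mg/serve while the prose headline says +1.1. The
  package reports the table arithmetic.

Similarly, the published modeled fiber mean (23.7 g) differs from
printed-original-plus-delta arithmetic (23.3 + 3.3/7 = 23.77 → 23.8),
again consistent with unrounded inputs upstream; the package computes,
it does not transcribe.

## Numerical and design choices

- All computation is unrounded end-to-end; rounding is a report-time
  concern only, and is always half-up.
- Quantiles: linear interpolation between order statistics.
- Degenerate inputs: empty cohorts, zero-energy/protein alternatives,
  non-PSD correlations, negative nutrients and zero thresholds raise
  typed validation errors naming the offending item.
- Constants (absorption fractions, vehicle factors, 270-day duration,
  NRV thresholds) live in dataclass defaults and the bundled NRV CSV;
  computation paths take them as parameters.
- Determinism: every stochastic path flows from a single integer seed
  through `numpy.random.default_rng`; identical configuration and seed
  give byte-identical pipeline reports.

## Limitations

- Nutrient–nutrient absorption interactions (enhancers/inhibitors) and
  supplement use are not modelled.
- Environmental intensities are global means; no uncertainty propagation
  over their distributions, and no country-specific values.
- Single-swap analysis only; no diet-level optimisation over swap sets.
- The synthetic cohort is a statistical stand-in, not a re-creation of
  any real population; compliance counts from it should be read as
  illustrative.
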
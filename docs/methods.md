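# Methods

## The model

`lignoferm` implements black-box stoichiometric accounting for anaerobic
mixed-acid fermentations of lignocellulose, the bookkeeping used to judge
consolidated-bioprocessing (CBP) cultures of cellulolytic thermophiles and
their saccharolytic, ethanologenic partners.

**Sugar equivalents.** A substrate is a vector of mass fractions of its
structural polysaccharides. Full hydrolysis of a loading *L* (g/l dry mass)
releases, for each polymer *p* with fraction *w_p*,

    equivalents_p = L · w_p / M_anhydro · 1000   [mM]

with M_anhydro = 162.14 g/mol for hexosans (glucan, galactan, mannan — one
water is consumed per glycosidic bond, so the monomer in the polymer weighs
a water less than free glucose) and 132.11 g/mol for pentosans (xylan,
arabinan). Galactan and mannan are treated identically to glucan and
arabinan identically to xylan; 162.14 is used uniformly even though some
published tables mix 162 and 162.14 at the second decimal, and agreement
with printed values is therefore expected at one-decimal precision.

**Theoretical capacity and utilization.** Glycolysis caps the organic
product pool (ethanol + acetate + lactate) at 2.0 mol per mol hexose; the
pentose route caps it at 1.67 mol per mol pentose. The pentose factor is
stored as the conventional rounded 1.67, not 5/3, so reported capacities
reproduce published tables digit for digit. Utilization is the measured
organic pool as a percent of capacity; CO₂, H₂ and cells are deliberately
excluded from the pool, matching how such sums are conventionally printed.

**Yield statistics.** Ethanol mol% is ethanol over the organic pool;
product ratios are normalized to ethanol = 1 (re-based on the largest
component, flagged, when no ethanol formed). Replicates are summarized by
computing each statistic per replicate and then aggregating as mean ±
sample standard deviation. Display rounding is half-up to one decimal and
applied only at report time; all arithmetic keeps full precision.

**Recovery balances.** Carbon recovery compares consumed-substrate carbon
(6 mM-C per mM hexose equivalent, 5 per pentose) with product carbon
(2 per ethanol and acetate, 3 per lactate, 1 per CO₂, plus cell carbon).
The electron balance weighs each species by its degree of reduction
relative to CO₂/H₂O/NH₃,

    γ = 4C + H − 2O − 3N,

giving 24 for glucose, 20 for xylose, 12 for ethanol and lactate, 8 for
acetate, 2 for H₂ and 0 for CO₂ and water (balances are therefore invariant
to water). Cell material uses the empirical per-carbon formula
CH₂N₀.₂₅O₀.₅ (25.53 g per C-mol; γ = 4.25 with NH₃ as nitrogen source —
γ_biomass is exposed as a parameter because measured cell compositions
vary). Acetate and lactate are treated as their free acids; ionization does
not change atom counts. Dry weight ↔ carbon conversion is provided in both
directions because either may be the measured quantity.

## Synthetic outcomes

The generator emulates end-point records and time courses of flask and
fermentor cultures so the whole pipeline can be validated without external
data. Catabolism is modelled at the C3 (pyruvate-equivalent) level: a
hexose yields 2 units and a pentose 5/3, so the 2.0/1.67 capacity factors
emerge from the mechanism. A strain is (φ_ethanol, φ_acetate, φ_lactate)
splitting the catabolized units, a biomass fraction *b* (share of consumed
carbon diverted to cells, 0–0.15), a consumption extent, and a scope
(cellulolytic strains hydrolyze polymers; saccharolytic strains need
soluble sugars). CO₂ follows from carbon conservation (one CO₂ per ethanol
or acetate) and H₂ is set so available electrons balance exactly; a split
whose products would carry more electrons than the substrate supplies (for
example a pure-ethanol split with biomass diversion) is rejected as
infeasible rather than silently clipped. Every noise-free record therefore
closes both balances at exactly 100%, which is the closure oracle the test
suite leans on.

Defaults describe the two partner physiologies under study conditions: the
cellulolytic strain splits (0.08, 0.65, 0.27) — little ethanol, lactate and
acetate dominating, as uncontrolled-flask cultures of cellulolytic
thermophiles show — and the saccharolytic partner (0.68, 0.06, 0.26),
strongly ethanologenic. Biomass diversion defaults to 5% of consumed
carbon, matching observed cell yields (≈0.25 g/l on 30 mM glucose), and
consumption extent to 0.9, the order of the utilization reached on washed
substrates at low loading. In co-cultures on polymeric substrates the
cellulolytic partner hydrolyzes at its own extent and released sugars are
shared 50:50 by default; the share is configurable because partitioning is
not a measured quantity.

Measurement noise is multiplicative truncated-Gaussian (factor
max(0, 1 + σ·Z)) per analyte, independent across analytes, with explicit
seeds — never global RNG state. Time courses follow a normalized logistic
progress curve; products accumulate proportionally to consumption, and the
endpoint is drawn first via the end-point generator so the final sample
equals it exactly even under noise (interior points use a separate
substream). Uncontrolled-flask cultures stall once total organic acids +
ethanol reach an acidification threshold (default 33 mM, placing flask
endpoints in the 20–40 mM range typical of unbuffered batch cultures while
pH-controlled fermentor runs, which have no cap, exceed 60 mM). The
stop-rule is a stand-in for medium acidification below pH 5, not an
inference about any organism's pH physiology.

What the generator does **not** emulate: Monod/hydrolysis kinetics, pH
chemistry and buffering, gas–liquid transfer, substrate inhibition,
inter-strain competition dynamics, or analytical biases of HPLC/GC.
Passing tests demonstrate the correctness of the stoichiometric accounting,
not that real cultures obey fixed product splits.

## Numerical choices and degenerate inputs

- Mass-fraction sums may exceed 1 by at most 0.02 (compositional analyses
  rarely close exactly).
- Zero consumed substrate makes recoveries undefined and raises, whether or
  not products were measured; zero capacity likewise for utilization, and
  an empty product pool for mole fractions and ratios.
- "No growth" of a strain whose scope excludes the substrate is represented
  as a zero-consumption, zero-product record, not an error.
- Integer-formula compounds must agree with their molar mass within
  0.5 g/mol at construction; the biomass pseudo-formula is exempt.
- Tolerances in tests: closure and oracle-equivalence checks at 1e-9;
  printed table values at the half-unit of their printed precision;
  published recoveries that derive from unrounded replicate means at
  ±3 percentage points (documented near-misses, not assertion targets).

## Problem sizes

The closure property is exercised on 1,000 randomized zero-noise records
across four substrates and one- or two-strain cultures; parameter recovery
uses 200 replicates at 5% relative noise. Both choices keep the suite
comfortably within seconds while being large enough for the law-of-large-
numbers bounds they assert (±0.02 on recovered splits).

## Known limitations

- The utilization statistic inherits the 1.67 rounding; against a 5/3
  generator it would read 100.2% at complete pentose fermentation.
- Published tables aggregated from unrounded replicates cannot be
  reproduced exactly from their own printed means; such values are
  tolerance-checked, never forced.
- Weight-loss → equivalents conversion attributes all loss to cellulose,
  valid only for washed substrates free of residual soluble hemicellulose.
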
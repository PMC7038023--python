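# Methods

## Scope and model structure

`waterhealth` scores water/wastewater system designs on a single
health-burden scale (DALY/year) for one functional unit: a community's
annual water and wastewater service demand.  The default example scenario
set models a Cape Cod town of 31,101 residents (≈12,959 households at 2.4
persons each) consuming 4.6 million US gallons/day of delivered water
(US gallon fixed at 3.78541 L), with wastewater volume equal to delivered
water and distribution losses uniform between 8% and 15%.  Three designs
are configured: a centralized system (BAU: water treatment, distribution,
sewered collection, activated-sludge plant), and two decentralized
resource-recovery systems that keep the centralized water supply but
replace the sewer and plant with on-site septic treatment plus composting
toilets (CT-SS) or urine-diverting toilets (UD-SS), each earning
fertilizer credits for recovered nutrients.

Two burden components are computed and summed exactly:

1. **Life-cycle chemical impacts.**  Stage intensities (distributions)
   scale to annual carrier amounts by the stage's throughput basis; an
   emission-factor table expands carriers into chemical releases per
   compartment; characterization factors (cases/kg) convert releases to
   expected cancer and noncancer cases; severity factors (11.5 and 2.7
   DALY/case) convert cases to DALY.  Credits enter as negative stage
   rows so contribution reports can show them as offsets against the
   gross positive impact (positive-stage fractions sum to 1, credits are
   negative fractions of the same denominator).
2. **Microbial risks.**  Per-event doses for recreational ingestion (all
   systems) and potable-water cross-connection (centralized only), the
   per-pathogen dose-response model, illness given infection, annual
   aggregation by complement products, and population scaling by the
   exposed fraction (25% swimmers, one recreational event per person-year;
   10% of the population behind a cross-connection event of 1 day by
   default).

## Distributions and sampling

Five families cover every uncertain input: triangular(min, peak, max),
normal(mean, sd), uniform(low, high), log-uniform (uniform in log10 of
the value) and point.  Quantiles and CDFs are exact closed forms of the
stated, untruncated distribution — in particular normal quantiles use the
full-precision standard-normal inverse, and normal inputs are *not*
truncated at zero by default, because the analytic 5th percentiles are
what published parameter tables report.  A `nonnegative` flag enables
rejection resampling for physical plausibility where wanted; it changes
sampling only, never the analytic quantiles.

Sampling is inverse-transform from `numpy` Generators.  One top-level
seed spawns a substream per parameter, keyed by a stable hash of the
parameter's name mixed with the seed — adding or removing a parameter
never perturbs any other parameter's draws, which keeps scenario variants
comparable under a common seed.  An Anderson–Darling A² statistic against
the analytic CDF is provided as a goodness-of-fit diagnostic on samples.

Parameters are sampled independently; no correlation structure is
modelled (a deliberate simplification — correlated energy prices or
co-varying pathogen loads would widen the output distributions).

## Dose-response models

* Approximate beta-Poisson: `1 − (1 + D/β)^(−α)`; the second parameter is
  interpreted as β (not N50), which for the Campylobacter pair
  (α = 0.145, β = 7.59) gives ID50 ≈ 897, consistent with the order of the
  conventionally quoted ~800 cfu.
* Exponential: `1 − e^(−rD)`; for Cryptosporidium (r = 0.09) the analytic
  ID50 is ln 2 / r ≈ 7.70, printed as 8 oocysts.
* Exact beta-Poisson ("hypergeometric"), used for norovirus
  (α = 0.04, β = 0.055): `1 − ₁F₁(α, α+β, −D)` — the expected infection
  probability for Poisson-distributed organisms with beta-distributed
  single-organism survival.  The confluent hypergeometric function is
  evaluated through the Kummer transformation
  `₁F₁(a, b, −d) = e^(−d) ₁F₁(b−a, b, d)`, whose series has all-positive
  terms, accumulated in log space with a stop rule once past the term
  mode; this is stable from d = 0 up to d ≈ 1e4 and is verified against an
  arbitrary-precision oracle to 1e-8 in the test suite.

All curves are 0 at dose 0, monotone non-decreasing and bounded by 1.
Annual risk uses `1 − Π(1 − p_i)` computed via `log1p` for accuracy at
small probabilities; cross-connection conditions (concentration,
chlorine) are held constant across the days of an event.

## Monte Carlo and sensitivity

Monte Carlo (default 10,000 iterations) evaluates the whole integrated
model — life-cycle and microbial halves jointly — vectorized over draws,
and reports 5th/50th/95th percentiles per output; non-finite iterations
are excluded with a reported count.  Percentiles of totals are always
taken on the joint draws of the total, never by summing component
percentiles (quantiles are not additive).

The deterministic reference case is the median of every distribution.
Monte Carlo and the deterministic run share a single evaluation path in
which stage sums accumulate in fixed configuration order, so collapsing
every distribution to a point makes the Monte Carlo percentiles equal the
deterministic result bit for bit.  The explicit
inventory → characterization → credits chain is kept as an independent
in-package route for stage-resolved reports and is cross-checked against
the fast path to 1e-12 relative error in the tests.

Sensitivity is one-at-a-time: each parameter moves to its 5th and 95th
percentile with all others at medians; bars are ranked by output swing.
On an additive linear model this reproduces coefficient × (q95 − q5)
exactly, which the tests assert to 1e-12.

## Synthetic background data — what is and is not a stand-in

The nine stage-intensity distributions of the example systems (coagulant
and energy per m³ for water treatment, distribution, wastewater
collection and treatment, septic energy, compost/urine transport per
household-year), the severity factors (11.5, 2.7 DALY/case), the
dose-response parameters, P(ill | infection) and DALY-per-case values of
the four pathogens (with norovirus route-specific: 1.6e-3 recreational,
9.5e-4 cross-connection), the exposure fractions (25% swimmers, 10%
cross-connected), the cross-connection dilution of 0.001, and the septic
leakage dilution family (uniform 1/100–1/10) are published modelling
inputs carried over as defaults.

Everything else is a synthetic stand-in chosen once for plausibility and
marked as such in exported files:

* **Emission factors and characterization factors.**  Generated per
  carrier with disjoint chemical sets; characterization factors drawn
  log-uniformly (cancer 1e-9–1e-5, noncancer 1e-8–1e-4 cases/kg), then
  emission factors rescaled so each carrier's implied intensity equals a
  fixed target exactly (electricity 1.5e-11 cancer cases/MJ, diesel
  5e-12, coagulant 3e-10 cases/kg, fertilizers 2–3e-10 cases/kg;
  noncancer = 30× cancer cases throughout).  These magnitudes put the
  example systems' burdens in the 0.01–0.1 DALY/yr range typical of
  town-scale assessments.  A coal-like/solar-like electricity pair with
  an exact 100× intensity ratio is included to represent the real spread
  between dirty and clean generation.
* **Pathogen water quality.**  Raw-sewage log10 concentrations (normal;
  e.g. norovirus 5.5 ± 0.5 log10 gc/L, Cryptosporidium 0.8 ± 0.4),
  centralized-treatment log removals (normal, ~5 logs for bacteria and
  viruses, 2.5 for chlorine-resistant protozoa), soil-passage removals
  for the septic designs (triangular 3–5 logs; norovirus log-uniform
  0.5–4 orders wide in log-removal, reflecting strong dependence on soil
  and travel distance), ingestion volumes (recreational 32 ± 12 mL,
  nonnegative; potable triangular 0.5/1.0/2.5 L/day), chlorine residual
  (1 mg/L, 30 min contact) and Chick–Watson constants (bacteria
  susceptible, viruses intermediate, protozoa resistant).  The
  composting-toilet design's septic norovirus density is far below raw
  sewage (feces diverted); its "uniform density" characterization is
  encoded as a uniform distribution on the log10 concentration — the
  quantity the dose equation consumes — a simplification of a uniform on
  the linear scale.
* **Nutrient credits.**  4 kg N + 0.6 kg P per household-year for
  compost, 9 kg N + 0.9 kg P for urine diversion, displacing synthetic
  fertilizer at the generator's fertilizer intensities.
* **Construction.**  A small fixed amortized diesel entry (2e5 MJ/yr
  centralized, 1e5 decentralized) so the operational phase dominates, as
  it does in practice; full construction modelling (trenching, pipe
  manufacture) is out of scope.
* The composting-toilet fan load is modelled as a continuous 5 W draw
  (≈158 MJ/household-year); septic maintenance as 73 MJ/household-year
  (tank cleaning plus residual transport).

Consequently, passing tests demonstrate the *mechanics* — scaling,
characterization, credit accounting, dose-response mathematics,
propagation and ranking — under realistic magnitudes, not agreement with
any licensed database; absolute burdens of real systems require real
background inventories.

## Numerical choices and edge cases

* Triangular quantiles use the piecewise closed form around the mode
  break F(c) = (c−a)/(b−a); degenerate peaks at either endpoint are
  supported; zero-width triangulars are rejected.
* Missing characterization or emission-factor rows raise errors naming
  the offending keys — never a silent zero.
* Stage-contribution fractions are undefined (error) at zero gross
  impact.
* System comparisons refuse to rank results computed under different
  functional units; exact ties rank stably by system name.
* Tornado bars for point-valued parameters are zero-width by definition
  and skip model evaluation.

## Problem sizes

Default study conditions are 10,000 Monte Carlo iterations per system
(seconds per run, vectorized); the test suite uses 1e5 iterations for
quantile-convergence checks and 25 log-spaced doses over 1e-2–1e4 for the
hypergeometric-oracle comparison.

## Known limitations

Independent inputs only (no rank correlation or Latin hypercube); no
process-network (Leontief) inventory inversion — emission factors are
fully aggregated per carrier; no pathogen fate/transport beyond the
log-removal abstraction, no secondary person-to-person transmission, and
no helminth-egg pathway; end-of-life impacts excluded; single-year,
steady-state accounting.
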
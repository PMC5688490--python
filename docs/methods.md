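# Methods

## Costing model

For intervention *i*, year *t* and need row *(p, t)* linking it to a target
population:

- services(i,t) = Σₚ pop(p,t) · need(i,p) · coverage(i,p,t)
- cost(i,t) = services(i,t) · unit_cost(i), component-wise
- total(t) = Σᵢ cost(i,t) + program_costs(t)

`need` is a proportion of the target population and may exceed 1 where a
person can require the service more than once per year (diarrhoea, malaria);
`coverage` is *effective* coverage — the share of those in need actually
served — and is bounded by 1. Service counts are kept as reals; rounding is
purely presentational.

The unit cost per case is a channel-mix-weighted sum over delivery channels
of three blocks:

1. **Drugs & supplies** (ingredients): Σ unit_price · units_per_case ·
   pct_receiving. `pct_receiving` is capped at 1; repeat dispensing is
   expressed through `units_per_case`.
2. **Labor**: Σ minutes_per_visit · n_visits · wage_per_minute, with
   wage_per_minute = annual_remuneration / (working_days · minutes_per_day ·
   utilization). Utilization sits in the denominator: a provider who is
   productive half the time costs twice as much per *delivered* minute. This
   is the convention under which paying for idle capacity is attributed to
   the services actually delivered.
3. **Facility overheads from hotel costs**: outpatient visits and inpatient
   bed-days per case are priced at the country cost per visit/bed-day
   ("hotel" cost: everything except drugs and laboratory costs) and
   multiplied by the other-direct and indirect factor shares — health-centre
   shares for outpatient visits, hospital shares for inpatient days, in all
   cases (no per-intervention override). The personnel and consumables
   shares of the hotel cost are *never* applied: those inputs are already
   costed as ingredients, and adding them would double count. This is
   enforced by a test: perturbing the two inert shares cannot change any
   output.

Above-facility program costs are specified per category (program management,
research, monitoring & evaluation, communication/media/outreach,
above-facility training, infrastructure & equipment) as either a fixed
annual amount or a markup fraction applied to the *total* facility-level
cost including drugs (the markup base is deliberately not net of any
component). In exports, other-direct costs are labelled "other recurrent"
and indirect costs "capital"; the mapping is recorded in the results-file
header.

Conventions: constant USD throughout, no discounting or inflation; annual
time steps with explicit per-year inputs (an optional helper interpolates
interior years linearly from endpoints, but nothing is interpolated
silently); channel mix fractions are constant per intervention over the
projection; all fractions are stored as [0, 1] proportions with a `percent`
reader dialect; negative inputs are rejected, never clamped.

## Factor-share estimation

The overhead proportions come from a four-factor translog cost function
(personnel, consumables excluding drugs and laboratory costs, other-direct,
indirect) fitted to facility-level cost data, one equation per facility
level. In the implemented normalization (dividing cost and prices by the
indirect-cost price, which imposes linear homogeneity; symmetry is imposed
by construction):

ln(C/p₄) = β₀ + Σᵢ₌₁³ βᵢ ln p̃ᵢ + ½ Σᵢⱼ γᵢⱼ ln p̃ᵢ ln p̃ⱼ + δ_y ln y + ε

Estimation is ordinary least squares on the 11-regressor design (intercept,
3 first-order terms, 3 squared terms entering as ½·z², 3 cross-products,
ln y). Differentiating with respect to log prices (Shephard's lemma) gives
the shares sᵢ = βᵢ + Σⱼ γᵢⱼ ln p̃ⱼ, evaluated at the sample mean of log
normalized prices (the standard evaluation point); s₄ is the complement, so
the four shares sum to one identically. Coefficient covariance is the
Huber/White sandwich with HC1 scaling n/(n−k), matching the common default
of that estimator; share standard errors follow by the delta method (shares
are linear in coefficients, so the delta method is exact given the
covariance). The implementation is plain numpy linear algebra and is
cross-checked in the tests against statsmodels' OLS/HC1 and against
hand-summed oracles.

Design choices that were genuinely open:

- A single ln y output term is included (δ_y); price–output interaction
  terms (non-homothetic technology) are available behind
  `price_output_interaction=True` but off by default.
- Besides the cost-function regression, a stacked share-system estimator
  (observed expenditure shares regressed on log normalized prices with
  cross-equation symmetry imposed, numeraire equation dropped) is provided
  as a sensitivity alternative; it requires observed share columns and is
  never the default.
- Country or facility fixed effects are not modelled.
- The packaged default share table is shipped verbatim as published. The
  health-centre row sums to 96.9% as printed; it is not silently
  renormalized (a `renormalize` option rescales rows to 100% on request).
  Preserving the printed values was preferred over guessing whether the
  shortfall is rounding or specification.

## Synthetic data generators

`simulate_facility_costs` draws from a known translog process: four i.i.d.
log-uniform[−0.5, 0.5] log prices (so prices are centred at 1, the design is
well conditioned, and the expected log normalized prices are zero — making
the mean factor shares equal the first-order coefficients), lognormal output
(log-mean ln 5000, log-sd 0.5), δ_y = 1 (constant returns; shares do not
depend on it), and N(0, noise_sd²) noise on log cost, i.e. multiplicative
lognormal noise — cost data are positive and right-skewed. The default
second-order terms are small but nonzero (±0.01/0.02, symmetric) so that
the cost-function and share-system estimators are distinguishable; passing a
zero matrix gives a Cobb-Douglas process. Observed expenditure shares
(Shephard shares plus N(0, 0.01) noise) are included for the share-system
estimator. Default noise_sd is 0.05 (5% multiplicative cost noise). The
generator's health-centre truth is the published row renormalized to sum to
1, since a data-generating process requires exact adding-up.

`build_country_scenario` generates a toy country: 10 interventions over
2025–2030 by default, four population groups (50k–2M people, 1% annual
growth), need fractions U(0.05, 1.5) (values above 1 exercise the
multiple-cases-per-year rule), linearly rising coverage trajectories
(starting U(0.1, 0.5), ending up to 0.95), one or two delivery channels per
intervention, 1–4 drug lines per channel with prices U(0.05, 20) USD,
provider time of 5–60 minutes over 1–4 visits across up to three cadres
(remuneration U(3k, 30k) USD/yr, 230 days × 480 min, utilization
U(0.4, 0.9)), hotel costs U(1, 5)/U(5, 25) USD per visit/bed-day, the
packaged default shares, and a nonzero program-cost specification mixing
markups (10% management, 3% M&E, 2% communication) and fixed amounts. These
magnitudes are plausible for a low-/middle-income MNCH program but the
generator makes no claim of epidemiological realism: what passing tests
demonstrate is the *arithmetic and statistical* correctness of the engine
and estimator on data with the right structure, not the realism of any
particular country projection. Real applications must supply their own
tables.

Both generators are deterministic: one seed, byte-identical files.

## Validation strategy and problem sizes

- Engine correctness: on 50 random small scenarios (≤ 5 interventions) every
  component equals an independently written per-line brute-force enumeration
  to 1e-9 relative; conservation (total = Σ components) holds for every
  output row; doubling all prices/wages/hotel costs doubles every
  facility-level component *exactly* in floating point (all operations are
  linear in prices, and doubling is an exponent shift).
- Estimator correctness: noise-free data are fitted exactly (adjusted
  R² = 1 to 1e-9, coefficients to 1e-8); with 5% noise, n = 1000 recovers
  each share within 0.02; a 200-replicate Monte-Carlo at n = 500 shows mean
  absolute share bias below 0.01 and ≥ 90% coverage of nominal-95%
  delta-method intervals. These sizes keep the whole suite under a few
  seconds while leaving the statistical checks comfortably powered.
- Invariance tests: price-scale invariance of shares, factor-relabelling
  equivariance, inertness of the personnel/consumables shares in costing,
  antisymmetry of scenario comparison, league-table permutation safety.

## Known limitations

- The packaged share proportions were estimated on circumcision-service
  facility data; applying them to MNCH visit/bed-day costs assumes
  comparable labor utilization across service types. They are defaults, not
  country truths — applications should re-estimate when facility cost data
  are available.
- No bottleneck/constraint modelling, supply-chain markups, activity-based
  program costing or health-system strengthening costs; mortality impact is
  an external input, never computed here.
- No discounting of costs or effects; constant prices.
- The league table requires per-intervention lives-saved rows; scenario-level
  impact totals support only aggregate cost-per-life-saved ratios.
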
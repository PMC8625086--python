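# Methods

## Problem and approach

No single public survey carries all the demographic, residential, and
physiological information needed to model an individual's chemical exposure
at home. `rpgen` therefore fuses three survey sources — a person-level
census microdata sample (with age, gender, race, ethnicity, state, PUMA,
household composition, income, and a sampling weight), a housing survey
(rooms, floor area, structure type, tenure, airflow-relevant features), and
an energy/appliance survey (washer, cooktops, fuel) — into a synthetic
population of individuals-in-residences. Every output row is one
individual whose person, housing, energy, and physiology attributes are
mutually consistent: values that could plausibly have come from one real
person in one real home.

Records are linked through the **pool** variable, a 5-tuple shared by all
three sources:

| dimension | values | derivation |
|---|---|---|
| setting | urban=1, rural=2 | metropolitan statistical areas are urban, all else rural; for person records, PUMA population density > 130 people/km² (strictly greater) is urban |
| region | Northeast=1, Midwest=2, South=3, West=4 | census region, from the state FIPS code for persons |
| house type | standalone=1, multi-structure=2, other=3 | houses/attached houses; apartments/condominiums; mobile homes/boats. Group-quarters codes (military bases, prisons, shelters) are excluded; vacant units are excluded |
| family category | 1–4 | (1 adult, 0 children), (2+, 0), (1, 1+), (2+, 1+); adult = age ≥ 18; households with no adult are filtered out |
| income category | 1=high, 2=middle, 3=low | terciles of household income **within each of the 8 (setting, region) locations**, so the category reflects local purchasing power |

The ordered tuple is packed into an integer in [1, 288]
(2·4·3·4·3 bins), with setting varying slowest and income fastest:

    index = ((((s-1)·4 + (r-1))·3 + (h-1))·4 + (f-1))·3 + c

The source material fixes only the count (288), not the ordering; this
bijection is our choice, documented and stable across versions, with
`decode_pool` as its exact inverse.

### Tercile details

Terciles are unweighted and computed after the exclusion filters, so
discarded rows cannot shift boundaries. For a location with n households,
bin sizes differ by at most one; when n mod 3 ≠ 0 the extra members go to
the lower categories (3 first, then 2). Ties are broken by stable input
order, preserving exact size balance. For the person table the ranking is
over distinct households, and each member inherits its household's
category.

## Population assembly

Sampling uses the two-step cumulative-weight interval method. Weights are
cumulated and divided by their total, yielding a vector on (0, 1] whose
interval widths are proportional to the weights; uniform draws are placed
by binary search (a draw exactly on a boundary takes the lower-indexed
record — a measure-zero event fixed for bit-reproducibility). Sampling is
with replacement. Persons are sampled first; then, for each person, one
housing and one energy record are drawn by the same method among the
records sharing the person's pool, using each survey's own weights.

**Empty pools.** Small household surveys do not populate all 288 pools
(rural high-income apartments are the classic gap). Rather than fail
silently or redraw, the key is relaxed stepwise — income category first,
then house type, then setting; region and family category are never
relaxed — and the level used is reported per row in `fallback_level`
(0 = exact pool match) plus per-source columns. If a pool is empty even at
full relaxation, assembly aborts with a report of the unmatched pools.
Income and structure type were chosen as the first casualties because they
are the least exposure-critical of the five keys; geography and household
composition drive the downstream product-use and inter-individual exposure
logic.

**Randomness.** One master seed feeds a `numpy` `SeedSequence` (PCG64);
named sub-streams are spawned for person sampling, housing match, energy
match, and physiology, so runs are bit-reproducible and insensitive to
module-order changes. Identical config + seed ⇒ byte-identical output CSV.

## Physiology

The physiology layer is a deliberately simple parametric model — not a
reimplementation of survey-regression machinery — whose contract is
internal consistency, demographic conditioning, and the hard caps:

* **height**: piecewise-linear growth knots by age and gender (birth ≈ 50
  cm up to adult means of 176/163 cm for males/females, with a small
  old-age decline), multiplied by a lognormal factor with CV 4.5%;
* **weight**: lognormal BMI around age/gender mean knots (σ = 0.16), times
  (height/100)²;
* **body surface area**: Du Bois, `0.007184·H^0.725·W^0.425` (m²);
* **cardiac output**: allometric `a·W^0.75` L/h with a = 12.0 (M) / 11.9
  (F), putting the adult male mean near 5.6 L/min;
* **breathing rate**: proportional to cardiac output (0.048/0.044
  m³·day⁻¹ per L·h⁻¹), giving ≈ 16 m³/day for adult males;
* **blood volume**: Nadler's height/weight formula for adults; a per-kg
  coefficient (decreasing from 0.085 L/kg at birth) for under-18s, because
  Nadler badly overestimates infant blood volume;
* **compartment volumes** (density ≈ 1 kg/L): adipose from a BMI-dependent
  fat fraction (clipped to [0.05, 0.50]); liver, kidney, lung, and muscle
  as fixed fractions of lean mass; brain capped at an adult maximum;
  rest-of-body as the remainder after blood, floored at 1% of body weight
  as a degenerate-extreme guard. Compartment volumes always sum to less
  than total body volume;
* **hematocrit**: deterministic age/gender knots (neonatal high, infant
  dip, adult 0.45/0.40).

All parameters live in `src/rpgen/data/physiology_constants.csv`
(long-format: parameter, gender, age knot, value), so a different
calibration — e.g. a regression backend fitted to health-survey data — can
replace the defaults without code changes. Ethnicity enters only as an
optional multiplicative mean-height shift, zero by default, because no
defensible default effect sizes are built in.

**Pre-jitter determinism and jitter.** Pre-jitter draws come from a
sub-stream keyed on (age, gender, ethnicity), so individuals sharing a
demographic profile receive identical pre-jitter physiology; per-individual
variation is then added by multiplicative lognormal jitter (σ = 0.05,
configurable) on height and weight. Post-jitter height is capped at
225 cm and weight at 160 kg, and **all derived quantities are recomputed
from the jittered pair**, so internal consistency survives jitter exactly:
recomputing BSA, CO, breathing rate, blood volume, and compartments from
any row's stored height/weight reproduces the stored values bit-exactly.
The jitter magnitude is a documented stand-in; nothing in the output
depends on it structurally, only dispersion.

## Synthetic surveys

The generator module emulates the three sources so that the whole pipeline
is testable offline. What it reproduces: the three schemas and categorical
vocabularies (through raw-coded CSVs plus schema maps, exercising the full
recode path); positive lognormal sampling weights; lognormal household
income per location with urban medians above rural (so the
purchasing-power stratification is observable); a Gaussian copula tying
rooms, floor area, and income with configurable Spearman correlation
(default target ρ = 0.5); income-dependent appliance ownership;
PUMA densities spanning both sides of the 130/km² cutoff; and optional
fault injection (zero-adult households, vacant units, group-quarters
codes) to exercise every exclusion filter.

With `ensure_full_pool_coverage`, households are laid out per location in
balanced (house type × family × income-third) cells with incomes drawn
inside disjoint tercile quantile bands, so the downstream tercile split
coincides with the intended thirds and all 288 pools are provably
populated; counts are padded to multiples of 36 per location, so delivered
sizes can exceed the requested n. `leave_pools_empty` removes rows whose
pool matches a target, re-harmonizing to a fixpoint because removals shift
tercile boundaries.

What the generator does **not** emulate: the US marginal distributions of
any variable, real geographic density surfaces, or real survey record
counts. Passing tests therefore demonstrate the correctness of the
machinery (filters, linkage, sampling, physiology, reproducibility), not
the demographic realism of any particular output population — with real
survey drop-ins, realism is inherited from the inputs.

## Run configuration

Runs are configured by a flat `key = value` text file (keys
case-insensitive, `.`/`_` interchangeable), YAML, or keyword arguments.
`run_name` and `num_persons` are required; everything else defaults
inclusively: ages 0–99, both genders, all race/ethnicity codes, all four
regions, all contiguous-US states (48 + DC, shipped as a packaged lookup)
within the selected regions. Region codes on input follow the run-file
convention 1=West, 2=Midwest, 3=South, 4=Northeast. Persons outside the
contiguous US are discarded because the household surveys do not cover
them.

## Problem sizes and numerical choices

Default test and demonstration sizes — survey tables of a few thousand
rows and output populations of 1,000–10,000 — were chosen as the scale at
which every statistical check (binomial frequency bands, chi-square
uniformity and representativeness at α = 0.001, Spearman correlation
bands) has comfortable power while the full suite stays fast. The
cumulative vector's last element is pinned to exactly 1.0 after
normalization to guard against rounding drift; empty survey reads, empty
filtered tables, and >50% row rejection are hard errors naming the cause.

## Known limitations

* The physiology model is parametric and calibrated to textbook norms, not
  fitted to health-survey microdata; swap the constants table for
  calibrated work.
* Income terciles are unweighted; a weighted variant would change bin
  boundaries for strongly weight-skewed surveys.
* Household members other than the sampled individual are not emitted as
  separate rows; within-household exposure modeling needs the household
  composition columns instead.
* No temporal adjustment: a generated population is a cross-section and
  does not age.
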
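# Model and methods

This note documents the science inside `cowcalf`: the simulated production
system, each sub-model with its parameters and defaults, the calibration
procedure, numerical conventions, and known limitations. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Production system

One herd is a spring-calving drylot operation of `herd_size` (default 100)
breeding females of a single genotype cell, simulated on integer days over a
fixed 365-day calendar (no leap days) for up to 24 years. The annual cycle:

- **Breeding** June 15 (day-of-year 166) for 90 days; cows and heifers share
  the season.
- **Pregnancy diagnosis** 60 days after the season ends (~Nov 12); open
  females and females older than 13 years are culled then (the herd-wide
  weaning date has already passed by then under the default calendar).
- **Calving** from late March (283-day gestation).
- **Weaning** herd-wide on the day the oldest live calf turns 220 days
  (~late October); calves are sold, enough heifer calves are retained
  (oldest first) to refill the herd, and any remaining gap at the next
  season start is filled by purchased heifers drawn from the same genotype
  cell ("matching the herd's traits").
- A female whose calf dies before the season start is removed immediately; a
  female aborting after diagnosis is removed on that day.

Females progress nursing calf → replacement heifer → bred heifer →
two-year-old → three-year-old → four-year-old → mature. Herd output
statistics are restricted to cows three years and older.

## Genotypes

A genotype cell is (mean mature shrunk body weight, mean peak milk yield):
MSBW ∈ {450, 550, 650} kg, peak milk ∈ {8, 10, 12} kg/d. Individuals draw
MSBW ~ N(mean, 25.4 kg) and peak milk ~ N(mean, 1.45 kg/d), truncated at
±3 SD to exclude non-physical values. Expected calf birth weight is linear
in the cell's mean MSBW (sire size assumed equal to the dam-cell mean):
31.475 + 0.0045·MSBW kg, giving 33.5/34.0/34.4 kg for the three sizes, with
individual variation of SD 2 kg. Retained heifer calves receive fresh,
independent genotype draws from the cell, which keeps the population moments
anchored at the cell means under arbitrary culling histories.

The founding herd spans ages 2–13 with geometric (0.85/yr) survival weights,
all pregnant from an emulated previous season; the first 3 simulated years
are discarded as burn-in (configurable).

## Cow energetics

All energy flows are on a net-energy-for-maintenance (NEm) equivalent basis.

- **Intake.** 3+-yr-old cows receive a fixed lifetime prescription:
  level/1000 × (a·MSBW)^0.75 kg DM/d with a = 0.96 for three-year-olds, 0.98
  for four-year-olds, 1.0 mature, plus 18 g/kg^0.75 while nursing. Levels:
  58, 76, 93, 111 g/kg^0.75. From 14 days before the calving season until 10
  days after her own calving a cow instead receives 7 kg DM/d of corn silage.
  Two-year-olds eat according to the standard beef-cow intake prediction
  (SBW^0.75·(0.04997·NEm² + 0.04631)/NEm + 0.2·milk); heifers are fed exactly
  what their growth targets require (below).
- **Diet energy.** The experimental ration has 2.25 Mcal ME/kg DM; NEm and
  NEg concentrations follow the Garrett polynomials (1.3835 and 0.803
  Mcal/kg at this ME). Silage defaults to the same ME.
- **Requirements.** Maintenance 0.077·SBW^0.75 Mcal/d on *current* shrunk
  weight, reduced 12 % for genotypes with peak milk below 7 kg/d. Lactation
  adds milk yield × 0.75 Mcal/kg (maintenance-equivalent milk energy).
  Gestation adds an exponential conceptus energy deposition
  CBW·(0.05855 − 0.0000996·t)·e^(0.03233·t − 0.0000275·t²)/1000 Mcal/d,
  expanded by the 13 % efficiency of ME use for conceptus growth and
  converted to the NEm scale by the diet's km = NEm/ME.
- **Tissue dynamics.** The daily balance (supply − requirement) changes
  weight by ΔSBW = balance / e(EBF), where e(EBF) = 0.55 + 0.165·EBF% (floor
  1.4) Mcal per kg — the energy content of gain/loss, rising with fatness.
  The fat fraction of exchanged tissue follows from its energy density
  (f = (e − 1.1)/8.3, i.e. fat at 9.4 and fat-free tissue at 1.1 Mcal/kg),
  which updates the fat pool and hence EBF; gain and loss use the same
  function (no mobilization asymmetry). BCS = EBF%/3.7678, clamped to [1, 9];
  herd condition is reported as the median.
- **Self-stabilization.** Because intake is fixed on mature size while
  maintenance follows current weight, weight converges to
  (supply/0.077)^(4/3): restricted cows shrink until maintenance fits their
  allowance rather than starving indefinitely; generously fed cows grow
  heavy and fat. This is the mechanism that keeps condition at the lowest
  level near BCS 4–5 and pushes it to 8+ at the highest level.

The e(EBF) anchors are calibration constants. Values near the literature's
gain-energy range (4.5–7 Mcal/kg) cause fat-dominated mobilization that
drives restricted cows to BCS 1–2; the shallower line used here yields the
intended BCS ≥ 4 floor at the 58 level together with the BCS ceiling at 111.
Annual gain/loss cycles are fat-neutral under a symmetric e(EBF), so
long-run condition is set by the transient from the initial state — a
deliberate, documented consequence of the symmetric design.

## Lactation and the calf

Milk yield follows a normalized Wood curve y(t) = peak·(t/60)^0.35·
e^(0.35(1 − t/60)) — maximum exactly at the individual's genetic peak on day
60, evaluated at day 1 for day 0. Yield is *independent of the cow's energy
intake*: cows pay for genetic milk potential out of body reserves. The calf
consumes all milk (single calf, no refusals).

Creep feed (same ration) begins at 75 days of age:
0.2 × max(0, 0.1857·BW^0.75 − 0.3562·milk) kg DM/d — about 3 kg/week at
onset, rising with calf weight and falling with milk supply so calves of
low-milk dams partially compensate.

Calf gain is a reduced-form net-energy equation:

    ADG = (k_milk·milk + 0.803·creep − 0.01·BW^0.75) / e_calf,
    e_calf = 1.5 · (MSBW/550)^(−0.251)  Mcal/kg gain

with k_milk = 0.126. k_milk and the small maintenance coefficient are
*effective regression-style coefficients*, not literal milk energy contents:
they were fitted (together with the creep coefficients and the size
exponent) by least squares so that 187-day trajectories reproduce the
drylot progeny grid — pre-weaning ADG rising 0.64 → 0.98 kg/d and lifetime
mean creep 0.43 → 0.54 kg/d from the smallest/lowest-milk to the
largest/highest-milk genotype. A literal NE system (milk at ~0.95 Mcal
NE/kg against calf maintenance at 0.077–0.086) predicts roughly twice the
observed response of gain to a 4 kg/d difference in dam peak milk; the
fitted coefficients encode that shallower empirical response. Larger-framed
calves deposit leaner, cheaper gain (the negative size exponent).

## Reproduction

At each calving the cow draws a postpartum anestrus interval from a
triangular distribution banded on her BCS at calving:

| band | (min, mode, max) d |
|------|--------------------|
| BCS ≥ 6 | (40, 50, 68) |
| BCS 5–6 | (42, 56, 88) |
| BCS 4–5 | (55, 75, 120) |
| BCS < 4 | (170, 205, 260) |

Only the top-band minimum mode (50 d) is fixed by the model description; the
rest are calibration constants (below). The bottom band effectively misses
the following breeding season — a cow calving below BCS 4 stays anestrous
through it and is culled open.

After the interval elapses the cow cycles every 21 days; each in-season
estrus of an open, exposed female is a Bernoulli conception trial with
constant probability 0.58 per cycle, independent of condition — a stated
model assumption, as is the condition-independent pregnancy loss (0.03 per
pregnancy, timed uniformly between diagnosis and term, cow removed at
abortion) and pre-weaning calf mortality (0.046, death age uniform in
1–60 d). Heifers cycle from the season start at a uniformly random phase.

Per-age-group minimum culling thresholds exist in the configuration but
default to 0 (disabled); no background cow mortality is applied.

## Output accounting

For breeding-season year *y*:

- **Forward percentages** (pregnancy, calving, weaning per cow exposed):
  denominator = 3+-yr-old females present at the season-*y* start;
  numerators = diagnosed pregnancies that fall, calvings the following
  spring, and calves weaned the following fall from those conceptions.
- **Contemporaneous progeny metrics** (birth weight, creep DMI, weaning age,
  ADG, weaning weight, weaned weight per cow exposed, annual DMI,
  efficiency): computed over exposed 3+ dams *with a calf at side* in year
  *y* and their calves weaned that fall. Because dams whose calves die
  before the season are removed before exposure, weaned weight per cow
  exposed runs ~1–2 % below mean weaning weight. Annual DMI is accumulated
  per dam over the 365 days from exposure; efficiency = 1000 × total weaned
  weight / total DMI of those dams.
- Scenario means average production years after burn-in (default 3) and
  seeded replicates (default 5) with equal weight. The paper-style design
  runs one herd per scenario; replicates are an artifact choice to tighten
  stochastic summaries.

Per-cow production years (calving-to-calving, or to culling) are also
tracked and reported as `pydmi_per_cow`.

## Response-surface analysis

Each response is fitted per genotype against realized annual DMI per cow by
ordinary least squares on a polynomial basis (degree 2 by default), solved
via a column-scaled least-squares solve. The interaction assessment reports
the spread (range and CV) of linear and quadratic coefficients across the
nine genotypes and flags interaction-like behaviour when any two fitted
curves cross within the overlap of their observed intake ranges or the
coefficient of variation of the curve slopes exceeds 25 %. Slopes are
evaluated as the derivative at each genotype's mean observed intake (the
raw linear coefficient of a quadratic is origin-sensitive and not a
meaningful slope); raw coefficient spreads are reported alongside. The
numeric threshold is an artifact convention — the source analysis judged
interaction by expert inspection. In the replication the efficiency curves
of all nine genotypes decline at a decreasing rate without crossing and
with slope CV well under the threshold: no interaction.

## Calibration

Free parameters (conception probability, pregnancy loss, calf mortality,
the PPI table, the gain-energy anchors, the calf gain/creep coefficients)
were calibrated once against the printed study tables at the full design
scale and frozen in `cowcalf.config` defaults; the acceptance script then
validates the calibrated pipeline. Targets: level-58 pregnancy/weaning
percentages (~85/80 per cow exposed), pregnancy ≥ 95 % at adequate levels,
~85 % of cows cycling in the first 21 days at high intake for genotypes
below 12 kg/d peak milk, the progeny grid (birth weight, ADG, weaning
weight, creep), and weaning age near 187 days.

## Known limitations

- **Weaning-age coupling.** Under the oldest-calf-220-days rule, the later
  mean calving date at the lowest intake level (late estrus resumption at
  low condition) makes level-58 calves several days younger at weaning and
  hence ~3–4 % lighter than the genotype's cross-level mean. Perfect
  weaning-weight invariance to intake level is unattainable jointly with
  the level-58 reproduction drop inside this mechanism; the residual
  dependence is measured by the test suite.
- **Condition-threshold failure.** The level-58 reproductive penalty is
  condition-mediated, so it concentrates in high-milk, small-frame
  genotypes (largest energy deficit per unit size) rather than applying
  uniformly across genotypes.
- Milk yield ignores energy intake; maintenance ignores body composition,
  visceral organ mass and feeding history; gain/loss energetics are
  symmetric. These simplifications are inherited deliberately from the
  replicated model — they are the very mechanisms whose absence explains
  why no genotype × environment interaction emerges.
- The synthetic herd emulates the study's statistical structure (normal
  genotype draws, fixed intake prescriptions, drylot feeding). It does not
  emulate grazing, weather, disease, or market-driven culling, so passing
  tests demonstrate internal consistency with the replicated design, not
  predictive validity for commercial herds.
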
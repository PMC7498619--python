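# Methods

## The experiment being modelled

A single-shrub winter experiment: on each of 15 staggered cutting dates
(21 Nov – 14 Mar; roughly weekly until late January, then 6–13-day
intervals), ten twigs are freshly cut from the shrub (treatment **S**) and —
from the second date on — five twigs are taken from containers that were
filled on day one and hung outdoors beside the shrub (treatment **C**).
All twigs go into water indoors, where their bud development is scored
periodically on the BBCH scale (0 dormancy, 1, 3, 7 bud break, 9 green
tips, 10, 11, 12 = leaf out) until the final visit, together with a
dead/alive check. Outdoor and indoor air temperature are logged every
10 minutes.

Chilling accumulates outdoors over `[experiment start, cutting date)` and
forcing indoors over `[cutting date, event date)`; the half-open windows
mean the cutting moment ends one and begins the other with no double
counting, and calendar chilling + calendar forcing always equals elapsed
days. Three parallel definitions are kept for both quantities (10-min
sample level, daily-mean level, calendar days) because a central question
for low-tech deployments is whether the simplest bookkeeping — days
outside vs days inside — suffices. Chilling uses strict `<` threshold,
forcing `≥`, so a sample exactly at the threshold counts toward forcing.
The degree-day contribution is the standard `(T − threshold)` excess.

## Statistical model

Forcing to reach a stage follows a negative exponential in chilling,
`f = a + b·e^{c·x} + ε`. The fit profiles `c` over 40 log-spaced negative
values in `[−1, −10⁻⁴]` (chilling in days): for fixed `c` the model is
linear in `(a, b)`, so each grid point costs one 2×2 solve, and the best
point seeds a Levenberg–Marquardt refinement (relative tolerance 1e-10,
max 200 evaluations). At least 4 distinct chilling values are required;
non-convergence is reported, never silently accepted. Parameter covariance
is the usual `σ̂²(JᵀJ)⁻¹`. Fits default to separate (endpoint, treatment,
definition) slices with pooling available, and rows flagged as outliers
(manual ids or a forcing ceiling per endpoint) are retained in the table
but excluded from fitting when requested.

The treatment comparison is an ANOVA-style cell-means model of forcing on
cutting date × treatment with one residual variance per cutting date. In a
saturated design the generalized-least-squares estimates are exactly the
per-cell averages, and the per-date variance is the pooled within-cell
residual variance at that date (pooled across treatments, one parameter
per chilling level); the implementation computes these in closed form, and
the test suite cross-checks against a statsmodels OLS fit on balanced
data. Contrasts use those variances with Welch–Satterthwaite degrees of
freedom and Holm adjustment — Holm because it is valid under
heteroscedasticity with no distributional extras. Between-date structure
is summarised as a compact letter display built by insert-and-absorb;
letters are verified against the brute-force pairwise matrix in tests.
Cells with fewer than two rows contribute no variance information.

Rows at late endpoints (BBCH 9/11) with under 25 calendar chill days are
dropped when fewer than 3 rows support that (endpoint, cutting date) cell;
the 3-row floor is a package choice exposed in configuration.

The simulator's model is `GDDcrit = a + b·ln(CD)`, fit by OLS on daily-mean
chill days and degree-days; zero-chill rows must be dropped (ln 0), an
asymmetry with the exponential model that is recorded in fit metadata.

## Synthetic experiment generator

The generator exists so every stage is testable without the original raw
data; its defaults are the study conditions.

- **Outdoor log**: linear-interpolated seasonal baseline anchors (6 °C in
  early Nov falling to 3 °C in Jan, rising to 16 °C by late May), a
  sinusoidal diurnal cycle (amplitude 3 °C, warmest 14:00), stationary
  AR(1) noise (sd 1.5 °C, per-step φ 0.97 at 10-min resolution), and an
  additive cold-spell window 16–24 Jan at −7 °C. This reproduces winter
  daily means mostly between 0 and 10 °C with a mid-January cold spell.
- **Indoor log**: AR(1) fluctuation (sd 0.4 °C) around 22.5 °C.
- **Truth law**: `a = 80`, `b = 400`, `c = −0.06` in subdaily degree-days
  against subdaily chill days — fully chilled buds need ≈5 days at room
  temperature to break, unchilled buds ≈27. Stage requirements are offsets
  from BBCH 7 (−60/−30/0/+25/+40/+55/+80 GDD for stages 1…12),
  non-decreasing so trajectories are monotone. One noise draw per twig
  (shared across stages) has a cutting-date-specific sd shrinking from
  45 GDD at date 1 to ≈8 GDD at date 15 — the study design motivates
  heteroscedasticity but states no magnitudes, so these are package
  choices.
- **Mortality**: death probability `p_max / (1 + (x/h)²)` with
  `p_max = 0.55` and half-scale `h = 5` chill days — maximal risk with no
  chilling, halved at `h`, negligible when well chilled. Dying twigs stall
  at BBCH ≤ 3 and are flagged dead at the first visit ≥ 14 days after
  cutting (the vitality call takes time). This yields ≈40–55 % failure at
  the first two cutting dates and well under 20 % thereafter.
- **Censoring**: twigs alive below BBCH 12 at the final visit are censored;
  twigs reaching BBCH 12 are removed (leaf-out) at that visit.
- A per-treatment additive forcing offset for C twigs exists (default 0:
  the containers hang in the shrub and see the same chilling), so the
  small S-vs-C difference can be emulated when wanted.

What the generator does **not** emulate: weather regime shifts beyond one
cold spell, humidity effects on development, photoperiod, observer error
in BBCH scoring, and between-twig correlation within a cutting beyond the
shared requirement curve. Passing tests therefore demonstrate the
pipeline's correctness and the design conclusions' internal logic on data
with this structure, not the biology of any particular shrub.

Stage attainment is evaluated at visit dates only (no back-dating into the
preceding interval), which biases recorded forcing upward by at most one
visit interval — exactly as periodic recording does in the field. Tests
that compare fitted curves against the generating truth therefore draw
(chilling, forcing) rows directly from the law
(`synthetic.sample_requirements`) rather than through the visit machinery.

## Imputation

Logger gaps (whole missing days or single samples, marked NaN) are filled
by linear interpolation in time between flanking valid samples; boundary
gaps are refused (no extrapolation). Missing BBCH entries are interpolated
linearly on the ordinal position of the valid stage sequence against date
and rounded half-*down* (a stage is only recorded once clearly reached;
half-up is available as an option), with leading/trailing gaps left
missing.

## Design evaluation

Systematic date thinning keeps every k-th cutting from starting week s;
the (k, s) grid (2,1)…(4,3) gives 8/7/5/5/5/4/4/4 dates. Twig subsampling
draws `n_keep` of the available rows per cutting date without replacement,
1,000 replicates by default, refits each, and summarises min/median/max
predicted forcing on a 101-point chilling grid from 0 to the observed
maximum. The stability figure of merit is the envelope width over the
low-chilling third of the grid, since that is where reduced designs
deteriorate first. Dates left short by mortality contribute all their rows
and are flagged.

## Warming simulator

Daily mean temperatures of a base year are shifted by `Δт_winter` over
Dec 1 – Feb 28/29 and `Δт_spring` over Mar 1 – May 31 (meteorological
seasons; both windows and the Nov 1 accumulation start are configuration
keys, as the app-style interface leaves them open). Chill days and
degree-days accumulate in parallel from the start date — a sequential mode
(forcing only after a chill quota) is deliberately not implemented —
and budburst is the first day with `CD ≥ 1` and `GDD ≥ a + b·ln(CD)`;
`CD ≥ 1` is a model boundary, since the logarithm is undefined before any
chilling has accrued. Offsets are validated against the supported
−1…+5 °C range. With `b = 0` the model degenerates to pure thermal time;
with steeply negative `b` and marginal chilling, winter warming can push
budburst later — the chilling-loss mechanism the scenario tool exists to
expose.

## Problem sizes and numerical choices

The test suite and the acceptance script run the experiment at its native
scale (15 × 10 + 14 × 5 = 220 twigs). Parameter-recovery checks use 500
replicates (tests) and 100 (script); twig-subsampling envelopes use 1,000
replicates per `n_keep` in tests and 500 in the script — the vectorised
profiling makes a fit ≈0.5 ms so these complete in seconds. Ties in BBCH
rounding go down; singular profiling grids report failure; fits with all
chilling values equal are rejected outright.

## Known limitations

- One donor plant, one winter: like the experiment it models, nothing here
  estimates between-plant or between-year variance components.
- No survival model: dead twigs contribute a "dead" endpoint row but no
  likelihood correction for censored development.
- The compact letter display refuses pathological significance patterns
  needing more than 62 groups.
- The exponential and logarithmic laws approximate each other only locally
  (tested at 5 % RMSE over a compressed chilling range); neither is a
  process-based bud model.
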
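# Methods note

## Scope and shape

`thnsim` is a forward stochastic agent-based simulator, organised as a
library of small modules (parameters/config, population synthesis, jail
dynamics, overdose engine, kit channels, runner, outcomes, Sobol screening)
with a thin CLI. There is no estimation step: all inputs are published point
values or published uncertainty ranges, and all outputs are simulated
tallies and their summaries.

## The simulated world

One tick is one day. A run is a 90-day warm-up (jail dynamics and overdoses
active, no naloxone, tallies discarded) followed by a 365-day reporting
horizon. Day ordering is fixed: bookings → releases → jail/network kit
distribution → overdose draws → event resolution → tallies. Events within a
day are resolved simultaneously (vectorised); no within-day interaction
exists between agents, so ordering inside a day has no effect — this
implements the intent of "shuffled person order" without a shuffle.

### Population

Users: 24 000 injecting (IOU) + 66 000 non-injecting (NIOU). CLI pool:
50 000, of which fractions `frac_inmates_iou` (default 0.035) and
`frac_inmates_niou` (default 0.105) are drawn uniformly from the IOU/NIOU
pools; the rest never use opioids and have zero overdose hazard. Because
bookings sample uniformly from the CLI pool, the in-custody composition
equals these fractions in expectation, which is how the published inmate
percentages are imposed. Sex and age marginals (25% female; 10/15/75% across
18–24 / 25–29 / ≥30) are placeholders for unpublished calibration detail and
are config keys, not constants.

### Jail

Bookings ~ Poisson(132/day), uniformly without replacement from alive CLI
members not in custody; re-incarceration has no modifier (released persons
rejoin the pool immediately). Stays are log-normal fitted to median 12 d and
mean 54.1 d (mu = ln 12, sigma = sqrt(2·ln(54.1/12)) ≈ 1.73547), rounded up
to ≥1 day; rounding inflates the realised mean by ~0.5 day, which we accept.
In-custody overdose hazard is zero (the risk table is framed around
community exposure) — an assumption, flagged here.

Little's law gives a steady-state census of 132 × 54.1 ≈ 7141, while the
published nightly census is ~6000. We do not resolve this tension: the
warm-up seeds custody at the configurable `census_target` (default 6000)
with length-biased residual stays (length-biased log-normal(mu+sigma²,
sigma); residual uniform on the total), and the census then drifts toward
its own steady state during the warm-up and year.

### Overdose hazard and survival

Per-user daily probability: `min(1, p0 · product of relative risks)` with
multiplicative factors for sex, injection route, age, and time since jail
release (half-open windows [0,14), [14,28), [28,∞) days; the ≥5-week
multiplier persists indefinitely; never-released = 1). Fatal and nonfatal
overdoses share all multipliers (published hazard data cannot decouple
them). At most one overdose per person per day.

Survival follows the bystander tree with closed form

    P(fatal) = f · [ (1−p_by) + p_by·( a(1−e_nx) + (1−a)(p_ems(1−e_ems) + 1−p_ems) ) ]

where `a = p_administer` if a kit is available at the scene, else 0.
Administration and the EMS call are drawn independently; naloxone dominates
(the EMS multiplier applies only when no naloxone is given) so reversal is
never double-counted. `eff_naloxone` defaults to 0.95 (proper-and-prompt
use; imperfect use is already in `p_administer`, and the key is configurable
down to 0.80). `eff_ems` has no published point value in the main analysis;
it is a visible config key defaulting to 0.50. The closed form doubles as
the test oracle for the simulated tree.

### Kits

Community: one-time assignment at horizon start (no ongoing inflow — no
re-distribution process is published). Jail and network channels trigger on
release events during the horizon only. One own kit and one peer-kit flag
per person; re-receipt is idempotent and not double-counted; kits survive
re-incarceration; an administered kit is replaced immediately and the
replacement tallied. Reported kit totals include replacements (the ledger
also carries the replacement-free total, since the published table's
convention is implied rather than stated).

## Randomness and common random numbers

All per-person randomness is *counter-based*: a splitmix64 hash of
(run key, stream id, day, person id, lane), so any variate is a pure
function of its coordinates and no hidden RNG state advances. Two runs with
the same run key — e.g. baseline and an intervention within one
(draw, replicate) cell — therefore share every booking, stay, overdose and
bystander draw exactly, and differ only where a kit changes an outcome. A
zero-coverage "intervention" reproduces the baseline bit-for-bit, and
deaths-averted comparisons are near-noiseless. Run keys derive from
(base seed, draw id, replicate id) via `numpy.random.SeedSequence` and stay
below 2^31.

For users who have never been released (static hazard), overdose days are
pre-drawn by geometric skip-ahead — distributionally identical to daily
Bernoulli draws at constant p and much faster; custody days are masked,
which is valid because the daily draws are independent. Once released, a
user switches to per-day draws on a separate stream (their hazard now varies
with the release clock).

## Scenario sweeps and summaries

The sweep runs every scenario from a per-(draw, replicate) warm-up snapshot
(warm-up dynamics are scenario-independent). Metrics are computed per draw
on replicate-averaged counts, then summarised across draws as median and
IQR (linear-interpolation percentiles, type 7 — the published method is
unstated). Per draw, cost per death averted = $76 × NNT exactly; both equal
the ICER against the zero-cost baseline, undiscounted over the one-year
horizon. Draws with zero baseline deaths (or nothing averted, for NNT/cost)
propagate as missing and are excluded with counts reported. The report
formatter rounds costs to the nearest $100 and NNT to one decimal (rounding
conventions inferred from the published table's uniform grid; switchable).

## Sensitivity screening

The published analysis does not state how its parameter draws were
generated; sampling is therefore exposed (`sobol_sequence` default,
`latin_hypercube`, `uniform_random`). Sobol first/total-order indices use
Saltelli-style sampling via `scipy.stats.sobol_indices` (SALib is not a
dependency). Each evaluation keys its runs by a CRC32 hash of the parameter
vector, making the model a pure deterministic function of the input point:
a collapsed range then contributes exactly zero variance. The default
screening outcome is the *percentage* of deaths averted among released
persons: the ratio removes most of the variance due to the baseline scale
parameters (p0, f) and isolates the intervention-effectiveness pathway in
which bystander presence acts.

## Desk scaling

`population_scale` scales the user pools, CLI pool, booking rate and census
target jointly; ratio metrics (percent averted, NNT, cost) are scale-free
and kit counts are rescaled by 1/scale for reporting. The validation
protocol (`thnsim.validation`) uses 64 Sobol-sequence draws × 27 scenarios ×
3 CRN replicates at scale 0.1 — within the stated reproduction protocol, at
roughly a tenth of full-scale cost — because the published comparisons are
medians over draws, not single-run values.

## What a green validation run does and does not establish

The generator emulates the published *stated world*: published population
sizes, booking statistics, hazard ranges and the scenario grid. It does not
reproduce unpublished calibration detail (race/ethnicity strata, the exact
sensitivity design size, the EMS effect size, MOUD dynamics, COVID-era jail
shifts, spatial structure). Green scenario-table checks therefore establish
that this implementation, run under the published protocol at desk scale,
lands inside the published IQRs — not that it matches the original code
run for run. Absolute annual overdose/death counts depend on calibration
material that is not published; ratio metrics are the primary validated
quantities, and kit counts validate the jail-flow machinery.

## Known limitations

- No multi-dose naloxone, EMS response-time variance, QALY/cost-utility
  accounting, sentencing/bail structure, or explicit social network (peers
  are a probability, not a graph) — all outside the model's scope.
- The booking-census tension (Little's law ≈7141 vs published ≈6000) is
  reported, not resolved.
- Stay rounding to whole days slightly inflates the realised mean stay.
- Demographic marginals are placeholders (see above) and materially affect
  absolute counts through the age relative risks.
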
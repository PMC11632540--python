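# thnsim

A stochastic, daily-tick simulator of opioid-overdose events and deaths in a
synthetic urban population that circulates through a county jail, built to
evaluate **take-home naloxone (THN)** distribution programs — community
handout, direct handout at jail release, and kits held by peers of released
persons — by deaths averted, cost per death averted, and the number needed to
treat (NNT).

It is aimed at modellers and harm-reduction program analysts who want a
transparent, fully reproducible re-implementation of a justice–community
circulation model: every parameter is a visible config key, every run is
deterministic given a seed, and paired scenario comparisons use common random
numbers so that "deaths averted" is not drowned in Monte-Carlo noise.

## The model

**Population.** ~90 000 opioid users — 24 000 injecting (IOU), 66 000
non-injecting (NIOU) — plus a 50 000-person pool with criminal-legal-system
involvement (CLI). CLI members who use opioids are drawn as subsets of the
user pools (defaults: 3.5% IOU, 10.5% NIOU of the pool) so that uniform
booking reproduces the published inmate composition; the remaining CLI
members never use opioids and carry no overdose hazard.

**Jail.** Bookings are Poisson (mean 132/day) from CLI members not in
custody; stays are log-normal fitted to the published median/mean pair
(12 d / 54.1 d): mu = ln 12, sigma = sqrt(2 ln(54.1/12)) ≈ 1.7355. The
warm-up seeds custody at ~6000 persons with length-biased residual stays.

**Overdose hazard.** Each user's daily overdose probability is

    p_i = min(1, p0 · RR_sex · RR_route · RR_release(t) · RR_age)

with baseline p0 = 3.3e-4/day and multiplicative relative risks; the
post-release multiplier is highest in weeks 0–2 after release (days 0–13),
lower in weeks 3–4, and a persistent ≥5-week multiplier thereafter.

**Survival.** A witnessed overdose follows a bystander tree: presence
(p = 0.3–0.9), naloxone administration when a kit is at the scene
(p = 0.5–0.9, mortality × (1−0.95)), otherwise an EMS call
(p = 0.2–0.8, mortality × (1−0.5)). Unwitnessed events are fatal with
probability f = 0.07–0.13. Kits are replaced immediately after use.

**Scenarios.** The 27-cell grid crosses community coverage {0, 15, 30%},
jail-release coverage {0, 50, 100%} and peer-network probability
{0, 15, 30%}; scenario 1 is the all-zero baseline. Outcomes are summarised
as medians/IQRs over quasi-random draws of the published parameter ranges.

## Worked example

```python
import thnsim

cfg = thnsim.load_config({"population_scale": 0.1})   # desk-scale world
grid = thnsim.scenario_grid()
base = thnsim.run_simulation(cfg, grid[0], seed=1)    # no distribution
s25  = thnsim.run_simulation(cfg, grid[24], seed=1)   # 30% community, 100% jail

print(base.deaths_total, s25.deaths_total, s25.ledger.total)
print(100 * (base.deaths_total - s25.deaths_total) / base.deaths_total)
```

prints (midpoint parameters, scale 0.1, seed 1):

```
432.0 381.0 3947
11.805555555555555
```

i.e. with every parameter at its published-range midpoint, 30% community
plus 100% jail-release distribution hands out ~3 947 kits (scaled world) and
averts ~11.8% of overdose deaths relative to the same year replayed with the
same random numbers and no naloxone. The CLI exposes the same machinery:

```sh
thnsim sweep --draws 64 --replicates 3 --scale 0.1 --out-dir out/
thnsim sobol --scenario 26 --n-base 128 --scale 0.1 --out-dir out/
```

## Validation / acceptance script

`scripts/acceptance.py` recomputes the headline scenario-table quantities
from scratch: it sweeps 64 quasi-random draws of the published parameter
ranges over the full 27-scenario grid (3 common-random-number replicates,
population scale 0.1), summarises medians across draws — deaths-averted
percentages for the key scenario groups, the cost-per-death-averted surface,
the released-subgroup targeting effect, jail-channel kit counts, NNT, and a
variant with bystander presence pinned at its upper bound — and writes them
as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Runtime is roughly 10–12 minutes on one CPU. See `docs/methods.md` for the
model's assumptions, numerical choices, and known limitations.
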
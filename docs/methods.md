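# Methods

This note documents the model, its parameters and the design choices behind
`grasstox`, in the spirit of a model description for an individual-based
ecological simulator.

## Community model

**State.** A rectangular grid of 1 cm² cells represents one pot.  Each plant
individual carries a plant functional type (PFT), integer cell coordinates,
shoot and root dry mass (mg) and an age in weeks.  Resources are abstract
units supplied homogeneously in space and constant in time, separately for
the above- and belowground layer (units · cell⁻¹ · week⁻¹).  One time step
is one week.

**Zone of influence (ZOI).** A plant acquires resources in the circle of
area `A = k · m^(2/3)` around its stem (geometric similarity: area scales
with the 2/3 power of mass).  Aboveground, `k` depends on the growth form —
rosette 1.5, semi-rosette 1.0, erect 0.5 cm²·mg^(−2/3) — because rosettes
spread leaf area over the ground while erect forms stack height.
Belowground a single coefficient `k_below = 0.6` applies to all PFTs
(similar root geometries).  `k_below` is deliberately below the mean
aboveground coefficient: root systems project less horizontal area per unit
mass, and this keeps *both* resource axes limiting in different parts of
the calibration range, i.e. identifiable (see Calibration).  Cells are
assigned by a centre-in-circle test; cells beyond the grid edge are lost
(plants cannot grow past the pot); the home cell always belongs to the ZOI.

**Competition.** In each cell the supply is divided among the claiming
plants.  Belowground weights are the PFT's competitive ability (derived
from the resource-response trait: competitor 1.0, intermediate 0.75,
stress-tolerator 0.5); aboveground weights additionally carry a factor
`shoot_mass^θ` with θ = 1, a partial size asymmetry representing shading.
Intraspecific competition is stronger than interspecific: heterospecific
competitor weights enter a focal plant's denominator discounted by
κ = 0.8.  Because per-focal denominators can nominally allocate more than
the supply in mixed cells, shares are renormalised so a cell never hands
out more than it has; conspecific-only cells partition the supply exactly.

**Growth.** Per-layer uptake is summed over the ZOI (capped at
`max_uptake_per_area` = 200 units·cm⁻²·week⁻¹, a physiological ceiling that
rarely binds at the default supplies).  The usable resource pool is the
*minimum* of the two layers (Liebig co-limitation) and is split evenly
between shoot and root.  Two species shift this split: the legume moves 20%
of the root share to the shoot, the catchfly moves 50% of the shoot share to
the root (allocation factors from trait-database root/shoot ratios).  Each
compartment then grows by

    Δm = c · R · (1 − m / m_cap),

with conversion rate `c = 0.1` mg per resource unit and `m_cap` half the
PFT's maximal plant mass per compartment (the maximal mass is a single
number per size class — small 1000, medium 3000, large 5000 mg — so the
shared cap is split half/half between shoot and root; this was a genuinely
open choice).  Combined with the `m^(2/3)` area scaling this yields sigmoid
growth of an uncrowded plant.  `c` is sized so a control monoculture
traverses the rising limb of its sigmoid over the 8-week horizon; a much
larger value saturates plants at `m_cap` within 2–3 weeks, which flattens
the growth response to the resource level and would make the resource
calibration uninformative.  Masses never decrease: mortality, senescence,
seed dynamics and biotic disturbances are excluded in this short-term model
version.

## Herbicide submodel

The effect of application rate `r` is the two-parameter log-logistic
`effect(r) = r^b/(ER50^b + r^b)` — 0.5 at `r = ER50` for any nonzero slope.
Parameters are fitted per species × product by bounded nonlinear least
squares (start: ER50 = median tested rate, b = 1; bounds ER50 ∈ (0, 100 ×
max rate], b ∈ [−10, 10]; negative slopes permitted).  Standard errors come
from the Gauss–Newton covariance at the optimum; if that matrix is singular
or ill-conditioned (condition number > 10¹²) estimates are returned with
the standard errors flagged undefined — near-flat dose responses genuinely
carry no rate information.

The fitted endpoint is the reduction of the shoot-mass *increment* between
the week-2 and week-4 assessments relative to control.  The model applies
the effect to weekly growth, and a growth-based endpoint removes the
dilution of the measured effect by pre-treatment biomass; with it,
noise-free synthetic data return the generating (ER50, b) exactly for all
reference parameter pairs, including the negative-slope one.  The plain
week-4 mass ratio is available (`baseline_week=None`).  In the simulation
the per-week gain multiplier is 1 before the application week and
`1 − effect(r)` from then on — the products do not dissipate on the 6-week
horizon.  The same multiplier acts on shoot and root gain (the simplest
reading; a shoot-only switch exists in the engine parameters).

## Experimental designs

Monoculture: 4 plants of one species on a 7×7 grid at 2-cell spacing,
germinating with probability 1 at 1 mg seedling mass (0.5 mg per
compartment).  Species are transplanted at different ages (weeks from
germination to the 2–4-true-leaf stage): 2, 0, 1, 1, 1, 2 weeks for the six
species; the herbicide is applied at that age and assessment weeks 2/4/6
after application map to simulation weeks `age + {2,4,6}`.

Community: a 20×20 grid with 8 individuals of each of the six species
placed uniformly at random under a global 2-cell minimum spacing (bounded
rejection sampling; a layout failure raises an explicit error), plus one
individual of a uniformly drawn species on the centre cell (10, 10) — 49
plants total.  Initial masses are the per-species monoculture means at the
transplant age from a control run at the same resource levels.  Application
is at community week 0.  Replicates are 4 pots per assessment date in
monoculture and 3 in the community; monoculture runs are deterministic
(replicates coincide by construction), community replicates differ through
placement and the centre-species draw, and treatment arms share their
replicate's layout seed so contrasts are paired.

## Calibration of the resource levels

Resources are abstract, so their levels are found by pattern matching:
Latin-Hypercube samples over belowground ∈ [60, 120] and aboveground ∈
[50, 100] (90 combinations × 10 replicate runs by default; exactly one
sample per equal-width stratum per dimension, uniform within stratum), each
run a control monoculture per species.  A combination is accepted iff its
mean simulated shoot mass lies inside the observed min–max envelope for
*every* species and assessment week (strict AND; a per-run mode exists).
An empty accepted set is a warning, not an error.

Identifiability: under Liebig co-limitation the growth response to each
layer has a kink — once the pot is fully covered, only the scarcer layer
matters.  The response is therefore flat in the belowground level wherever
it exceeds the aboveground level, and acceptance regions extend further on
the high-belowground side than the low side.  Recovery tests account for
this by pooling accepted samples over many generator seeds; at desk scale
(6-sample sweeps) single seeds frequently accept nothing, because the
strict conjunction over 18 species-week envelopes is demanding.

## Validation statistics

For each species (× product × rate) and week, the modeled envelope is the
2.5th–97.5th percentile band of the simulated values and the observed
envelope the min–max of the measurements; widths summed over the three
assessment weeks give the modeled area M, observed area O and their
intersection I, with the per-week overlap clamped at zero for disjoint
intervals (a signed version would count gaps as overlap).  Adequacy = I/O,
reliability = I/M.  Per-rate ratios are averaged over rates for the summary
tables ("area" mode); a "weekly" mode averages per-week ratios first — both
are provided because either aggregation is defensible, and the "All" row is
always the mean of the species rows on the same path.  Observed fresh
weights are converted to dry mass by static species-specific factors
(default 0.20, per-species overridable).  Model–data pairs are additionally
compared per species-week by Welch's unequal-variance t-test, two-sided,
α = 0.05, with no multiple-comparison correction.

Simulated per-plant records must be aggregated to per-run species means
before banding when compared against pot-level measurements — otherwise the
modeled band includes between-individual variation that the observed
records do not contain.

A structural note on reliability: when the observed envelope is the min–max
of only 3 replicates, even an exact model cannot reach reliability 1 — the
expected range of 3 draws covers ≈ 1.69 sd while a 95% band spans ≈ 3.92 sd,
an expected ceiling of ≈ 0.43.  Pipeline self-consistency tests therefore
require adequacy ≥ 0.5 but reliability only relative to that ceiling.

## Synthetic greenhouse data

The generator emulates the study design: fresh shoot weights per species ×
week (2/4/6) × replicate (4 per date in monoculture, two product batches, so
8 pooled controls per species-week; 3 per date in the community), five
rates plus control per product — 3/5/9/15/25% of 3 L/ha for the
broad-spectrum product (90–750 mL/ha) and 5/9/17/31/55% of 25 g/ha for the
selective one (1.25–13.75 g/ha).  Replicate noise is multiplicative
lognormal with sd σ = 0.15 (shoot weights are positive and right-skewed);
dry:fresh ratios are species-specific latents around 0.2.  Latent control
trajectories come from engine runs at the generating resource levels
(default (90, 75), the centre of the calibration box); per-species growth
multipliers exist to perturb the generator away from the engine but default
to 1 so that self-consistency tests operate under shared parameters.

Monoculture *treated* trajectories scale the latent control's weekly gains
by `1 − effect` — no competition feedback — so the generated week-4 growth
effect equals the generating dose-response, which is what greenhouse
endpoint data are taken to measure.  Community treated records are full
engine runs with the effect schedule, so competitive release (tolerant
species gaining from suppressed neighbours) is produced by the simulator
itself rather than an ad-hoc formula.  A truth manifest records every
generating parameter.

What the generator does not emulate: the real experiment's between-replicate
variance structure (reportedly very high for some species), temporal or
intraspecific variation in the fresh:dry ratio, batch/soil/season
differences between the two product trials, and phytotoxicity symptoms.
Passing tests therefore show pipeline self-consistency under the stated
noise model, not fidelity to the unpublished empirical data.

## Problem sizes in the test suite and acceptance script

Tests run the designs at reduced scale as the package's own choice of
desk-scale study conditions: sweeps of 2–16 Latin-Hypercube samples with 1–2
replicates (the full 90 × 10 = 900-run protocol is asserted structurally on
the manifest), communities with 1–2 replicates, dose-response round trips
over 20–25 generator seeds, and the sweep-recovery check with 6-sample
sweeps pooled over 20 seeds.  `scripts/acceptance.py` uses 20 effect points
per fit and 12-sample control ensembles.

## Known limitations

- Six-week horizon only: no mortality, recruitment, clonality or
  disturbance regimes; conclusions do not extend to long-term dynamics.
- Resource axes are abstract; the belowground level is weakly identified
  above the aboveground level (Liebig kink), so calibrated levels are a
  region, not a point.
- The dose-response transfer assumes the weekly gain reduction is constant
  (no dissipation, no recovery) and identical for shoot and root.
- Square pots stand in for the circular monoculture pots (the grid cannot
  represent a circle; the larger 7×7 square errs on the side of room for
  growth).
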
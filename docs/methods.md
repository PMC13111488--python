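# Methods

## Decision model

The package evaluates five treatment strategies for children considered for
orthodontic correction: four interceptive appliances (removable plate, Quad
Helix, extra-oral traction, Activator) and comprehensive fixed-appliance
therapy as baseline. Each interceptive arm is a two-stage chance tree. The
initial stage has three outcomes — success, partial success, failure — at
the proportions observed in a regional registry cohort. The long-term stage
applies expert-set stability probabilities: an initial success remains stable
with probability 0.75, a partial success with 0.5; the complements, and all
initial failures, receive rescue fixed-appliance therapy, which is modelled
as certain to succeed. The baseline arm is a single certain pathway. This
yields exactly five pathways per interceptive arm (probability-0 pathways
are retained so pathway counts are stable under degenerate inputs), and
expected cost/effect are probability-weighted sums over pathways. Because
the tree is linear in the outcome probabilities, Monte Carlo propagation and
deterministic evaluation share one vectorised structure.

**Effect definition.** The default effect is the indicator of initial full
success, so an arm's expected effect equals its observed initial success
rate and the baseline's is 1. Partial success contributes 0: the reported
incremental effects are consistent only with this reading. An alternative
definition — long-term stability without fixed-appliance rescue — is
available via `effect_definition="long-term"` but is not the default.

## Costs, timing, discounting

Costs are direct payer costs in EUR (inputs in SEK convert at 0.0875 EUR/SEK,
the 2024 average, at input time only). A treatment's full cost is booked at
its start year — the model works at whole-year resolution and no
intra-treatment schedule is available — and discounted at 3% per year over
an 8-year horizon. Interceptive treatment and the baseline comparator are
booked at year 0 (so the baseline's expected cost equals its undiscounted
cost); rescue fixed-appliance therapy is booked at a configurable start year,
default 5, reflecting interceptive care at roughly ages 8–10 and fixed
appliances at 14–16. Relapse after initial success may be given its own
start year; the default equals the follow-up year.

The exact timing the source analysis used is not recoverable: no single
discounted follow-up cost reproduces all four of its published interceptive
expected costs from the published per-arm inputs (the implied discounted
rescue cost differs arm by arm, because the underlying cost schedule lives
in unpublished supplementary detail). Timing is therefore a declared
parameter, and the incremental/threshold layer also accepts externally
supplied expected values (`table3_expected.csv` ships the published ones),
so that downstream arithmetic — incremental costs and effects, quadrants,
cost-neutrality thresholds and margins — is validated against the published
table independently of the timing convention. Under the package's own
default timing the model's expected costs are higher (e.g. 1989 EUR for the
Quad Helix versus the published 1545), which leaves every qualitative
conclusion intact (all interceptive arms southwest; Quad Helix the only arm
meeting its threshold) but narrows the Quad Helix margin from +20 points to
about +3.

A `CostComponents` breakdown (materials + fees + overhead + visits ×
chair-time × personnel rate) supports assembling arm costs from resource
use; when absent, the published per-arm totals are used directly.

## Incremental analysis

For each arm: Δcost and Δeffect versus baseline; plane quadrant by strict
sign (any zero component is "boundary"); minimum required effectiveness as
the ratio of expected costs (scale-invariant); margin to cost-neutrality as
(observed − required) × 100 points. ICERs are deliberately not reported —
with all arms southwest, the plane coordinates and thresholds are the
decision-relevant outputs. Reporting rounds costs to whole euros, effects
and thresholds to two decimals, margins to whole points.

## Probabilistic sensitivity analysis

Outcome triples are drawn from Dirichlet distributions centred on the
observed proportions. Each Dirichlet component is marginally
Beta(α_i, α₀ − α_i) with variance p(1 − p)/(α₀ + 1), so targeting a success
SD of σ gives the closed form α₀ = p(1 − p)/σ² − 1; σ = 0.05 by default
(≈95% of success draws within ±0.10 of the centre). Calibration targets the
success component only; partial/failure dispersions follow from the common
concentration. Degenerate centres (component 0 or 1) raise a calibration
error instructing exclusion — accordingly the baseline arm, with certain
effect, is never varied. Long-term stability probabilities are held fixed:
the probabilistic analysis addresses sampling uncertainty in the observed
rates, while the expert-set parameters are explored deterministically.

Default 10,000 iterations. One master seed; per-arm substreams are derived
from (seed, arm position) so appending an arm leaves other arms' draws
unchanged, and identical seeds give bitwise-identical outputs. Because the
tree is linear in the probabilities and the Dirichlet mean is its centre,
the PSA mean cost estimates the deterministic base case; tests check
agreement within three Monte Carlo standard errors.

## Deterministic scenario analysis

One-at-a-time scenarios: treatment cost +10% and +50%; long-term failure
rates (after initial success, `sf`; after initial partial success, `psf`)
varied ±10/50/90%. Rate changes are multiplicative on the failure
probability with the paired success probability absorbing the complement,
clamped to [0, 1] — multiplicative changes keep the entire ±90% grid
feasible for every arm, which additive changes would not. The identity
scenario returns the arm object unchanged, so the null scenario reproduces
the base case bit for bit. By default a cost scenario also scales the
in-scope arm's rescue fixed-appliance cost (cost inflation plausibly hits
the rescue treatment too); `scale_follow_up_cost=False` restricts it to the
arm's own cost. The baseline is invariant under rate scenarios (its failure
rate is 0).

## Synthetic registry cohort

`generate_cohort` draws independent multinomial outcomes per arm at
configurable true proportions — the defaults for an end-to-end run are the
registry count table's proportions at its arm sizes (4000 / 1764 / 655 /
101 / 1327). Visit counts are shifted Poisson (minimum 1; mean 6 for
interceptive arms, 20 for the comprehensive baseline) and durations
log-normal (mean 18 ± 8 months interceptive, 24 ± 6 baseline). The visit and
duration distributions are inventions of the generator — the registry
reports only that such data were extracted from it — and the decision model
consumes only the outcome proportions, so these choices affect resource-use
summaries, not cost-effectiveness results. Emergency/surplus visits are
excluded by default (the source registry's emergency data were considered
unreliable); a surplus-visit experiment can be run through the DSA cost
scenarios instead. The generator emulates sampling variation in outcome
proportions; it does not model referral pathways, clinic or operator
effects, age structure, or outcome–resource-use correlation, so passing
recovery tests demonstrate statistical consistency of the pipeline, not
clinical realism of individual records.

One published count row is internally inconsistent (removable plate:
1145 + 484 + 149 = 1778 ≠ 1764, while the printed percentages imply a
failure count of 135); the packaged count table uses 135 so that counts sum
to N and estimated percentages reproduce the printed ones.

`estimate_rates` returns per-arm proportions with Wilson 95% confidence
intervals (statsmodels); `cohort_to_params` combines estimated rates with a
cost table and the default long-term assumptions into model-ready arms.

## Numerical choices and degenerate inputs

Probability triples must sum to 1 within 1e-9; all validation errors name
the offending field. Zero-probability pathways are kept. The Dirichlet
calibration rejects target SDs at or beyond the feasibility boundary
sqrt(p(1 − p)) (with a 1e-9 guard for round-off). Quadrant classification is
strict-sign with an explicit boundary class, so an arm compared with itself
is boundary, not an error. All tabular I/O is header-first delimited text.

## Problem sizes and known limitations

Tests run the probabilistic analysis at the full 10,000 iterations, the
enumeration-versus-joint-distribution oracle on 1,000 randomised arms, and
parameter recovery over 200 replicate cohorts at the registry arm sizes —
the analysis is small enough that the study-scale configuration runs in
seconds. Known limitations: the baseline's assumed certain success overstates
real-world effectiveness; long-term stability parameters are expert opinion,
not data; the published expected costs cannot be reproduced exactly from
published inputs (see timing, above), so the model's own base-case costs are
systematically higher and its cost-neutrality margins more conservative; and
the Quad Helix margin under the default timing (+3 points) is narrow enough
that replicate cohorts at the registry sample size flip its cost-neutrality
verdict in roughly one seed in ten — an honest reflection of how close that
arm sits to the threshold under this cost model.
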
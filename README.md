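# ascot-bws

A best–worst scaling (BWS) valuation pipeline for the **ASCOT-Carer**
instrument — the Adult Social Care Outcomes Toolkit for informal carers,
which measures long-term-care-related quality of life over 7 domains
(occupation, control over daily life, looking after yourself, personal
safety, social participation, space and time to be yourself, feeling
supported and encouraged), each at 4 outcome levels (ideal state, no needs,
some needs, high needs).

The package is aimed at health-economics and outcomes researchers who need
preference weights for the instrument's 28 domain-levels: it builds the
profile-case (case 2) BWS experiment, simulates respondent choice data,
estimates the choice model by maximum likelihood, and turns the fitted
utilities into a 0–1 preference-weight table and a scorer for full response
profiles. Because valuation survey microdata typically cannot be shared, a
first-class synthetic-data generator reproduces the structure of an
Austrian general-population valuation survey (n = 1001, 8 tasks per
respondent, 4 sequential picks per task) so the whole estimation chain is
testable end to end.

## Model

Each choice task shows one statement per domain (7 items). Respondents pick
best, worst, second best and second worst; the available set shrinks
7 → 6 → 5 → 4. Stage choices follow a **scale-adjusted multinomial logit
(S-MNL)** with an exploded (sequential) likelihood: for respondent *r* with
scale multiplier λ<sub>r</sub>, item *i* at display position *p*,

- best-type stages:  P(i) ∝ exp( λ<sub>r</sub> (β<sub>i</sub> + δ<sub>p</sub>) )
- worst-type stages: P(i) ∝ exp( −λ<sub>r</sub> β<sub>i</sub> )

and the task probability is the product of the four stage probabilities
with sequential removal. β are the 28 level utilities (reference: *space
and time to be yourself*, level 4, pinned to 0; levels 1–2 of *feeling
supported and encouraged* share one coefficient), δ are positioning effects
for best-type picks (position 1 = 0), and λ captures scale heterogeneity —
group multipliers for task understanding, age 35+, and slow completion
(completion time at or above the first-quartile threshold), with the
reference group at λ = 1. That leaves 26 + 6 + 3 = 35 free parameters,
estimated by quasi-Newton maximum likelihood with an analytic score, and
inference uses the cluster-robust sandwich covariance A⁻¹BA⁻¹ clustered on
respondents to account for the 8 repeated tasks.

The experimental plan is an orthogonal main-effects plan: an
OA(32, 8, 4, 2) — 32 scenarios, 7 domain columns plus one blocking column,
every column pair strength-2 orthogonal — constructed by collapsing
disjoint closed triples of the 32-run Hadamard-derived two-level array, and
verified by exhaustive pair counting. The 8th column splits the scenarios
into 4 blocks of 8 tasks; display order is randomised per respondent.
Respondents completing the experiment in under 4.5 minutes are dropped
before estimation.

Fitted utilities become preference weights via per-domain min–max rescaling
with a shared denominator, w[d][l] = (β[d][l] − min<sub>l</sub> β[d]) / C with
C = Σ<sub>d</sub> (max<sub>l</sub> β[d] − min<sub>l</sub> β[d]), so the total
score of the best possible state is exactly 1 and of the worst possible
state exactly 0.

## Worked example

```python
from ascot_bws import (
    austria_reference_params, default_instrument, rescale_weights,
    score_state, rank_items,
)

spec = default_instrument()
params = austria_reference_params()          # published Austrian estimates
weights = rescale_weights(params.beta, spec)

for r in rank_items(params.beta, spec)[:3]:
    print(f"{r.item.domain} level {r.item.level}: utility {r.value:.2f}, "
          f"weight {weights.weight_of(r.item):.4f}")

carer = {"OCC": 2, "CTL": 1, "SELF": 2, "SAFE": 1, "SOC": 3, "STS": 2, "ENC": 2}
print(f"score of a mixed state: {score_state(carer, weights):.4f}")
```

prints

```
OCC level 1: utility 3.53, weight 0.1699
STS level 1: utility 3.50, weight 0.1876
STS level 2: utility 3.39, weight 0.1817
score of a mixed state: 0.8966
```

The two top-ranked states by utility are *occupation* at level 1 (3.53) and
*space and time to be yourself* at level 1 (3.50); on the weight scale the
ordering between near-tied items can differ because each domain is shifted
by its own minimum. The mixed state — an informal carer doing "enough" but
not everything they value, with some unmet social contact — scores 0.8966
of the 0–1 range; the all-level-1 state scores exactly 1.0 and the
all-level-4 state exactly 0.0.

The same steps are available from the shell:

```sh
ascot-bws design   --seed 0 --out design.csv
ascot-bws simulate --design design.csv --seed 3 --n-respondents 1001 --out-dir survey/
ascot-bws fit      --choices survey/choices.csv --profiles survey/profiles.csv --out fit.json
ascot-bws weights  --fit fit.json --out-csv weights.csv
ascot-bws score    --weights weights.csv --states states.csv --out scores.csv
```

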
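# cohortmslt

Multistate life-table (MSLT) estimation of **partial life expectancy (LE)**
and **disability-free life expectancy (DFLE)** from longitudinal disability
panels, with full-pipeline bootstrap inference for comparing birth cohorts.

## Who this is for

Demographers and epidemiologists asking whether successive generations of
the oldest old (ages 80+) are living longer *and* with less disability.
Cross-sectional prevalence comparisons miss the dynamics — individuals
relapse and remit between disabled and disability-free life, and disability
interacts with mortality — so the question needs transition modeling. This
package implements the full analysis sequence for panel surveys that
observe Katz ADL disability at a handful of waves: person-year expansion,
transition-model fitting, attrition weighting, microsimulation life tables,
and bootstrap cohort comparison. Because real oldest-old panels are
typically access-restricted, a first-class synthetic-panel generator with
known ground truth makes every stage testable.

## The model

Disability is coded from the six Katz ADL items: a person is **disabled**
if they need personal assistance in one or more of the five essential
activities (bathing, transferring, dressing, eating, toileting) or are
incontinent; otherwise **nondisabled**; **dead** is absorbing.

Wave observations are expanded to an annual person-year scale, assuming at
most one transition per observation interval, placed at a uniformly random
year within it (deaths with known dates are placed deterministically).
Annual transitions out of each living state are modeled with a
partial-proportional-odds cumulative logit on the ordered outcome
nondisabled < disabled < dead:

    P(Y ≤ j | x, z) = expit(α_j + β·(age − a₀) + γ_j·z),   j = 1, 2

with `z = (sex, urban/rural residence, formal schooling)` carrying
logit-specific coefficients `γ_j` (the proportional-odds assumption is
relaxed for them), fit by weighted maximum likelihood stratified by origin
state. Fits are weighted by inverse-probability-of-attrition weights times
the cross-sectional sampling weight. The fitted models give age- and
profile-specific 3×3 transition matrices; a synthetic cohort of 100,000
individuals is then microsimulated year by year across a bounded age
window (e.g. 80–89) to estimate partial total LE, DFLE and disabled LE
under the standard a = 0.5 occupancy-credit convention. Confidence
intervals re-run the entire sequence on bootstrap resamples of
individuals (central 95% of 499 replicates by default), and cohort
differences get nonparametric sign-count p-values.

An exact deterministic occupancy oracle (forward propagation of the state
distribution) mirrors the microsimulation for testing and ground truth,
and an end-of-life sensitivity adjustment reallocates a uniform fraction
of the final life-year of those dying straight from the nondisabled state
to disabled time.

## Worked example

`examples/03_cohort_comparison.py` generates an earlier and a later
octogenarian cohort (1,500 individuals each at desk scale), runs the full
pipeline with a 49-replicate bootstrap and prints:

```
| Stratum   | Quantity        | Earlier cohort   | Later cohort     |   Diff | P value   |
|:----------|:----------------|:-----------------|:-----------------|-------:|:----------|
| overall   | Total           | 6.05 [5.76–6.28] | 6.32 [6.06–6.56] |   0.27 | 0.041     |
| overall   | Disability-free | 5.09 [4.78–5.41] | 5.43 [5.16–5.67] |   0.35 | < 0.001   |
| overall   | ADL disabled    | 0.97 [0.85–1.06] | 0.89 [0.78–0.99] |  -0.08 | 0.327     |
```

Read: between exact ages 80 and 89 the earlier-born cohort lives on
average 6.05 of the 10 possible years, 5.09 of them disability-free; the
later-born cohort gains 0.27 years of partial LE and 0.35 disability-free
years — the generator's ground truth encodes exactly such an improvement,
and the pipeline recovers it with calibrated uncertainty. The other
examples cover the generator (`01`), oracle-vs-microsimulation agreement
(`02`), attrition weighting (`04`) and the end-of-life sensitivity
adjustment (`05`).

A thin CLI mirrors the library:
`cohortmslt simulate | expand | weights | fit | simulate-lt | bootstrap |
compare | run` (see `cohortmslt --help`); `cohortmslt run --config
analysis.yaml` executes a reproducible end-to-end analysis with a run
manifest.

## Panel CSV schema

Long format, one row per individual-wave: `id, wave_index, wave_date, age,
bathing, transferring, dressing, eating, toileting, continence, state,
dead, death_date, lost, sex, residence, schooling, sampling_weight,
aux_*`. Either all six ADL item columns are filled (the state is derived)
or the precoded `state` column is used. Absent death dates are empty
fields. `examples/01_simulate_cohort.py` writes a valid fixture.

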
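# Methods

## The disproportionality model

Spontaneous-report databases collect case reports, each naming one or
more drugs (with FAERS role codes — primary suspect, secondary suspect,
concomitant, interacting) and one or more adverse-event preferred terms
(PTs). Disproportionality analysis asks, for one target drug and each PT,
whether the pair is co-reported more often than the rest of the database
would predict. The counting unit throughout is the unique deduplicated
case: each report contributes to exactly one cell of the fourfold table
(a, b, c, d), where "drug" membership means the target drug is named as
primary suspect and the comparator is every other report in the ingested
corpus. Tables are emitted for every PT with a ≥ 1 so that sub-threshold
pairs stay inspectable; the a ≥ 3 rule is applied at signal-detection
time, not at counting time.

### ROR

ROR = (a·d)/(b·c), with the Wald interval on the natural-log scale,
SE(ln ROR) = √(1/a + 1/b + 1/c + 1/d) and critical value z = 1.96
(configurable). When b, c or d is zero the estimate or its SE is
undefined; 0.5 is then added to all four cells (Haldane–Anscombe) and the
result is flagged `zero_corrected` rather than silently shifting
estimates for well-populated tables. The signal criterion — a ≥ 3 and CI
lower bound > 1 — always evaluates a on the uncorrected table.

### BCPNN information component

IC = log₂[a·N/((a+b)(a+c))] measures observed-to-expected co-reporting.
The Bayesian version places conjugate Beta priors on the joint and
marginal reporting probabilities with prior counts α₁ = β₁ = γ₁₁ = 1,
α = β = 2 and the data-dependent joint prior total

    γ = γ₁₁ (N+α)(N+β) / ((a+b+α₁)(a+c+β₁)),

chosen so that the prior centers IC at 0. The closed forms are

    E(IC) = log₂[(a+γ₁₁)(N+α)(N+β) / ((N+γ)(a+b+α₁)(a+c+β₁))]
    V(IC) = (1/ln 2)² [ (N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
                      + (N−(a+b)+α−α₁)/((a+b+α₁)(1+N+α))
                      + (N−(a+c)+β−β₁)/((a+c+β₁)(1+N+β)) ]

and IC025 = E(IC) − 2√V(IC); the signal criterion is IC025 > 0. The
hyperparameters are exposed (`BcpnnHyperparams`) because published
analyses vary in their exact parameterization.

Two numerical properties of these closed forms are worth knowing:

- **Shrinkage is approximate, not exact.** Because γ centers the prior at
  the *prior-adjusted* margins rather than the observed-margin
  independence point, |E(IC)| can overshoot |IC_raw| by up to about
  3/min(a+b, a+c). The property tests assert shrinkage up to that slack.
- **The delta approximation is anticonservative at small a.** E(IC) is
  the log of a ratio of posterior means, not the posterior mean of IC,
  and the ±2 SD band ignores the strong left skew of log₂ of a Beta
  variate with small shape. Against the Monte-Carlo posterior quantile
  (`mc_ic_quantile`, independent Beta draws for the joint and the two
  margins exactly as the prior structure implies), the worst-case
  |IC025(delta) − IC025(MC)| scales like ≈1.4/a: about 0.45 at a = 3,
  crossing 0.15 near a = 10, and negligible for well-supported pairs.
  Both routes are provided; for pairs near threshold with a < 10 the MC
  quantile is the more trustworthy bound. A Dirichlet posterior over the
  four cells was considered and rejected as the oracle: without the
  data-dependent shrinkage prior it diverges from the BCPNN model by more
  than one IC unit on disproportional tables.

### Signals, ranking, aggregation

A pair is a signal iff both criteria hold simultaneously. Sub-threshold
pairs are carried with `is_signal=False` for auditability. Ranking is by
report frequency (a) or signal intensity (ROR CI lower bound), ties
broken by the other key then PT name, so orderings are total and
reproducible. SOC aggregation conserves totals and refuses silently
dropping unmapped PTs (it raises listing the offenders). SOC exclusion
defaults to the four conventionally non-pharmacologic categories
(injury/poisoning/procedural, pregnancy, congenital, product issues) and
is a plain configuration list. Label expectedness is exact case-folded PT
membership in a supplied label term list — clinical "relatedness" between
different terms is deliberately out of scope and must be reviewed by a
human; absent a list the field is unknown rather than false.

## Ingest conventions

The on-disk format is long (one row per case–drug–reaction), tab-delimited
by default, ISO-8601 dates, empty field = unknown; mandatory columns are
case id, drug name, role code and PT. Unparseable demographics degrade to
unknown, never to an error. Deduplication keeps the highest case version
per case id (ties: latest receipt date, then smallest canonical
serialization) — the standard rule for raw FAERS quarterly files — and is
an explicit, skippable stage because pre-cleaned extracts may arrive
already deduplicated. The date window filter is a closed interval on
receipt date; records without a parseable date are excluded by the
filter. PT normalization is trim + case-fold only: mapping verbatim text
to a licensed MedDRA dictionary is out of scope, so PT identity is
textual.

## The synthetic-report generator

The generator emulates the marginal structure the statistics actually
consume, and nothing more: per report, one primary-suspect drug (a
designated target drug with prevalence 0.02 by default, otherwise a
uniform other drug) plus a Poisson(1) number of co-reported drugs with
non-suspect roles; conditional on drug status, PTs are independent
Bernoulli draws. Injected pairs multiply the background rate by a rate
ratio (≥ 1, capped at probability 1) on target-drug reports only. Default
background rates are drawn once per corpus, uniform on [0.001, 0.05]
(≈2.5 PTs per report, a realistic reporting multiplicity); the
recovery-benchmark configuration pins the injected PTs' background at
0.002 with rate ratio 10 and 50,000 reports, giving expected a = 20.
Demographics are MCAR categorical draws whose defaults reproduce the
heavy missingness of real oncology spontaneous reports (≈75% unknown sex
and age; countries dominated by an unclassified bucket); receipt dates
are uniform over a June 2020 – June 2023 window. All randomness fans out
from one root seed via `numpy.random.SeedSequence`, so corpora are
byte-identical under a fixed config.

Two deliberate simplifications: (1) a report whose Bernoulli draws all
miss receives one PT drawn proportional to its rate vector, so every
report carries a reaction; this inflates marginal PT rates by a few
percent, well inside the 3-SD band the count-calibration test uses.
(2) There is no drug–drug correlation, no reporter-type structure and no
time trend — so passing recovery tests demonstrates correctness of the
counting and statistics under the model's own assumptions, not robustness
to confounded real-world reporting.

`inject_duplicates` adds version-bumped copies of a chosen fraction of
cases (payload otherwise identical), making the dedup round-trip an exact
identity on full records.

## Demographics and outputs

Composition ratios are 100·n/total rounded **half-up** to two decimals
(this is the rounding rule that reproduces published composition tables
exactly; banker's rounding does not). Age bands are fixed at 18–49,
50–69, ≥ 70 and unknown; ages under 18 are counted as unknown because the
banding targets an adult-indication drug. Country grouping is a
configurable mapping defaulting to United States / Japan / Europe /
Other, with missing countries in Other. The demographics denominator for
a fitted result is the set of distinct target-drug reports contributing
to cell a of at least one signal PT. All tabular outputs are written with
fixed column orders and are byte-identical across reruns on identical
inputs; plots are not generated (the tabular surfaces are the product).

## Problem sizes

Defaults were chosen so a full validation pass is cheap on one CPU: the
closed-form precision suite uses 1,000 random tables against a 50-digit
decimal oracle; the MC agreement suite 60 tables × 50,000 posterior
draws; the recovery benchmark 8 corpora of 50,000 reports with 3 injected
pairs each (24 detection trials) plus one 600-PT null corpus (≥ 500 null
pairs). The end-to-end demo pipeline completes in a few seconds.

## Known limitations

- PT identity is textual; no MedDRA hierarchy beyond the supplied PT→SOC
  map.
- The comparator is "all other reports in the corpus"; stratified or
  restricted-background tables are not implemented.
- The IC025 delta approximation should not be trusted to better than
  ~1.4/a against the exact posterior quantile (see above).
- Label annotation is exact membership; "related" terms require human
  review.
- Signal ≠ causality: the statistics measure reporting disproportion in a
  voluntary reporting system, with all its biases.
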
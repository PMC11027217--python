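# Methods

This note documents the models and procedures implemented in `ddiprev`,
the assumptions behind them, and the design choices made where the design
was genuinely open.

## Temporal model of administration

A dispensation is a half-open day interval `[start, start + duration)`
(daily resolution) or a single billing month (monthly resolution). We
assume dispensed drugs are administered for the entire recorded length.
Before any pairwise computation, same-drug intervals of one patient are
merged when they overlap **or abut**: a refill issued the day a previous
supply runs out is one continuous administration episode. After merging,
α<sub>i</sub><sup>u</sup> is the number of disjoint episodes of drug *i*
for patient *u* and λ<sub>i</sub><sup>u</sup> the number of distinct
administration days (in monthly mode, months; there α = λ by construction).
Merging matters: without it, overlapping refills would double-count
calendar time and inflate every downstream length statistic. Whether
source refill records should be merged is a judgement call; we merge, and
pair overlap still requires at least one genuinely shared day.

## Co-administration and the pair statistics

Two drugs are co-administered by a patient when their merged day sets
intersect (≥ 1 shared day) or share a billing month. Because per-drug
intervals are disjoint and non-abutting after merging, the pairwise
intersection fragments are themselves disjoint, non-abutting episodes, so
α<sub>ij</sub> is simply the fragment count and λ<sub>ij</sub> the summed
fragment length. The implementation is an interval sweep over a
self-merge of the interval table; the test suite holds it equal to a
brute-force oracle that materializes every (patient, drug, day) triple.

Per patient, the strength of co-administration is

τ<sub>ij</sub><sup>u</sup> = λ<sub>ij</sub> / (λ<sub>i</sub> + λ<sub>j</sub> − λ<sub>ij</sub>),

the Jaccard overlap of the two drugs' administered time units. The
denominator is read as the *union* of administered time rather than the
symmetric difference: the union form is the one that satisfies both
required boundary behaviours (τ ∈ (0, 1], and τ = 1 exactly at complete
temporal overlap, where a symmetric-difference denominator would divide by
zero). τ is symmetric, and grows monotonically when the overlap grows
with the union held fixed.

At population level, γ<sub>ij</sub> = |U<sub>ij</sub>| / |U<sub>i</sub>|
is the conditional likelihood that a user of *i* co-administers the pair;
it is directional (γ<sub>ij</sub> ≠ γ<sub>ji</sub>), and each patient
counts once regardless of episode count. The identity
γ<sub>ij</sub>·|U<sub>i</sub>| = γ<sub>ji</sub>·|U<sub>j</sub>| =
|U<sub>ij</sub>| holds exactly because all three quantities are integer
counts divided at the last step.

## Stratified prevalence and relative risks

PC (prevalence of co-administration) and PI (prevalence of interaction)
are patient fractions. Strata are gender × 5-year age bin × severity.
Age is completed years at the *event date* (the start of the dispensation
or of the co-administration episode), so one patient legitimately
contributes to several age bins; the denominator of a stratum is the
number of patients with at least one administration in it — populations
here are defined by drug use, not enrolment. Severity strata are
non-exclusive.

The gender relative risk RR<sup>W</sup> is the ratio of the two gender
prevalences, with a two-sided Fisher exact test on the gender × affected
2×2 and Benjamini–Hochberg correction across the strata of a report
(Bonferroni available as an option). RRs are reported to two decimals in
presentation tables; note that a ratio recomputed from *rounded* printed
prevalences can differ from an RR computed on unrounded counts by up to a
few hundredths — the package always computes from counts.

## Null model

The null asks how much of the age-increasing PI is explained by
polypharmacy alone. Per age bin and replicate, every patient receives
exactly their observed number of distinct drugs, drawn without replacement
from the drugs observed in that bin, and then their observed number of
distinct co-administered pairs, drawn without replacement from the pairs
of the randomized set (capped at C(d, 2)); the patient counts as
interacting if any drawn pair is in the reference. Default 100
replicates. Observed counts are compared with the replicate-pooled null
counts in a single 2×2 (odds ratio + Fisher exact); per-replicate
expected PI is also reported, and its Monte-Carlo error shrinks as
1/√reps.

Two sampling modes exist. `frequency_weighted` (default) weights each
drug by its observed patient count in the bin, approximating a label
shuffle that preserves drug popularity; `uniform_distinct` draws uniformly
from the bin's distinct-drug pool. Weighted sampling without replacement
uses the exponential-race construction (keys ∼ Exp(1)/w, take the d
smallest), which is exactly successive weighted draws and vectorizes
across patients and replicates. Patients with zero observed pairs are
skipped in the replicate loop — their null outcome is identically
non-interacting.

On synthetic cohorts whose interaction labels are independent of
dispensation the pooled odds ratio is ≈ 1 with a small conservative lean
(mean ≈ 0.96 across seeds): the bin's patient-count weights are slightly
more concentrated than the generator's popularity law, so null draws hit
popular (and hence popular-pair) interactions marginally more often than
observed dispensation does. The lean is well inside the calibration band
and is a property of the label-shuffle approximation, not of the data.
We pass over all patients once per replicate rather than bootstrap
resampling patients; with all patients included the two readings differ
only in Monte-Carlo noise.

## Interaction network

Each observed interacting pair is tested for co-usage enrichment: a
one-sided hypergeometric tail on the 2×2 of (takes *i*) × (takes *j*)
with the joint cell the number of *concomitant* co-administrators. Both
Bonferroni-adjusted p-values and BH q-values are emitted; edges require
FDR ≤ 0.05. Note the joint cell is a subset of "uses both", so pairs
whose co-usage is temporally dilute are (correctly) depleted — an edge
asserts that the pair is co-administered concomitantly more often than
independent usage would produce. Node weight is
|U<sub>i</sub><sup>φ</sup>| / |U<sub>i</sub>|, the probability that a user
of the drug is exposed to a significant interaction involving it, computed
as a set union over the drug's significant pairs. Edges carry mean τ, the
pair's gender relative risk (stored unclipped plus a display copy clipped
to [1, 5]), severity, co-user count and the test results. Export is
GraphML (round-trip safe) or a flat edge list, optionally filtered by a
minimum strength (the published rendering shows strengths above 0.18).
Patients are counted over the whole study window for the margins.

## Substitution simulation

For a target drug with same-class alternatives, every merged target
episode that participates in a known interaction is examined; the first
alternative (ascending count of known interactions, ties broken
lexicographically — deterministic and biased toward the safest substitute)
whose known interactions are disjoint from *all* drugs concurrently
administered during that episode replaces the target in the underlying
records, dates and durations unchanged. If no alternative qualifies the
episode is kept and the blocking drugs recorded. Decisions are per
episode, so a patient can keep the target in one episode and substitute in
another; a `scope="all"` mode attempts replacement of every target episode
instead of only interacting ones. By construction substitution never
creates a new interaction, is idempotent, and conserves each patient's
administered time; prevalences can therefore only decrease, and the report
gives PI before/after, the relative reduction, and the number of patients
freed of interactions per (gender, severity) stratum.

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes,
not a fit to any real population's marginals:

* **Drug popularity** — rank power law with exponent 1.2 over 150 drugs,
  reproducing the situation where a few hub drugs dominate
  co-administration.
* **Polypharmacy** — distinct drugs per patient ∼ negative binomial
  (dispersion 5) with mean 3.0 + 0.8 per decade of age; overdispersed
  counts with an age-increasing mean are the empirical norm.
* **Administrations** — start dates uniform in the window; durations
  geometric with mean 75 days (monthly mode: geometric month runs,
  mean 2.5); a 25% chance of a second dispensation per drug exercises the
  refill-merging logic. These defaults yield PC ≈ 76% and PI ≈ 12% on an
  18-month monthly cohort, matching the aggregate levels reported for the
  real populations this pipeline is designed for.
* **Interaction reference** — a fraction 0.035 of unordered pairs marked
  interacting, severities drawn from (0.3, 0.5, 0.2) over
  (major, moderate, minor); labels are independent of dispensation, which
  is what makes the null-model calibration experiment meaningful.
* **Gender-specific drugs** — 2% of drugs restricted to one gender
  (contraceptive-like), switchable off for gender-null experiments.
* **Planted effects** — a pair's co-dispensation probability in a target
  gender/age stratum is multiplied by m: the natural qualifying-overlap
  rate q is measured on the eligible stratum, then overlaps are removed
  with probability 1 − m (m < 1) or injected for non-overlapping patients
  with probability q(m − 1)/(1 − q) (m > 1), giving a stratum rate of
  exactly q·m in expectation. Per-patient uniforms come from a
  multiplier-independent substream, so the co-dispensation indicator is
  pathwise monotone in m. If q = 0 a multiplicative effect has nothing to
  scale and no overlap is injected.
* **Determinism** — every table derives from one seed through named
  substreams, so any table can be regenerated independently.

Parameter-recovery experiments (e.g. recovering a planted women-only
interaction relative risk of 1.6 in the 40–44 bin) use a chronic-cohort
configuration (ages 40–44, mean 5 drugs, 120-day durations) in which the
planted pair's natural co-occurrence is ≈ 15%: the precision of a ratio
of two prevalence estimates is governed by the affected counts, and at
n = 20,000 a rare pair (q ≈ 1%) would leave ≈ 15% noise on the ratio —
more than the recovery tolerance itself.

What passing tests on synthetic data do **not** show: the generator has no
comorbidity structure (drug choices are conditionally independent given
age/gender), no seasonal or calendar effects, no informative censoring,
and interaction labels uncorrelated with therapeutic class. Conclusions
about real cohorts require real data; the synthetic suite validates the
*machinery* — detection, counting, stratification, calibration of the
tests — not epidemiological claims.

## Numerical and procedural choices

* Day arithmetic is integer throughout; half-open intervals make lengths
  and overlaps exact. No floating point enters before the final ratios.
* Hypergeometric tails are computed directly (`scipy.stats.hypergeom.sf`)
  rather than per-pair Fisher calls; the two agree to machine precision
  and the former vectorizes over all pairs.
* Fisher exact tests (gender 2×2, observed-vs-null 2×2) use
  `scipy.stats.fisher_exact`; multiplicity correction uses
  `statsmodels.stats.multitest.multipletests`.
* Empty strata are emitted with null prevalences and an `empty` flag
  rather than dropped, so report shapes are stable.
* A drug-user count of zero can never reach a γ division: pairs are only
  emitted for patients who administered both drugs.
* Pipeline runs write a manifest with a config hash and SHA-256 of every
  output; identical config + seed reproduces every artifact byte for byte.

## Problem sizes

Default experiment sizes used by the test suite and the acceptance script:
oracle equivalence on 500 instances of ≤ 20 patients × ≤ 8 drugs × 60
days; null-model calibration and relative-risk recovery at n = 20,000
patients × 100 replicates × 20 seeds (monthly resolution); the
gender-null false-positive-rate check at 200 replicates of n = 1,000.
These sizes give the experiments their stated statistical power while
keeping a full run on one CPU in the tens of minutes.

## Known limitations

* Monthly resolution cannot see sub-month timing; two drugs billed in one
  month count as co-administered even if taken on disjoint days.
* The enrichment network tests usage-pattern association, not clinical
  harm; severity is an annotation, not a weight in the test.
* The substitution planner is greedy per episode and does not model dose
  equivalence, formulary availability or cost.
* Combination products must be atomized to constituent drugs upstream;
  the pipeline consumes already-normalized drug identifiers.
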
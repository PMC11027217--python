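# ddiprev

Population-scale surveillance of the co-administration of drugs known to
interact, built for longitudinal drug-dispensation records (EHR extracts,
pharmacy claims) at daily or monthly temporal resolution.

## The problem

Adverse drug reactions caused by drug–drug interactions (DDIs) are a major
public-health burden, and their prevalence rises sharply with age and
polypharmacy. Given a table of dispensations (patient, drug, start,
duration), patient demographics, and a reference of known interacting pairs
with severities (major / moderate / minor), `ddiprev` answers:

* **Who co-administers what?** Two drugs are co-administered when their
  administration periods share at least one day (daily data) or are billed
  in the same calendar month (monthly data). Per patient *u* and drug pair
  (*i, j*) the package counts disjoint co-administration episodes
  α<sub>ij</sub><sup>u</sup> and co-administered time units
  λ<sub>ij</sub><sup>u</sup>.
* **How strongly?** The strength of co-administration
  τ<sub>ij</sub><sup>u</sup> = λ<sub>ij</sub> / (λ<sub>i</sub> + λ<sub>j</sub> − λ<sub>ij</sub>) ∈ (0, 1]
  is 1 at complete temporal overlap; its cohort mean weights the
  co-administration graph. The directed conditional likelihood
  γ<sub>ij</sub> = |U<sub>ij</sub>| / |U<sub>i</sub>| gives the probability
  that a patient taking drug *i* also co-administers *j*.
* **How prevalent, and for whom?** The prevalence of co-administration (PC)
  and of interaction (PI) are computed overall and stratified by gender,
  5-year age bin (age at the drug event — a patient can appear in several
  bins) and severity, with gender relative risks
  RR<sup>W</sup> = prevalence(W)/prevalence(M) tested by Fisher's exact
  test under Benjamini–Hochberg (or Bonferroni) correction.
* **Is it explained by polypharmacy alone?** A null model reassigns each
  patient the same number of distinct drugs and co-administered pairs, drawn
  at random from the drugs observed in the patient's own age bin, and
  compares observed vs expected PI per bin by odds ratio (100 replicates by
  default).
* **Which interactions matter at population level?** Interacting pairs
  co-administered more than expected from their usage margins
  (one-sided Fisher, FDR ≤ 0.05) form a network whose node weight is the
  probability a drug's users are exposed to a significant DDI through it;
  exported as GraphML or an edge list.
* **What could be done?** A counterfactual simulation replaces a target drug
  (e.g. an omeprazole-like hub) with same-class alternatives wherever the
  alternative avoids all known interactions with concurrently administered
  drugs, then recomputes prevalences.

Because real dispensation EHRs are not shareable, the package includes a
first-class synthetic cohort generator (Zipf-like drug popularity,
age-increasing negative-binomial polypharmacy, gender-specific drugs,
plantable pair effects) so every stage is testable end to end.

## Worked example

```python
from ddiprev import SyntheticConfig, NullModelConfig
from ddiprev import synthetic as sy, coadmin as ca
from ddiprev.prevalence import compute_prevalence, gender_relative_risks
from ddiprev.nullmodel import run_null_model

cfg = SyntheticConfig(n_patients=20000, seed=1, resolution="monthly")
patients = sy.generate_population(cfg)
records = sy.generate_dispensations(patients, cfg)
ddi = sy.generate_ddi_reference(cfg)

intervals = ca.pair_intervals(records, cfg.window)
prev = compute_prevalence(intervals, records, patients, ddi)
overall = prev.query("gender == 'all' and age_bin == 'all' and severity == 'any'")
print(f"PC = {100 * overall.pc.iloc[0]:.2f}%  PI = {100 * overall.pi.iloc[0]:.2f}%")

summary, _ = run_null_model(intervals, records, patients, ddi,
                            NullModelConfig(n_reps=100, seed=1), cfg.window)
row = summary.query("age_bin == 'all'").iloc[0]
print(f"expected PI = {100 * row.expected_pi_mean:.2f}%  "
      f"observed-vs-null OR = {row.odds_ratio:.3f}")
```

prints

```
PC = 76.42%  PI = 11.76%
expected PI = 12.37%  observed-vs-null OR = 0.944
```

i.e. roughly three quarters of this synthetic cohort co-administer at least
one drug pair, about 12% are exposed to a known interaction, and — because
the generator assigns interaction status independently of dispensation —
the observed PI matches the polypharmacy-preserving null expectation
(odds ratio ≈ 1).

The same stages are available from the shell:

```bash
ddi synth --config synth.yaml --out tables/
ddi prevalence --dispensations tables/dispensations.csv \
    --patients tables/patients.csv --ddi tables/ddi_reference.csv \
    --resolution monthly --window 2014-01-01:2015-06-30 --out prev/
ddi run --config pipeline.yaml --out run1/   # full pipeline + manifest
```

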
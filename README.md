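# targetdx

Targeted evaluation of diagnostic accuracy studies: derive **minimally
acceptable criteria (MAC)** for sensitivity and specificity from the
quantitative consequences of testing, test the joint MAC hypothesis on
2×2 data, size the study that can demonstrate MAC compliance, and verify
the whole procedure by simulation.

## The problem

A diagnostic accuracy study compares an index test against a reference
standard and reports two accuracy proportions: sensitivity
Se = TP/(TP+FN) and specificity Sp = TN/(FP+TN). Unlike a trial, where
"no effect" is a natural null, "not informative" is useless as a null
for a test that is already on the bench: the meaningful question is
whether the test is informative **enough** for its clinical role. That
is formalised as a joint hypothesis against pre-specified MAC:

    H1: Se ≥ MAC(Se)  and  Sp ≥ MAC(Sp)
    H0: Se < MAC(Se)  and/or  Sp < MAC(Sp)

The alternative is a rectangle [MAC(Se), 1] × [MAC(Sp), 1] — the
"target region" — in ROC space. `targetdx` covers the quantitative
steps of this workflow, for statisticians and clinical researchers
designing or appraising single-test accuracy studies:

* **MAC derivation** — back-calculate the minimal specificity implied by
  a cap on the test-positivity rate (e.g. an acceptable prescription
  rate) at a given prevalence and sensitivity floor; or derive the
  minimum positive likelihood ratio LR+ = [t/(1−t)]·[(1−π)/π] that
  reaches a required post-test probability t from prevalence π.
* **Inference** — an intersection–union test (IUT): each component is an
  exact one-sided binomial test at level α and the joint null is
  rejected only when both reject, so p_joint = max(p_Se, p_Sp). By
  Clopper–Pearson duality this is exactly the graphical rule "the
  one-sided rectangular (1−α) confidence region lies inside the target
  region". For continuous scores, a threshold scan reports which cut-offs
  meet MAC.
* **Sample size** — per group, the two-z one-sample proportion formula

      n = ⌈( z₁₋α·√(MAC(1−MAC)) + z_pow·√(p(1−p)) )² / (p − MAC)²⌉

  with p the expected accuracy, plus an exact-binomial search; the cohort
  total inflates the binding group through the prevalence.
* **Simulation** — Monte-Carlo size and power of the joint test under a
  known truth, and end-to-end calibration of the sample-size procedure.

## Worked example

A clinical decision rule is meant to triage children with pharyngitis
for group-A streptococcal (GAS) infection (prevalence ≈ 35%). Capping
the antibiotic prescription rate at 40% with a sensitivity floor of 85%
forces a specificity of at least 85%:

```sh
$ targetdx derive-mac --prevalence 0.35 --mac-sensitivity 0.85 \
    --max-positivity-rate 0.40 --arithmetic per_hundred_integer
```

yields (stdout, abridged): `"expected_tp_per_100": 30.0,
"allowed_fp_per_100": 10.0, "nondiseased_per_100": 65.0,
"specificity_percent": 85` — per 100 children, 30 true-positive
prescriptions leave room for 10 false positives among 65 GAS-negative
children, i.e. specificity 1 − 10/65 ≈ 85%.

Sizing a study to demonstrate MAC 0.85/0.85 when the expected accuracy
is Se = 0.92, Sp = 0.95 (one-sided α = 0.05, power 0.90):

```sh
$ targetdx sample-size --mac-sens 0.85 --mac-spec 0.85 \
    --expected-sens 0.92 --expected-spec 0.95 \
    --alpha 0.05 --power 0.90 --prevalence 0.35
```

prints

```json
"sample_size": {
  "n_diseased": 179,
  "n_nondiseased": 76,
  "n_total": 512,
  "binding_group": "diseased",
  "n_total_for_diseased": 512,
  "n_total_for_nondiseased": 117
}
```

179 participants **with** and 76 **without** the condition are needed;
at 35% prevalence the diseased group binds, so ⌈179/0.35⌉ = 512
suspected patients must be enrolled. The same numbers are available in
Python:

```python
from targetdx import DesignSpec, MACriteria, sample_size

design = DesignSpec(alpha=0.05, power=0.90,
                    expected_sensitivity=0.92, expected_specificity=0.95,
                    mac=MACriteria(0.85, 0.85), prevalence=0.35)
sample_size(design).n_diseased   # 179
```

Evaluating observed strategies (`targetdx evaluate --tables tables.csv
--mac-sens 0.85 --mac-spec 0.85`) reports per-strategy exact p-values,
whether each point estimate and confidence region lies in the target
region, and summary counts; `targetdx region` exports the plot-ready
rectangle and confidence-region geometry in ROC axes
(x = 1 − specificity, y = sensitivity).

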
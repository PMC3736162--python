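# mdstiming

Decision analysis of allogeneic stem-cell transplantation (HSCT) timing in
myelodysplastic syndromes (MDS), built on continuous-time multistate Markov
models.

Allogeneic HSCT is the only curative option for MDS but carries substantial
treatment-related mortality, so *when* to transplant is a genuine decision
problem: transplanting a low-risk patient trades a long indolent course for
up-front risk, while waiting too long means transplanting advanced disease
with poor post-transplant outcomes. This package implements the full
analysis pipeline for that question, for biostatisticians and outcomes
researchers working with panel-observed registry data:

* **Model.** Disease course is a continuous-time Markov chain on the risk
  states of a prognostic score (IPSS: Low → Int-1 → Int-2 → High; WPSS:
  Very-low → … → Very-high), leukemic evolution (AML) and absorbing death.
  From each risk state the chain may move to the next risk state, to AML or
  to death, with transition intensities `q_ij` (per year). Transplantation
  enters as a time-dependent covariate multiplying each state's death
  intensity by a state-specific hazard ratio `HR_k = exp(β_k)`; under WPSS
  the very-low state is not transplantable and carries no HR.
* **Estimation.** Maximum likelihood from two panel-observed cohorts — a
  supportive-care cohort (states seen at visit times, death times exact) and
  a transplanted cohort observed from transplantation onward — in one joint
  likelihood built from matrix exponentials `P(t) = exp(Qt)`, with Wald CIs
  from the inverse Hessian and goodness of fit by model-vs-Kaplan–Meier
  survival curves.
* **Decision analysis.** For a policy "transplant on reaching threshold
  state s\* after a delay of *t* months, or immediately on progression past
  s\*, never at or after age 65", expected survival from diagnosis — plain
  or QALY-weighted — is computed algebraically from phase-type expectations
  `α'(−A)⁻¹w`, validated by microsimulation, with bootstrap CIs by
  subject-level resampling stratified by cohort.

## Worked example

Evaluate delayed-transplantation policies under the documented IPSS fixture
parameters (invented values whose structure mimics real cohorts; see
`docs/methods.md`):

```python
import mdstiming as m
from mdstiming.likelihood import FittedModel

params = m.default_fixture_parameters("IPSS")
model = FittedModel.from_parameters(params.space, params.structure,
                                    params.q, params.effects)

print(f"life expectancy from Low, no transplant: "
      f"{m.no_transplant_value(model, 0):.2f} years")
for label, delay in [("Low", 0), ("Low", 60), ("Int-1", 0), ("Int-1", 60), ("Int-2", 0)]:
    pol = m.TransplantPolicy(params.space.index(label), delay, age_at_diagnosis=40)
    pv = m.policy_expected_survival(model, pol, m.default_utilities(params.space))
    print(f"transplant in {label:>5} after {delay:>2} mo: "
          f"LE {pv.life_expectancy:.2f} y, gain {pv.gain_vs_no_transplant:+.2f} y, "
          f"QALY {pv.qaly:.2f}")
```

prints

```
life expectancy from Low, no transplant: 6.96 years
transplant in   Low after  0 mo: LE 6.82 y, gain -0.14 y, QALY 6.13
transplant in   Low after 60 mo: LE 7.87 y, gain +0.92 y, QALY 7.22
transplant in Int-1 after  0 mo: LE 8.18 y, gain +1.22 y, QALY 7.53
transplant in Int-1 after 60 mo: LE 8.01 y, gain +1.06 y, QALY 7.47
transplant in Int-2 after  0 mo: LE 7.98 y, gain +1.03 y, QALY 7.46
```

Read: transplanting a 40-year-old at diagnosis in Low risk *costs* 0.14
expected years (the HR of 3 in low-risk disease outweighs its low baseline
mortality), whereas waiting for progression to Int-1 and transplanting
immediately gains 1.22 years over never transplanting; delaying once in
Int-1 erodes that gain. The independent Monte-Carlo check agrees:

```python
pol = m.TransplantPolicy(params.space.index("Int-1"), 0, age_at_diagnosis=40)
mu, se = m.microsim_value(params.q, params.effects, pol, params.space,
                          n=200_000, rng=0)
# -> 8.18 +/- 0.012, matching the algebraic 8.18
```

The same workflow applies to fitted models: `fit_model(cohorts, space,
structure)` returns a `FittedModel` usable everywhere above.

## Command line

```sh
mdstiming simulate-cohort --scheme IPSS --n 660 --seed 1 --out nh.csv
mdstiming fit --scheme IPSS --cohort nh.csv --cohort tx.csv --out model.yaml
mdstiming policy-table --model model.yaml --out gains.csv
mdstiming run-all --config config.yaml --out results/
```

`run-all` executes fit → goodness of fit → policy tables (plain and QALY)
→ microsimulation cross-check → optional bootstrap, and writes CSV tables,
plots and a summary; every output embeds the config hash and seed, and
reruns are byte-identical.

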
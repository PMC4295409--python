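# prevmod

Registry-based estimation and projection of **complete cancer prevalence** —
the number of people alive today who were ever diagnosed with a cancer —
and its decomposition into **phases of care** for health-service planning.
The package is aimed at cancer epidemiologists and registry analysts who
need current and future prevalence, not just counts at a past date, and who
want those projections broken into clinically meaningful groups (initial
therapy, post-treatment monitoring, long-term survivorship, end-of-life
care, and renewed treatment after metastasis or a second primary).

The defaults describe the motivating application: first primary female
breast cancer in an Australian state registry, ages 18–84 at diagnosis,
diagnoses observed 1972–2007, projections to 2017. Because such extracts
are confidential, the package ships a synthetic-registry generator with
known ground truth, and the whole estimation chain is validated against the
generator's direct-count oracle.

## The model

Prevalence is built from modelled incidence and net survival through
discrete transition equations on a mid-year grid. For report year *t*,
attained age *a* and duration *d* since diagnosis:

```
N(a, t, d) = I(a−d, t−d) · PY(a−d, t−d) · RS(d; g(a−d), t−d) · S_E(a−d, t−d, d)
```

- **I** — incidence rate per person-year from an age–period–cohort Poisson
  model, `log λ = α₀ + Σ αᵢ aⁱ + Σ γₖ cᵏ` with cohort `c = p − a`; nine
  candidate polynomial models (APC101 … APC303) ranked by the
  likelihood-ratio statistic, projected backward and forward;
- **RS** — net (relative) survival: a Pohar Perme actuarial tabulation by
  age group × diagnosis period (cohort approach), smoothed by a mixture
  cure model `RS(t) = c + (1−c)·exp(−(λt)^γ)` with the cure fraction `c`
  trending on the logit scale over diagnosis years;
- **S_E** — expected (other-cause) survival along the diagnosis-cohort
  diagonal of the all-cause life table.

Summing over *d* gives complete prevalence; the excess-survival decrement
`S_E(d)·[RS(d) − RS(d+1)]` gives expected cancer deaths, which are compared
with an external mortality series as a validation of the whole chain, and
which drive the last-year-of-life phase. Phase counts are mutually
exclusive and sum to total prevalence exactly. `docs/methods.md` has the
full account.

## Worked example

Run the whole pipeline on the default synthetic registry and read the
report:

```python
from prevmod.cli_report import PipelineConfig, run_pipeline

out = run_pipeline(PipelineConfig(), "runs/default")
print((out / "report.md").read_text())
```

which prints (default seed):

```
# Prevalence projection report

Total prevalence: 48,991 (2007) -> 68,557 (2017); average annual linear increase 3.99%.

Percent change by age group (attained age at the report year;
denominators are the start-year group counts):
- 18-49: 29.9%
- 50-69: 44.9%
- 70-84: 38.8%

Mean absolute relative difference, expected vs observed cancer deaths: 0.029
About 9% of prevalent cases in 2017 require active treatment (initial therapy or treatment for metastases/second primary).
```

Reading the numbers: prevalence grows from ~49,000 women in the last
observed year to ~68,600 a decade later (a linear 4%/year), driven by
rising cohort incidence, improving survival and population ageing; the
expected-mortality validation (2.9% mean absolute relative difference
against deaths the model never saw) says the fitted survival surface
correctly modulates the incidence–mortality relationship; and about 9% of
survivors need active treatment — initial therapy plus renewed treatment
after metastasis or second primary — while most need monitoring or
long-term follow-up only. The output directory also contains the APC model
ranking, the tabulated and fitted survival surfaces, the full prevalence
surface by age × year × duration, the phase-of-care table and a manifest of
digests; reruns with the same seed are byte-identical.

The same stages are available from the shell:

```
prevmod run-all --out runs/default
prevmod simulate --out runs/registry --seed 7
prevmod fit-incidence --registry runs/registry --out runs/inc --model APC303
```

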
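# hepakin

Dual-input liver FDG kinetic modelling and parameter estimation for short
(5-minute) dynamic PET, with three interchangeable fitters — bounded
nonlinear least squares (NLLS), the gravitational search algorithm (GSA)
and a dynamic chaotic GSA (DCGSA) — plus a synthetic-cohort simulator and
a statistical evaluation layer (AIC/BIC, group t-tests, ROC/DeLong).

It is aimed at researchers in PET pharmacokinetics who want to study how
estimator choice affects liver kinetic parameters — for example how well
hepatocellular carcinoma (HCC) separates from background liver on
`k1`/`k3`/`HPI` — on fully controlled simulated data.

## The model

The liver's dual blood supply is mixed by the hepatic arterial perfusion
index:

```
C_B(t) = HPI · A(t) + (1 − HPI) · P(t)
```

and the tissue curve follows the reversible two-tissue-compartment
solution

```
C_T(t) = K1/(α2−α1) · [(k3+k4−α1) e^{−α1 t} + (α2−k3−k4) e^{−α2 t}] ⊗ C_B(t)
α1,2  = [(k2+k3+k4) ∓ √((k2+k3+k4)² − 4 k2 k4)] / 2
```

with `k1` (ml/min/ml) blood→tissue transport, `k2` (1/min) clearance,
`k3` phosphorylation, `k4` dephosphorylation. All five quantities
`(k1, k2, k3, k4, HPI)` are estimated jointly by minimising the sum of
squared residuals between the measured per-frame values and the model
curve averaged over the 16-frame schedule (12 × 5 s + 4 × 60 s). See
`docs/methods.md` for numerics, the optimizer update rules, and known
limitations.

## Worked example

Simulate one noisy HCC-like subject and fit it with all three methods:

```python
import numpy as np
from hepakin import default_cohort_spec, generate_cohort, fit_tac, fit_quality

spec = default_cohort_spec(n_per_group=1, noise_level=0.01, seed=42)
subject = generate_cohort(spec)[0]          # group "HCC", 16-frame TAC
print("true:", np.round(subject.true_params.to_vector(), 3))
for method in ("nlls", "gsa", "dcgsa"):
    res = fit_tac(subject.tissue, subject.arterial, subject.portal,
                  method, seed=1)
    q = fit_quality(res)
    print(f"{method:6s} x={np.round(res.x, 3)}  sse={res.fun:.4g}  "
          f"aic={q.aic:.1f}")
```

prints

```
true: [0.649 0.605 0.149 0.06  0.955]
nlls   x=[0.623 0.562 0.142 0.079 1.   ]  sse=0.00675  aic=-114.3
gsa    x=[1.311 2.19  0.628 0.347 0.477]  sse=0.01168  aic=-105.6
dcgsa  x=[1.414 2.352 0.572 0.299 0.434]  sse=0.01108  aic=-106.4
```

The true parameter vector (k1, k2, k3, k4, HPI) is drawn from the HCC
group distribution; multi-start NLLS lands close to it with the lowest
residual (and hence lowest AIC), while the swarm fitters stop on the
flat valley of the sum-of-squares surface — individual kinetic fits of
16-frame data are only weakly identified, which is exactly the kind of
estimator behaviour the package exists to quantify (see "Known
limitations" in `docs/methods.md`). At cohort level the group contrasts
in `k1`, `k3` and `HPI` remain recoverable (see the report produced
below).

The same pipeline is available from the shell:

```
hepakin simulate --out cohort/ --n-per-group 10 --seed 7
hepakin fit --cohort cohort/ --method nlls --method dcgsa --out fits/ --seed 7
hepakin evaluate --fits fits/ --out report/
hepakin benchmark --out bench.csv --seed 7
```

`report/summary.csv` is a per-method table of mean ± sd per parameter and
group with Student's-t p values and oriented ROC AUCs (DeLong CIs);
`report/fit_quality.csv` summarises AIC/BIC per group and method.

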
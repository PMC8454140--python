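# ritisurv

Effect estimation for a **time-varying intermediate event** on a
time-to-event outcome when part of the population is **insusceptible** to
the intermediate event.

## The problem

In transplantation, oncology and other follow-up settings, an intermediate
event — acute GVHD, disease progression, a treatment switch — changes the
hazard of the terminal outcome and enters the analysis as a time-varying
covariate z(t).  Extended Cox (Mantel–Byar) regression and landmark
analysis remove immortal-time bias, but both keep subjects who can *never*
experience the intermediate event in the event-free group.  That
contamination biases the estimated log hazard ratio β_z.

`ritisurv` implements a three-step remedy:

1. **Fit** a logistic–Weibull mixture cure model to the intermediate-event
   data by EM: susceptibility probability π(x) = expit(γ₀ + γᵀx), latency
   S(t|s=1,x) = exp(−λ_e t^{ν_e} e^{β_eᵀx}).
2. **Pre-identify** the susceptible subpopulation by residual
   intermediate-event time imputation (RITI): a subject censored at C_e is
   labelled susceptible iff a uniform draw u exceeds the insusceptible
   posterior (1−π)/(1−π+πS(C_e|s=1,x)) — exactly when a residual event
   time can be imputed by inverting the conditional survival function.
   A deterministic 0.5-cutoff variant and a Bernoulli(π(x)) logistic
   control classifier (LRM) are included.
3. **Estimate** β_z on the identified subpopulation by extended Cox
   regression (counting-process encoding, semiparametric partial likelihood
   or Weibull baseline) or landmark analysis at t_LM.

A full simulation engine with known truth and a Monte-Carlo harness compare
the eight strategies exCox1–4 / LM1–4 (entire population / LRM-identified /
RITI-identified / true susceptible, per estimator) by BIAS and MSE.

## Worked example

```python
from ritisurv import run_method
from ritisurv.simulation import SimulationConfig, assemble_dataset

cfg = SimulationConfig(scenario="iii", r=0.3, beta_z=-1.0, nu=1.0,
                       omega=0.67, N=2000, seed=23)
data = assemble_dataset(cfg)        # subject table with simulation truth
for code in ["exCox1", "exCox3", "exCox4"]:
    est = run_method(code, data, rng_seed=5)
    print(code, round(est.beta_z_hat, 3))
```

prints

```
exCox1 -0.232
exCox3 -0.287
exCox4 -0.634
```

The true effect is β_z = −1.  `exCox1` (entire population) is badly
attenuated by the 70% insusceptible fraction; `exCox4` (true susceptible,
infeasible in practice) is closest; the proposed `exCox3` (cure-model fit →
stochastic RITI → extended Cox) sits in between on this single cohort.
Averaged over 20 replications (`examples/method_comparison.py`) the
ordering is stable:

```
method   BIAS   MSE
exCox1  0.363 0.160
exCox2  0.325 0.136
exCox3  0.196 0.074
exCox4 -0.019 0.022
LM1     0.511 0.309
LM2     0.467 0.285
LM3     0.422 0.252
LM4     0.230 0.101
```

i.e. RITI pre-identification (codes 3) removes roughly half of the
contamination bias, the LRM control (codes 2) barely helps, and the
extended-Cox benchmark (exCox4) is unbiased.

The `examples/` directory has one narrative script per capability
(cure-model fitting, classification, effect estimation, the method
comparison, and a shell pipeline for a case-study-style analysis via the
`ritisurv` CLI: `simulate`, `fit-cure`, `classify`, `estimate`,
`run-experiment`, `case-study`).  All inputs and outputs are plain
delimited text; see `docs/methods.md` for the model, its assumptions and
numerical details.

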
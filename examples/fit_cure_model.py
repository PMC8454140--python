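"""Fit the logistic--Weibull mixture cure model to intermediate-event data.

Simulates a cohort in which only part of the population is susceptible to
the intermediate event, fits the mixture cure model by EM, and compares the
recovered incidence/latency parameters with the generating values.
"""

import numpy as np

from ritisurv import fit_mixture_cure
from ritisurv.cure_model import export_fit
from ritisurv.simulation import SimulationConfig, assemble_dataset, calibrate_gamma0, scenario

# half the population susceptible; covariate scenario (ii): two binary
# covariates plus U(0,5) and U(0,10); omega=1 and beta_z=0 keep the
# intermediate-event censoring law identical in both latent classes, so the
# cure-model likelihood is correctly specified and estimates target truth
cfg = SimulationConfig(scenario="ii", r=0.5, beta_z=0.0, omega=1.0, nu=1.0,
                       N=3000, seed=7)
data = assemble_dataset(cfg)
print(f"cohort: N={len(data)}, intermediate events={int(data.delta_e.sum())}, "
      f"susceptible fraction={data.s_true.mean():.3f}")

fit = fit_mixture_cure(data)
print(f"EM converged={fit.converged} after {fit.n_iter} iterations\n")
print(export_fit(fit))

g0 = calibrate_gamma0(scenario("ii"), np.ones(4), 0.5)
print("generating values: gamma0=%.3f, gamma=1 (all), lambda_e=0.0115, "
      "nu_e=1.0, beta_e=(1.2, 1.2, 0.24, 0.12)" % g0)
print("Each fitted coefficient should sit within a few Monte-Carlo standard "
      "errors of its generating value.")
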
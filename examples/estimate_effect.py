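"""Estimate the intermediate-event effect with and without pre-identification.

On one simulated cohort with a 30% susceptible fraction and a protective
intermediate-event effect (beta_z = -1), compares:

* exCox1 - extended Cox on the entire population (biased: insusceptible
  subjects dilute the event-free group);
* exCox3 - extended Cox on the RITI-identified susceptible subpopulation
  (the proposed pipeline);
* exCox4 - extended Cox on the true susceptible subpopulation (benchmark,
  infeasible in practice).
"""

from ritisurv import run_method
from ritisurv.simulation import SimulationConfig, assemble_dataset

cfg = SimulationConfig(scenario="iii", r=0.3, beta_z=-1.0, nu=1.0, omega=0.67,
                       N=2000, seed=23)
data = assemble_dataset(cfg)

print(f"true beta_z = {cfg.beta_z}")
for code in ["exCox1", "exCox3", "exCox4"]:
    est = run_method(code, data, rng_seed=5)
    print(f"{code}: beta_z_hat={est.beta_z_hat:+.3f} (SE {est.se_beta_z:.3f}), "
          f"n={est.n_subjects}, events={est.n_events}")
print("\nexCox4 should be closest to -1, and exCox3 should sit between "
      "exCox1 and exCox4 by dropping likely-insusceptible subjects before "
      "fitting.  A single cohort is noisy; method_comparison.py shows the "
      "ordering stabilise across replications.")
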
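"""Pre-identify the susceptible subpopulation with RITI and the LRM control.

After fitting the mixture cure model, subjects whose intermediate event was
censored are classified as susceptible or insusceptible.  RITI uses both the
incidence part pi(x) and the conditional latency survival S(C_e | s=1, x);
the LRM control uses pi(x) alone.  Against the simulation truth, RITI should
score a higher Youden index (sensitivity + specificity - 1).
"""

from ritisurv import (
    classify_lrm,
    classify_riti_deterministic,
    classify_riti_stochastic,
    fit_mixture_cure,
    youden_index,
)
from ritisurv.simulation import SimulationConfig, assemble_dataset

cfg = SimulationConfig(scenario="iii", r=0.3, beta_z=-1.0, nu=1.0, N=2000, seed=11)
data = assemble_dataset(cfg)
fit = fit_mixture_cure(data)

s_true = data.sort_values("id")["s_true"].to_numpy()
for name, calls in [
    ("RITI stochastic", classify_riti_stochastic(fit, data, rng_seed=1)),
    ("RITI deterministic (cutoff 0.5)", classify_riti_deterministic(fit, data)),
    ("LRM control", classify_lrm(fit, data, rng_seed=1)),
]:
    y = youden_index(s_true, calls["label"].to_numpy())
    n_sus = int((calls["label"] == 1).sum())
    print(f"{name:32s} susceptible calls={n_sus:4d}  Youden index={y:.3f}")

print("\nTrue susceptible count:", int(s_true.sum()),
      "- RITI should out-score the LRM because it also uses how long each"
      " subject stayed event-free.")
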
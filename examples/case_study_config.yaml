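# Template configuration for a case-study-style synthetic cohort.
#
# Emulates a progression-to-death analysis: a minority of patients is
# susceptible to disease progression (the intermediate event), progression
# raises the death hazard, and baseline covariates drive both progression
# and survival.  Adjust the fields to match the disease setting at hand;
# scenario picks the covariate layout (i / ii / iii).
scenario: i      # four binary prognostic factors
r: 0.25          # susceptible (progression-prone) fraction
beta_z: 2.0      # log hazard ratio of progression on death
nu: 1.0          # Weibull shape shared by progression and death times
omega: 0.67      # covariate-effect attenuation in the insusceptible group
tau: 12.0        # administrative censoring, months
N: 1500
seed: 42
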
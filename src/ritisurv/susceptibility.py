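"""Pre-identification of the subpopulation susceptible to the intermediate event.

Subjects with an observed intermediate event are susceptible by definition.
For a subject censored at C_e, the fitted mixture cure model gives the
conditional probability of being insusceptible given no event by C_e:

    ratio = (1 - pi(x)) / (1 - pi(x) + pi(x) S(C_e | s=1, x))

RITI (residual intermediate-event time imputation) draws u ~ U(0,1) and tries
to invert the conditional residual-time distribution: when u > ratio a
positive residual event time a_e is calculable and the subject is labelled
susceptible; when u <= ratio the inversion has no solution ("incalculable")
and the subject is labelled insusceptible.  The deterministic variant instead
compares the ratio with a fixed cutoff (0.5 by default).  The LRM control
classifier uses only the incidence part: Bernoulli(pi(x)).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cure_model import (
    CureModelFit,
    incidence_probability,
    latency_survival,
)

__all__ = [
    "insusceptible_ratio",
    "residual_event_time",
    "classify_riti_stochastic",
    "classify_riti_deterministic",
    "classify_lrm",
    "youden_index",
]

INCALCULABLE = None  # distinguished residual-time value


def insusceptible_ratio(fit: CureModelFit, x: np.ndarray, C_e: float) -> float:
    """Posterior probability of insusceptibility given no event by C_e.

    Nondecreasing in C_e (the longer a subject stays event-free, the more
    likely they are insusceptible); equals 1 - pi(x) at C_e = 0.
    """
    if C_e < 0:
        raise ValueError("censoring time must be nonnegative")
    pi = incidence_probability(fit.incidence, np.asarray(x, dtype=float))
    S = latency_survival(fit.latency, float(C_e), np.asarray(x, dtype=float))
    return (1.0 - pi) / (1.0 - pi + pi * S)


def residual_event_time(
    fit: CureModelFit, x: np.ndarray, C_e: float, u: float
):
    """Impute the residual intermediate-event time after censoring at C_e.

    Solves P(T_e > C_e + a | T_e > C_e) = u for a by inverting the Weibull
    latency survival.  Returns the positive residual time, or ``None``
    ("incalculable") when u <= insusceptible ratio, in which case the target
    survival level is not attainable by a susceptible subject and the subject
    is deemed insusceptible.
    """
    if not (0.0 < u < 1.0):
        raise ValueError("u must be in (0,1)")
    x = np.asarray(x, dtype=float)
    pi = incidence_probability(fit.incidence, x)
    S_C = latency_survival(fit.latency, float(C_e), x)
    target = (u * (1.0 - pi + pi * S_C) - (1.0 - pi)) / pi if pi > 0 else -1.0
    if target <= 0:
        return INCALCULABLE
    lat = fit.latency
    rate = lat.lambda_e * np.exp(float(x @ lat.beta_e))
    t_total = (-np.log(target) / rate) ** (1.0 / lat.nu_e)
    a = t_total - C_e
    return float(a) if a > 0 else INCALCULABLE


def _prep(data: pd.DataFrame) -> pd.DataFrame:
    """Stable subject-id order so random draws are order-independent."""
    return data.sort_values("id", kind="mergesort").reset_index(drop=True)


def _ratios(fit: CureModelFit, data: pd.DataFrame) -> np.ndarray:
    from .cure_model import covariate_columns

    X = data[covariate_columns(data)].to_numpy(dtype=float)
    pi = np.asarray(incidence_probability(fit.incidence, X))
    S = np.asarray(latency_survival(fit.latency, data["t_e"].to_numpy(float), X))
    return (1.0 - pi) / (1.0 - pi + pi * S)


def _check_fit(fit: CureModelFit) -> None:
    if not fit.converged:
        warnings.warn(
            "classifying from a non-converged cure-model fit", RuntimeWarning
        )


def classify_riti_stochastic(
    fit: CureModelFit, data: pd.DataFrame, rng_seed: int
) -> pd.DataFrame:
    """Stochastic RITI classification of every subject.

    Event subjects (delta_e=1) are labelled susceptible unconditionally; each
    censored subject gets one independent uniform draw and is labelled
    insusceptible iff u <= ratio.  Draws are consumed in subject-id order, so
    results depend only on the seed, not on input row ordering.
    """
    _check_fit(fit)
    d = _prep(data)
    ratio = np.where(d["delta_e"].to_numpy(int) == 1, 0.0, _ratios(fit, d))
    rng = np.random.default_rng(rng_seed)
    u = rng.uniform(size=len(d))
    censored = d["delta_e"].to_numpy(int) == 0
    label = np.where(censored & (u <= ratio), 0, 1)
    return pd.DataFrame(
        {
            "id": d["id"],
            "label": label,
            "ratio": ratio,
            "u": np.where(censored, u, np.nan),
            "method": "RITI-stochastic",
        }
    )


def classify_riti_deterministic(
    fit: CureModelFit, data: pd.DataFrame, cutoff: float = 0.5
) -> pd.DataFrame:
    """Deterministic RITI: insusceptible iff censored and ratio > cutoff (strict)."""
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must be in (0,1)")
    _check_fit(fit)
    d = _prep(data)
    ratio = np.where(d["delta_e"].to_numpy(int) == 1, 0.0, _ratios(fit, d))
    censored = d["delta_e"].to_numpy(int) == 0
    label = np.where(censored & (ratio > cutoff), 0, 1)
    return pd.DataFrame(
        {
            "id": d["id"],
            "label": label,
            "ratio": ratio,
            "u": np.nan,
            "method": "RITI-deterministic",
        }
    )


def classify_lrm(
    fit: CureModelFit, data: pd.DataFrame, rng_seed: int
) -> pd.DataFrame:
    """Logistic-regression-model control classifier.

    Uses only the incidence part: a censored subject is labelled susceptible
    with probability pi(x), by one Bernoulli draw; event subjects are
    susceptible unconditionally.
    """
    from .cure_model import covariate_columns

    d = _prep(data)
    X = d[covariate_columns(d)].to_numpy(dtype=float)
    pi = np.asarray(incidence_probability(fit.incidence, X))
    rng = np.random.default_rng(rng_seed)
    u = rng.uniform(size=len(d))
    censored = d["delta_e"].to_numpy(int) == 0
    # Bernoulli(pi): susceptible iff u < pi
    label = np.where(censored & (u >= pi), 0, 1)
    ratio = np.where(censored, 1.0 - pi, 0.0)
    return pd.DataFrame(
        {
            "id": d["id"],
            "label": label,
            "ratio": ratio,
            "u": np.where(censored, u, np.nan),
            "method": "LRM",
        }
    )


def youden_index(true_s: np.ndarray, predicted_s: np.ndarray) -> float:
    """Youden index = sensitivity + specificity - 1 of a susceptibility call."""
    true_s = np.asarray(true_s, dtype=int)
    predicted_s = np.asarray(predicted_s, dtype=int)
    if true_s.shape != predicted_s.shape:
        raise ValueError("length mismatch")
    n_pos = (true_s == 1).sum()
    n_neg = (true_s == 0).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in the truth")
    sens = ((true_s == 1) & (predicted_s == 1)).sum() / n_pos
    spec = ((true_s == 0) & (predicted_s == 0)).sum() / n_neg
    return float(sens + spec - 1.0)
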
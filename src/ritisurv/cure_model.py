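"""Logistic--Weibull mixture cure model for a time-varying intermediate event.

The population survival function of the intermediate-event time mixes an
insusceptible fraction, which never experiences the event, with a susceptible
fraction whose event time follows a Weibull proportional-hazards law:

    S_pop(t | x) = 1 - pi(x) + pi(x) * S(t | s=1, x)

with logistic incidence  pi(x) = 1 / (1 + exp(-(gamma0 + gamma' x)))  and
Weibull latency  S(t | s=1, x) = exp(-lambda_e * t**nu_e * exp(beta_e' x)).

``fit_mixture_cure`` maximises the observed-data likelihood

    L = prod_i [pi f(t_ei)]**delta_ei * [1 - pi + pi S(t_ei)]**(1-delta_ei)

by EM: the E-step computes the posterior susceptibility weight of each
censored subject; the M-step is a weighted logistic fit (incidence) plus a
weighted Weibull-PH likelihood maximisation (latency), both warm-started from
the previous iterate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "IncidenceParams",
    "LatencyParams",
    "CureModelFit",
    "covariate_columns",
    "incidence_probability",
    "latency_survival",
    "latency_density",
    "marginal_intermediate_survival",
    "observed_loglik",
    "fit_mixture_cure",
    "read_subject_table",
    "write_subject_table",
    "export_fit",
]

# numerical guards used inside logarithms
_PI_EPS = 1e-12
_S_FLOOR = 1e-300
_LP_CAP = 30.0  # cap on logistic linear predictors (|eta| <= 30)


@dataclass
class IncidenceParams:
    """Logistic incidence part: P(susceptible | x)."""

    gamma0: float
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if not np.isfinite(self.gamma0) or not np.all(np.isfinite(self.gamma)):
            raise ValueError("incidence parameters must be finite")


@dataclass
class LatencyParams:
    """Weibull proportional-hazards latency part for susceptible subjects.

    Hazard: lambda_e * nu_e * t**(nu_e - 1) * exp(beta_e' x).
    """

    lambda_e: float
    nu_e: float
    beta_e: np.ndarray

    def __post_init__(self) -> None:
        self.beta_e = np.atleast_1d(np.asarray(self.beta_e, dtype=float))
        if self.lambda_e <= 0 or self.nu_e <= 0:
            raise ValueError("Weibull scale and shape must be positive")


@dataclass
class CureModelFit:
    """Result of the EM fit, with per-subject posterior weights."""

    incidence: IncidenceParams
    latency: LatencyParams
    posterior_weights: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]


def covariate_columns(data: pd.DataFrame) -> list[str]:
    """Names of the baseline-covariate columns x1..xg, in index order."""
    cols = [c for c in data.columns if c.startswith("x") and c[1:].isdigit()]
    return sorted(cols, key=lambda c: int(c[1:]))


def _xmat(data: pd.DataFrame) -> np.ndarray:
    return data[covariate_columns(data)].to_numpy(dtype=float)


def _eta(inc: IncidenceParams, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != inc.gamma.size:
        raise ValueError(
            f"covariate dimension {X.shape[1]} != gamma dimension {inc.gamma.size}"
        )
    return inc.gamma0 + X @ inc.gamma


def incidence_probability(inc: IncidenceParams, x: np.ndarray) -> np.ndarray | float:
    """Susceptible probability pi(x) = expit(gamma0 + gamma' x)."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    eta = _eta(inc, x)
    out = 1.0 / (1.0 + np.exp(-np.clip(eta, -_LP_CAP * 25, _LP_CAP * 25)))
    return float(out[0]) if scalar else out


def _latency_logsurv(lat: LatencyParams, t: np.ndarray, X: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != lat.beta_e.size:
        raise ValueError("covariate dimension mismatch in latency part")
    return -lat.lambda_e * np.power(t, lat.nu_e) * np.exp(X @ lat.beta_e)


def latency_survival(lat: LatencyParams, t, x) -> np.ndarray | float:
    """Susceptible-subject survival S(t | s=1, x) of the Weibull-PH latency."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    scalar = t.ndim == 0 and x.ndim == 1
    out = np.exp(_latency_logsurv(lat, np.atleast_1d(t), x))
    return float(out[0]) if scalar else out


def latency_density(lat: LatencyParams, t, x) -> np.ndarray | float:
    """Density f(t | s=1, x) = lambda nu t^(nu-1) e^(beta'x) S(t | s=1, x)."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    x = np.asarray(x, dtype=float)
    scalar = np.ndim(t) == 0 and x.ndim == 1
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    if lat.nu_e < 1 and np.any(t_arr == 0):
        raise ValueError("density is unbounded at t=0 for Weibull shape < 1")
    X = np.atleast_2d(x)
    lp = X @ lat.beta_e
    with np.errstate(divide="ignore"):
        hazard = lat.lambda_e * lat.nu_e * np.power(t_arr, lat.nu_e - 1.0) * np.exp(lp)
    out = hazard * np.exp(_latency_logsurv(lat, t_arr, X))
    return float(out[0]) if scalar else out


def marginal_intermediate_survival(fit: CureModelFit, t, x) -> np.ndarray | float:
    """Population survival 1 - pi(x) + pi(x) S(t | s=1, x); plateaus at 1-pi."""
    pi = incidence_probability(fit.incidence, x)
    S = latency_survival(fit.latency, t, x)
    return (1.0 - pi) + pi * S


def observed_loglik(
    inc: IncidenceParams, lat: LatencyParams, data: pd.DataFrame
) -> float:
    """Observed-data log-likelihood of the mixture cure model."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    X = _xmat(data)
    t = data["t_e"].to_numpy(dtype=float)
    d = data["delta_e"].to_numpy(dtype=int)
    pi = np.clip(
        1.0 / (1.0 + np.exp(-np.clip(_eta(inc, X), -700, 700))), _PI_EPS, 1 - _PI_EPS
    )
    logS = _latency_logsurv(lat, t, X)
    S = np.maximum(np.exp(logS), _S_FLOOR)
    ev = d == 1
    ll = np.zeros(len(data))
    if ev.any():
        dens = latency_density_safe(lat, t[ev], X[ev])
        if np.any(dens <= 0):
            raise FloatingPointError("zero latency density at an event time")
        ll[ev] = np.log(pi[ev]) + np.log(dens)
    ll[~ev] = np.log((1.0 - pi[~ev]) + pi[~ev] * S[~ev])
    total = float(np.sum(ll))
    if not np.isfinite(total):
        raise FloatingPointError("nonfinite observed log-likelihood")
    return total


def latency_density_safe(lat: LatencyParams, t: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Vectorised latency density without the nu<1, t=0 domain check."""
    lp = X @ lat.beta_e
    haz = lat.lambda_e * lat.nu_e * np.power(t, lat.nu_e - 1.0) * np.exp(lp)
    return haz * np.exp(_latency_logsurv(lat, t, X))


# ---------------------------------------------------------------------------
# EM machinery
# ---------------------------------------------------------------------------


def _weighted_logistic(
    X: np.ndarray, w: np.ndarray, coef0: np.ndarray, max_iter: int = 50
) -> np.ndarray:
    """IRLS for the fractional-response logistic M-step.

    Maximises sum_i [w_i log pi_i + (1-w_i) log(1-pi_i)] over (gamma0, gamma),
    warm-started at ``coef0``.  Linear predictors are capped to keep the step
    finite under separation (all-events degenerate data).
    """
    Z = np.column_stack([np.ones(len(X)), X])
    coef = coef0.copy()
    for _ in range(max_iter):
        eta = np.clip(Z @ coef, -_LP_CAP, _LP_CAP)
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = Z.T @ (w - p)
        W = np.maximum(p * (1.0 - p), 1e-10)
        H = (Z * W[:, None]).T @ Z
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # dampen absurd steps (separation)
        nrm = np.max(np.abs(step))
        if nrm > 10.0:
            step *= 10.0 / nrm
        coef = coef + step
        if np.max(np.abs(grad)) < 1e-9 or nrm < 1e-10:
            break
    return coef


def _latency_negloglik_grad(theta, t, X, d, w, logt):
    """Weighted Weibull-PH negative log-likelihood and gradient.

    theta = (log lambda, log nu, beta); event terms carry weight 1 (delta=1
    implies w=1), survival terms carry weight w.
    """
    a, b = theta[0], theta[1]
    beta = theta[2:]
    lam, nu = np.exp(a), np.exp(b)
    lp = X @ beta
    tnu = np.exp(nu * logt)
    cumhaz = lam * tnu * np.exp(lp)  # Lambda(t) e^{beta x}
    wch = w * cumhaz
    nev = d.sum()
    ll = (a + b) * nev + (nu - 1.0) * logt[d].sum() + lp[d].sum() - wch.sum()
    g = np.empty_like(theta)
    g[0] = nev - wch.sum()  # d/d loglambda
    g[1] = nev + nu * (logt[d].sum() - (wch * logt).sum())  # d/d lognu
    g[2:] = X[d].sum(axis=0) - X.T @ wch
    return -ll, -g


def _fit_latency(
    t: np.ndarray,
    X: np.ndarray,
    d: np.ndarray,
    w: np.ndarray,
    theta0: np.ndarray,
) -> np.ndarray:
    logt = np.log(np.maximum(t, 1e-300))
    res = optimize.minimize(
        _latency_negloglik_grad,
        theta0,
        args=(t, X, d, w, logt),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9},
    )
    return res.x


def _observed_negloglik_grad(phi, X, t, d, logt):
    """Observed-data negative log-likelihood and analytic gradient.

    phi = (gamma0, gamma, log lambda, log nu, beta).  Used by the direct
    ascent polish that finishes the fit when plain EM stalls on a flat ridge.
    """
    g = X.shape[1]
    eta = np.clip(phi[0] + X @ phi[1 : g + 1], -700, 700)
    a, b = phi[g + 1], phi[g + 2]
    beta = phi[g + 3 :]
    lam, nu = np.exp(a), np.exp(b)
    pi = np.clip(1.0 / (1.0 + np.exp(-eta)), _PI_EPS, 1 - _PI_EPS)
    lp = X @ beta
    Lam = lam * np.exp(nu * logt + lp)
    S = np.exp(-Lam)
    ev = d.astype(bool)
    ll = np.where(
        ev,
        np.log(pi) + a + b + (nu - 1.0) * logt + lp - Lam,
        np.log(np.maximum(1.0 - pi + pi * S, 1e-300)),
    ).sum()
    D = np.maximum(1.0 - pi + pi * S, 1e-300)
    g_eta = np.where(ev, 1.0 - pi, pi * (1.0 - pi) * (S - 1.0) / D)
    g_a = np.where(ev, 1.0 - Lam, -pi * S * Lam / D)
    g_b = np.where(ev, 1.0 + nu * logt * (1.0 - Lam), -pi * S * Lam * nu * logt / D)
    grad = np.empty_like(phi)
    grad[0] = g_eta.sum()
    grad[1 : g + 1] = X.T @ g_eta
    grad[g + 1] = g_a.sum()
    grad[g + 2] = g_b.sum()
    grad[g + 3 :] = X.T @ np.where(ev, 1.0 - Lam, -pi * S * Lam / D)
    return -ll, -grad


def fit_mixture_cure(
    data: pd.DataFrame,
    init: tuple[IncidenceParams, LatencyParams] | None = None,
    tol: float = 1e-7,
    max_iter: int = 500,
    polish: bool = True,
) -> CureModelFit:
    """Fit the logistic--Weibull mixture cure model by EM.

    Parameters
    ----------
    data
        Subject table with columns ``x1..xg``, ``t_e``, ``delta_e``.
    init
        Optional warm start; by default the incidence part is initialised by
        an unweighted logistic fit of ``delta_e`` on x and the latency part by
        a Weibull-PH fit treating every censored subject as latency-censored.
    tol
        Convergence: relative change of the observed log-likelihood.
    max_iter
        Maximum EM iterations; non-convergence returns ``converged=False``
        with a warning.
    """
    X = _xmat(data)
    t = data["t_e"].to_numpy(dtype=float)
    d = data["delta_e"].to_numpy(dtype=int).astype(bool)
    n, g = X.shape
    if d.sum() == 0:
        raise ValueError("no observed intermediate events: cure model unidentifiable")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < g + 1:
        raise ValueError("covariate matrix is rank deficient")

    if init is not None:
        inc, lat = init
        coef = np.concatenate([[inc.gamma0], inc.gamma])
        theta = np.concatenate([[np.log(lat.lambda_e), np.log(lat.nu_e)], lat.beta_e])
    else:
        coef = _weighted_logistic(X, d.astype(float), np.zeros(g + 1))
        # crude exponential-rate warm start: events per unit person-time
        rate0 = max(d.sum() / max(t.sum(), 1e-12), 1e-8)
        theta = _fit_latency(
            t, X, d, np.ones(n), np.concatenate([[np.log(rate0), 0.0], np.zeros(g)])
        )

    trace: list[float] = []
    w = np.ones(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        inc = IncidenceParams(coef[0], coef[1:])
        lat = LatencyParams(np.exp(theta[0]), np.exp(theta[1]), theta[2:])
        # E-step
        pi = np.clip(
            1.0 / (1.0 + np.exp(-np.clip(_eta(inc, X), -700, 700))),
            _PI_EPS,
            1 - _PI_EPS,
        )
        S = np.maximum(np.exp(_latency_logsurv(lat, t, X)), _S_FLOOR)
        w = np.where(d, 1.0, pi * S / (1.0 - pi + pi * S))
        ll = observed_loglik(inc, lat, data)
        trace.append(ll)
        if len(trace) > 1:
            rel = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-12)
            if rel < tol:
                converged = True
                break
            if polish and rel < 100 * tol:
                break  # EM is crawling along a flat ridge: hand over to polish
        # M-step (warm-started)
        coef = _weighted_logistic(X, w, coef, max_iter=25)
        theta = _fit_latency(t, X, d, w, theta)

    if not converged and polish:
        # Direct quasi-Newton ascent of the observed log-likelihood from the
        # last EM iterate; EM guarantees monotone approach, the polish
        # finishes the climb that plain EM takes thousands of iterations for.
        logt = np.log(np.maximum(t, 1e-300))
        phi0 = np.concatenate([coef, theta])
        res = optimize.minimize(
            _observed_negloglik_grad,
            phi0,
            args=(X, t, d.astype(int), logt),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-8},
        )
        if np.isfinite(res.fun) and -res.fun >= trace[-1] - 1e-9:
            coef = res.x[: g + 1]
            theta = res.x[g + 1 :]
            ll_polished = -res.fun
            converged = np.max(np.abs(res.jac)) <= 1e-3 * max(1.0, abs(ll_polished))
            trace.append(ll_polished)
            # E-step at the polished parameters so weights match the fit
            inc = IncidenceParams(coef[0], coef[1:])
            lat = LatencyParams(np.exp(theta[0]), np.exp(theta[1]), theta[2:])
            pi = np.clip(
                1.0 / (1.0 + np.exp(-np.clip(_eta(inc, X), -700, 700))),
                _PI_EPS,
                1 - _PI_EPS,
            )
            S = np.maximum(np.exp(_latency_logsurv(lat, t, X)), _S_FLOOR)
            w = np.where(d, 1.0, pi * S / (1.0 - pi + pi * S))
    if not converged:
        warnings.warn(
            f"mixture cure fit did not converge in {max_iter} EM iterations",
            RuntimeWarning,
        )
    inc = IncidenceParams(coef[0], coef[1:])
    lat = LatencyParams(np.exp(theta[0]), np.exp(theta[1]), theta[2:])
    ids = data["id"].to_numpy() if "id" in data.columns else np.arange(n)
    return CureModelFit(
        incidence=inc,
        latency=lat,
        posterior_weights=w,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
        ids=ids,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_subject_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited subject table (id, x1..xg, t_e, delta_e, t_o, delta_o[, s_true])."""
    df = pd.read_csv(path, sep=sep)
    required = {"id", "t_e", "delta_e", "t_o", "delta_o"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    return df


def write_subject_table(data: pd.DataFrame, path, sep: str = "\t") -> None:
    data.to_csv(path, sep=sep, index=False)


def export_fit(fit: CureModelFit) -> str:
    """Key/value text export of the fitted parameters."""
    lines = [f"gamma0\t{fit.incidence.gamma0:.10g}"]
    for j, v in enumerate(fit.incidence.gamma, start=1):
        lines.append(f"gamma{j}\t{v:.10g}")
    lines.append(f"lambda_e\t{fit.latency.lambda_e:.10g}")
    lines.append(f"nu_e\t{fit.latency.nu_e:.10g}")
    for j, v in enumerate(fit.latency.beta_e, start=1):
        lines.append(f"beta_e{j}\t{v:.10g}")
    lines.append(f"loglik\t{fit.loglik_trace[-1]:.10g}")
    lines.append(f"n_iter\t{fit.n_iter}")
    lines.append(f"converged\t{int(fit.converged)}")
    return "\n".join(lines) + "\n"
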
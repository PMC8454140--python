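"""Data-generating process for the intermediate-event / outcome simulation study.

Each subject carries baseline covariates x, a latent susceptibility s ~
Bernoulli(pi(x)) with logistic pi calibrated so E[pi(x)] hits a target
susceptible proportion r, a latent intermediate-event time T_e (susceptible
only, Weibull-PH by inverse-transform), and a latent outcome time T_o.
Insusceptible subjects get a Weibull-PH outcome with attenuated covariate
effects omega*beta; susceptible subjects get an outcome whose hazard is
multiplied by exp(beta_z) from T_e onwards, drawn by the two-branch
piecewise-hazard inversion: with E = -log(u),

    T_o = [E / (lambda e^{beta'x})]^{1/nu}                       if E <  lambda T_e^nu e^{beta'x}
    T_o = [(E - lambda e^{beta'x} T_e^nu) / (lambda e^{beta'x + beta_z})
           + T_e^nu]^{1/nu}                                      otherwise.

Administrative censoring at tau (12 months by default): t_o = min(T_o, tau),
t_e = min(T_e, T_o, tau) with delta_e = 1 iff a susceptible subject's T_e
precedes both; insusceptible subjects are always intermediate-event censored
at C_e = min(T_o, tau).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit, roots_legendre

__all__ = [
    "CovariateScenario",
    "SimulationConfig",
    "scenario",
    "calibrate_gamma0",
    "draw_covariates",
    "draw_susceptibility",
    "draw_intermediate_time",
    "draw_outcome_insusceptible",
    "draw_outcome_susceptible",
    "assemble_dataset",
]

# default Weibull scale per covariate scenario
_SCENARIO_LAMBDA = {"i": 0.005, "ii": 0.0115, "iii": 0.0015}

# per-covariate log hazard ratios: 1.2 for binary, 0.24 for U(0,5), 0.12 for
# U(0,10), so each multiplicative effect exp(beta*x) spans 1..exp(1.2)
_BETA_BY_KIND = {"bern": 1.2, "unif5": 0.24, "unif10": 0.12}


@dataclass(frozen=True)
class CovariateScenario:
    """Covariate layout: a list of ("bern", p) or ("unif", a, b) generators."""

    label: str
    generators: tuple
    beta_per_covariate: tuple

    @property
    def g(self) -> int:
        return len(self.generators)


def scenario(label: str) -> CovariateScenario:
    """The three study covariate scenarios.

    (i)   four Bernoulli covariates, p = 0.1, 0.2, 0.3, 0.5;
    (ii)  Bernoulli(0.3), Bernoulli(0.5), U(0,5), U(0,10);
    (iii) scenario (i) plus U(0,5) and U(0,10).
    """
    b = _BETA_BY_KIND
    if label == "i":
        gens = (("bern", 0.1), ("bern", 0.2), ("bern", 0.3), ("bern", 0.5))
        betas = (b["bern"],) * 4
    elif label == "ii":
        gens = (("bern", 0.3), ("bern", 0.5), ("unif", 0.0, 5.0), ("unif", 0.0, 10.0))
        betas = (b["bern"], b["bern"], b["unif5"], b["unif10"])
    elif label == "iii":
        gens = (
            ("bern", 0.1),
            ("bern", 0.2),
            ("bern", 0.3),
            ("bern", 0.5),
            ("unif", 0.0, 5.0),
            ("unif", 0.0, 10.0),
        )
        betas = (b["bern"],) * 4 + (b["unif5"], b["unif10"])
    else:
        raise ValueError(f"unknown covariate scenario {label!r}")
    return CovariateScenario(label=label, generators=gens, beta_per_covariate=betas)


@dataclass
class SimulationConfig:
    """One simulation scenario; defaults are the study conditions.

    lambda/nu are shared between the intermediate-event and outcome Weibulls
    (lambda_o = lambda_e, nu_o = nu_e); omega attenuates the covariate effect
    on the insusceptible outcome hazard; tau is the administrative censoring
    time in months.
    """

    scenario: CovariateScenario = field(default_factory=lambda: scenario("iii"))
    r: float = 0.5
    gamma: np.ndarray | None = None  # defaults to all ones
    beta_z: float = -1.0
    nu: float = 1.0
    lam: float | None = None  # defaults to the scenario's scale
    omega: float = 0.67
    tau: float = 12.0
    N: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.scenario, str):
            self.scenario = scenario(self.scenario)
        if self.gamma is None:
            self.gamma = np.ones(self.scenario.g)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.lam is None:
            self.lam = _SCENARIO_LAMBDA[self.scenario.label]
        if not (0.0 < self.r < 1.0):
            raise ValueError("susceptible proportion r must be in (0,1)")
        if not (0.0 < self.omega <= 1.0):
            raise ValueError("omega must be in (0,1]")
        if self.lam <= 0 or self.nu <= 0 or self.tau <= 0 or self.N < 1:
            raise ValueError("invalid positivity constraint in config")

    @property
    def beta(self) -> np.ndarray:
        return np.asarray(self.scenario.beta_per_covariate, dtype=float)

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# gamma0 calibration
# ---------------------------------------------------------------------------

_GL_NODES = 64


def _support_grid(sc: CovariateScenario):
    """Exact-mean integration grid: enumerate binary support, Gauss--Legendre
    nodes per uniform covariate; returns (points matrix, weights)."""
    axes_vals, axes_wts = [], []
    for gen in sc.generators:
        if gen[0] == "bern":
            p = gen[1]
            axes_vals.append(np.array([0.0, 1.0]))
            axes_wts.append(np.array([1.0 - p, p]))
        else:
            a, b = gen[1], gen[2]
            nodes, wts = roots_legendre(_GL_NODES)
            axes_vals.append(0.5 * (b - a) * nodes + 0.5 * (a + b))
            axes_wts.append(wts / 2.0)  # normalised to a probability measure
    mesh = np.meshgrid(*axes_vals, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    wmesh = np.meshgrid(*axes_wts, indexing="ij")
    wts = np.prod(np.column_stack([m.ravel() for m in wmesh]), axis=1)
    return pts, wts


def calibrate_gamma0(
    sc: CovariateScenario, gamma: np.ndarray, r: float, tol: float = 1e-6
) -> float:
    """Intercept gamma0 such that E_x[pi(x)] = r under the covariate law.

    E_x[pi] is strictly increasing in gamma0, so root-finding on the exact
    (enumeration + quadrature) mean is well posed; gamma = 0 returns logit(r)
    exactly.
    """
    gamma = np.asarray(gamma, dtype=float)
    if not (0.0 < r < 1.0):
        raise ValueError("r must be in (0,1)")
    if np.all(gamma == 0.0):
        return float(logit(r))
    pts, wts = _support_grid(sc)
    lp = pts @ gamma

    def mean_pi(g0: float) -> float:
        return float(wts @ expit(g0 + lp))

    lo, hi = -50.0, 50.0
    while mean_pi(lo) > r:
        lo *= 2
    while mean_pi(hi) < r:
        hi *= 2
    return float(optimize.brentq(lambda g0: mean_pi(g0) - r, lo, hi, xtol=tol))


_CAL_CACHE: dict = {}


def _calibrate_cached(sc: CovariateScenario, gamma: tuple, r: float) -> float:
    key = (sc.label, gamma, r)
    if key not in _CAL_CACHE:
        _CAL_CACHE[key] = calibrate_gamma0(sc, np.asarray(gamma), r)
    return _CAL_CACHE[key]


# ---------------------------------------------------------------------------
# elementary draws
# ---------------------------------------------------------------------------


def draw_covariates(sc: CovariateScenario, N: int, rng: np.random.Generator) -> np.ndarray:
    """N independent covariate vectors per the scenario's generators."""
    cols = []
    for gen in sc.generators:
        if gen[0] == "bern":
            cols.append((rng.uniform(size=N) < gen[1]).astype(float))
        else:
            cols.append(rng.uniform(gen[1], gen[2], size=N))
    return np.column_stack(cols)


def draw_susceptibility(
    X: np.ndarray, gamma0: float, gamma: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Latent susceptibility s ~ Bernoulli(pi(x)), independent across subjects."""
    pi = expit(gamma0 + X @ np.asarray(gamma, dtype=float))
    return (rng.uniform(size=len(X)) < pi).astype(int)


def _weibull_ph_inverse(E: np.ndarray, lp: np.ndarray, lam: float, nu: float) -> np.ndarray:
    return np.power(E / (lam * np.exp(lp)), 1.0 / nu)


def draw_intermediate_time(
    X: np.ndarray,
    beta_e: np.ndarray,
    lambda_e: float,
    nu_e: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Susceptible intermediate-event times T_e by Weibull-PH inverse transform."""
    u = rng.uniform(size=len(X))
    return _weibull_ph_inverse(-np.log(u), X @ np.asarray(beta_e, float), lambda_e, nu_e)


def draw_outcome_insusceptible(
    X: np.ndarray,
    beta: np.ndarray,
    omega: float,
    lam: float,
    nu: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Insusceptible outcome times: Weibull-PH with attenuated effects omega*beta."""
    u = rng.uniform(size=len(X))
    return _weibull_ph_inverse(
        -np.log(u), omega * (X @ np.asarray(beta, float)), lam, nu
    )


def draw_outcome_susceptible(
    X: np.ndarray,
    T_e: np.ndarray,
    beta: np.ndarray,
    beta_z: float,
    lam: float,
    nu: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Susceptible outcome times under the hazard shift exp(beta_z) at T_e.

    Two-branch inversion of the piecewise cumulative hazard: the pre-switch
    branch applies when the exponential deviate E = -log(u) is exhausted
    before T_e; otherwise the post-switch hazard finishes the inversion.
    Both branches return exactly T_e at the boundary E = lambda T_e^nu
    e^{beta'x}, and at beta_z = 0 they coincide with the plain inversion.
    """
    lp = X @ np.asarray(beta, float)
    E = -np.log(rng.uniform(size=len(X)))
    thresh = lam * np.power(T_e, nu) * np.exp(lp)
    out = np.empty(len(X))
    pre = E < thresh
    out[pre] = np.power(E[pre] / (lam * np.exp(lp[pre])), 1.0 / nu)
    post = ~pre
    out[post] = np.power(
        (E[post] - thresh[post]) / (lam * np.exp(lp[post] + beta_z))
        + np.power(T_e[post], nu),
        1.0 / nu,
    )
    return out


def assemble_dataset(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One complete simulated cohort with observed fields and latent truth.

    Returns a subject table with columns id, x1..xg, t_e, delta_e, t_o,
    delta_o, s_true, plus latent T_e_latent (NaN for the insusceptible) and
    T_o_latent.  Draw order: covariates, susceptibility, T_e, T_o.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sc = config.scenario
    N, tau = config.N, config.tau
    X = draw_covariates(sc, N, rng)
    gamma0 = _calibrate_cached(sc, tuple(config.gamma), config.r)
    s = draw_susceptibility(X, gamma0, config.gamma, rng)
    sus = s == 1

    T_e = np.full(N, np.inf)
    T_e[sus] = draw_intermediate_time(
        X[sus], config.beta, config.lam, config.nu, rng
    )
    T_o = np.empty(N)
    T_o[~sus] = draw_outcome_insusceptible(
        X[~sus], config.beta, config.omega, config.lam, config.nu, rng
    )
    T_o[sus] = draw_outcome_susceptible(
        X[sus], T_e[sus], config.beta, config.beta_z, config.lam, config.nu, rng
    )

    t_o = np.minimum(T_o, tau)
    delta_o = (T_o <= tau).astype(int)
    t_e = np.where(sus, np.minimum.reduce([T_e, T_o, np.full(N, tau)]), t_o)
    delta_e = (sus & (T_e <= np.minimum(T_o, tau))).astype(int)

    df = pd.DataFrame({"id": np.arange(N)})
    for j in range(sc.g):
        df[f"x{j + 1}"] = X[:, j]
    df["t_e"] = t_e
    df["delta_e"] = delta_e
    df["t_o"] = t_o
    df["delta_o"] = delta_o
    df["s_true"] = s
    df["T_e_latent"] = np.where(np.isinf(T_e), np.nan, T_e)
    df["T_o_latent"] = T_o
    return df
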
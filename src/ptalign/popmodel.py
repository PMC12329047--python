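"""Linear ODE model of quiescence-activation-differentiation dynamics.

The population is tracked in three compartments (Q, A, D).  Quiescent cells
activate at rate ``r_act``; active cells divide at rate ``r_div`` (fixed to
1, defining the time unit) with three division outcomes: both daughters
quiescent (self-renewal, probability ``p_self``), both active
(amplification, ``p_amp``), or both differentiated (otherwise);
differentiated cells are lost at rate ``r_death``.  This yields the linear
system d(Q,A,D)/dt = M (Q,A,D) with a Metzler matrix M, so the dominant
eigenvalue is the long-run exponential growth rate and its nonnegative
eigenvector the equilibrium stage composition (Perron-Frobenius).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eig, expm
from scipy.optimize import brentq, minimize

from .align import aitchison_distance

__all__ = [
    "PopulationParams",
    "SimulationResult",
    "build_model_matrix",
    "growth_and_equilibrium",
    "fit_to_composition",
    "simulate_growth",
    "activation_growth_regression",
]


@dataclass(frozen=True)
class PopulationParams:
    """Rates and division-outcome probabilities of the QAD model."""

    r_act: float
    p_self: float
    p_amp: float
    r_death: float
    r_div: float = 1.0

    def __post_init__(self) -> None:
        if min(self.r_act, self.p_self, self.p_amp, self.r_death, self.r_div) < 0:
            raise ValueError("all rates and probabilities must be >= 0")
        if self.p_self + self.p_amp > 1 + 1e-12:
            raise ValueError("p_self + p_amp must be <= 1")


@dataclass
class SimulationResult:
    times: np.ndarray
    states: np.ndarray  # len(times) x 3, nonnegative
    growth_rate: float
    equilibrium: np.ndarray
    tE: float | None  # time of proportion equilibrium
    tD: float | None  # time of reaching detection size


def build_model_matrix(params: PopulationParams) -> np.ndarray:
    """The 3x3 system matrix M with d(Q,A,D)/dt = M (Q,A,D)."""
    r, d = params.r_div, params.r_death
    p_diff = 1.0 - params.p_self - params.p_amp
    return np.array(
        [
            [-params.r_act, 2.0 * params.p_self * r, 0.0],
            [params.r_act, (2.0 * params.p_amp - 1.0) * r, 0.0],
            [0.0, 2.0 * p_diff * r, -d],
        ]
    )


def growth_and_equilibrium(M: np.ndarray) -> tuple[float, np.ndarray]:
    """Dominant eigenvalue (growth rate) and unit-sum equilibrium composition.

    Falls back to long-time simulated proportions if the dominant eigenvector
    is degenerate (e.g. a defective or non-sign-definite eigenspace).
    """
    w, v = eig(M)
    i = int(np.argmax(w.real))
    growth = float(w[i].real)
    vec = v[:, i].real
    if abs(vec.sum()) < 1e-12 or np.any(vec * np.sign(vec.sum()) < -1e-8 * np.abs(vec).max()):
        import warnings

        warnings.warn("degenerate dominant eigenspace; using long-time simulation",
                      stacklevel=2)
        s = expm(M * (50.0 / max(abs(growth), 0.1))) @ np.array([1.0, 1.0, 1.0])
        vec = s
    vec = vec * np.sign(vec.sum())
    vec = np.clip(vec, 0.0, None)
    return growth, vec / vec.sum()


def fit_to_composition(
    observed,
    bounds: dict | None = None,
    n_starts: int = 25,
    seed: int = 0,
    residual_tol: float = 0.05,
) -> tuple[PopulationParams, dict]:
    """Fit model parameters so the equilibrium matches an observed composition.

    Multi-start bounded minimization of the Aitchison distance between the
    model equilibrium and the observed (Q, A, D) composition over
    (r_act, p_self, p_amp, r_death) with r_div pinned to 1.  A 3-part
    composition has two degrees of freedom against four parameters, so the
    fit is a representative, not unique, parameterization; diagnostics
    report the residual, convergence flag, and spread across starts.
    Deterministic given ``seed``.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (3,) or np.any(obs < 0) or not np.isclose(obs.sum(), 1.0, atol=1e-6):
        raise ValueError("observed must be a nonnegative (Q, A, D) composition summing to 1")
    b = {"r_act": (1e-3, 10.0), "p_self": (0.0, 1.0), "p_amp": (0.0, 1.0),
         "r_death": (1e-3, 10.0)}
    if bounds:
        b.update(bounds)
    names = ["r_act", "p_self", "p_amp", "r_death"]
    lo = np.array([b[k][0] for k in names])
    hi = np.array([b[k][1] for k in names])

    def objective(x: np.ndarray) -> float:
        r_act, p_self, p_amp, r_death = x
        excess = p_self + p_amp - 1.0
        if excess > 0:  # smooth penalty keeps L-BFGS-B inside the simplex
            return 10.0 + 100.0 * excess
        params = PopulationParams(r_act, p_self, p_amp, r_death)
        _, eq = growth_and_equilibrium(build_model_matrix(params))
        return aitchison_distance(eq, obs)

    rng = np.random.default_rng(seed)
    best = None
    solutions = []
    for _ in range(n_starts):
        x0 = lo + rng.uniform(size=4) * (hi - lo)
        if x0[1] + x0[2] > 0.95:
            x0[1:3] *= 0.95 / (x0[1] + x0[2])
        res = minimize(objective, x0, method="L-BFGS-B", bounds=list(zip(lo, hi)))
        solutions.append(res)
        if best is None or res.fun < best.fun:
            best = res
    x = best.x
    params = PopulationParams(
        r_act=float(x[0]),
        p_self=float(min(x[1], 1.0 - x[2])),
        p_amp=float(x[2]),
        r_death=float(x[3]),
    )
    near = [s.x for s in solutions if s.fun < best.fun + 1e-3]
    spread = float(np.max(np.ptp(np.vstack(near), axis=0))) if len(near) > 1 else 0.0
    diagnostics = {
        "residual": float(best.fun),
        "converged": bool(best.fun <= residual_tol),
        "n_starts": n_starts,
        "param_spread": spread,
        "multimodal": spread > 0.05,
    }
    return params, diagnostics


def simulate_growth(
    params: PopulationParams,
    initial=(1.0, 0.0, 0.0),
    N_detect: float = 1e11,
    eps_equil: float = 0.01,
    n_grid: int = 400,
) -> SimulationResult:
    """Propagate the population by matrix exponential and extract tE and tD.

    ``tE`` is the first time the total-variation distance of the stage
    proportions to the equilibrium composition drops below ``eps_equil``
    and stays below for the rest of the simulated horizon; ``tD`` solves
    total(t) = ``N_detect`` (None unless the growth rate is positive).
    Matrix-exponential propagation is exact for this linear system.
    """
    M = build_model_matrix(params)
    growth, eq = growth_and_equilibrium(M)
    x0 = np.asarray(initial, dtype=float)
    if np.any(x0 < 0) or x0.sum() <= 0:
        raise ValueError("initial state must be nonnegative with positive total")

    tD = None
    if growth > 0:
        # bracket the detection time along the dominant growth
        t_hi = max(np.log(N_detect / x0.sum()) / growth * 2.0, 1.0)
        total = lambda t: (expm(M * t) @ x0).sum()  # noqa: E731
        while total(t_hi) < N_detect:
            t_hi *= 2.0
        tD = float(brentq(lambda t: np.log(total(t)) - np.log(N_detect), 0.0, t_hi))
        horizon = tD
    else:
        horizon = 50.0 / max(abs(growth), 0.1)

    times = np.linspace(0.0, horizon, n_grid)
    states = np.vstack([expm(M * t) @ x0 for t in times])
    totals = states.sum(axis=1)
    props = states / totals[:, None]
    tv = 0.5 * np.abs(props - eq).sum(axis=1)

    below = tv < eps_equil
    tE = None
    # earliest time after which TV stays below eps_equil
    stays = np.flip(np.logical_and.accumulate(np.flip(below)))
    idx = np.flatnonzero(stays)
    if idx.size:
        tE = float(times[idx[0]])
    return SimulationResult(
        times=times,
        states=states,
        growth_rate=growth,
        equilibrium=eq,
        tE=tE,
        tD=tD,
    )


def activation_growth_regression(cohort, z_threshold: float = 2.0) -> dict:
    """Regress cohort growth rates on log activation rate.

    ``cohort`` is a sequence of (r_act, growth_rate) pairs.  Returns the
    R-squared of the logarithmic fit, per-tumor residuals, and flags for
    tumors whose residual z-score exceeds ``z_threshold`` (candidates for
    compensation through other parameters, e.g. self-renewal).
    """
    arr = np.asarray(cohort, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (r_act, growth_rate) pairs")
    r_act, growth = arr[:, 0], arr[:, 1]
    if np.any(r_act <= 0):
        raise ValueError("activation rates must be positive for the logarithmic fit")
    x = np.log(r_act)
    if np.ptp(x) == 0:
        raise ValueError("constant activation rate; logarithmic fit undefined")
    import statsmodels.api as sm

    fit = sm.OLS(growth, sm.add_constant(x)).fit()
    resid = np.asarray(fit.resid)
    z = (resid - resid.mean()) / resid.std() if resid.std() > 0 else np.zeros_like(resid)
    return {
        "r_squared": float(fit.rsquared),
        "intercept": float(fit.params[0]),
        "slope": float(fit.params[1]),
        "residuals": resid,
        "high_residual": np.abs(z) > z_threshold,
    }
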
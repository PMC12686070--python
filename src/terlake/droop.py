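"""Flexible-quota (Droop) variant of the algal physiology.

Growth depends on internal cell quotas rather than external concentrations:

    mu      = mu_max_inf * min_X(1 - q_min_X / Q_X) * f_I
    v_X     = v_max_X * X/(m_X + X) * clip((q_max_X - Q_X)/(q_max_X - q_min_X), 0, 1)
    dQ_X/dt = v_X - mu * Q_X
    dA/dt   = (mu - a) * A
    dX/dt   = a * (X_in - X) - v_X * A

Uptake is down-regulated linearly as the quota approaches its maximum, so
quotas stay in [q_min, q_max]. In the rigid limit (q_max -> q_min -> c_X
with fast uptake and large mu_max_inf) steady states approach the
fixed-quota model's.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InvalidParameterError, NumericalFailureError
from .model import RATE_EPS, SteadyState, light_limitation
from .params import WASHOUT_BIOMASS, ModelParams, ModelState, Supply

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DroopParams:
    """Fixed-quota parameters plus quota-dynamics constants.

    ``base.c_N/c_P`` are not used by the variant dynamics (quotas are state
    variables) but remain available for comparison runs.
    """

    base: ModelParams
    mu_max_inf: float = 2.0
    q_min_N: float = 0.0542
    q_min_P: float = 0.0075
    q_max_N: float = 0.2168
    q_max_P: float = 0.03
    v_max_N: float = 0.06
    v_max_P: float = 0.009

    def __post_init__(self) -> None:
        for name in (
            "mu_max_inf", "q_min_N", "q_min_P", "q_max_N", "q_max_P", "v_max_N", "v_max_P",
        ):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if self.q_max_N <= self.q_min_N or self.q_max_P <= self.q_min_P:
            raise InvalidParameterError("q_max must exceed q_min for both nutrients")


def rigid_droop_params(params: ModelParams, slack: float = 0.05, rate_factor: float = 10.0) -> DroopParams:
    """Droop parameterization approximating the fixed-quota model.

    Quota bounds are pinched to within ``slack`` of the fixed quotas and
    maximum rates inflated by ``rate_factor`` so quota dynamics are fast and
    nearly rigid.
    """
    return DroopParams(
        base=params,
        mu_max_inf=rate_factor * params.mu_max,
        q_min_N=(1 - slack) * params.c_N,
        q_min_P=(1 - slack) * params.c_P,
        q_max_N=(1 + slack) * params.c_N,
        q_max_P=(1 + slack) * params.c_P,
        v_max_N=rate_factor * params.a * params.c_N,
        v_max_P=rate_factor * params.a * params.c_P,
    )


def _uptake(conc: float, v_max: float, halfsat: float, q: float, q_min: float, q_max: float) -> float:
    regulation = min(max((q_max - q) / (q_max - q_min), 0.0), 1.0)
    return v_max * conc / (halfsat + conc) * regulation


def droop_rhs(
    y: np.ndarray, dp: DroopParams, supply: Supply
) -> np.ndarray:
    """Derivatives of the extended state (A, N, P, Q_N, Q_P)."""
    A, N, P, q_N, q_P = np.clip(y, 0.0, None)
    p = dp.base
    f_I = light_limitation(A, p)
    f_qN = max(0.0, 1.0 - dp.q_min_N / max(q_N, dp.q_min_N * 1e-9))
    f_qP = max(0.0, 1.0 - dp.q_min_P / max(q_P, dp.q_min_P * 1e-9))
    mu = dp.mu_max_inf * min(f_qN, f_qP) * f_I
    v_N = _uptake(N, dp.v_max_N, p.m_N, q_N, dp.q_min_N, dp.q_max_N)
    v_P = _uptake(P, dp.v_max_P, p.m_P, q_P, dp.q_min_P, dp.q_max_P)
    out = np.array(
        [
            (mu - p.a) * A,
            p.a * (supply.N_in - N) - v_N * A,
            p.a * (supply.P_in - P) - v_P * A,
            v_N - mu * q_N,
            v_P - mu * q_P,
        ]
    )
    if not np.all(np.isfinite(out)):
        name = ["dA/dt", "dN/dt", "dP/dt", "dQ_N/dt", "dQ_P/dt"][int(np.argmax(~np.isfinite(out)))]
        raise NumericalFailureError(f"non-finite derivative in term {name}")
    return out


def solve_droop_steady_state(
    dp: DroopParams,
    supply: Supply,
    t_max: float = 4000.0,
    tol: float = 1e-6,
) -> SteadyState:
    """Integrate the Droop variant to steady state (chunked LSODA, rate criterion).

    Returns the shared SteadyState container: the nutrient limitation slots
    hold the quota-based factors (1 - q_min/Q) and ``mu`` the realized rate;
    at a persistent steady state ``v_X = mu * Q_X`` for both nutrients.
    """
    if t_max < 500:
        raise InvalidParameterError(f"t_max must be >= 500 d, got {t_max!r}")
    if not 0 < tol <= 1e-3:
        raise InvalidParameterError(f"tol must lie in (0, 1e-3], got {tol!r}")
    p = dp.base

    def fun(_t: float, y: np.ndarray) -> np.ndarray:
        return droop_rhs(y, dp, supply)

    y = np.array(
        [1.0, supply.N_in, supply.P_in, 0.5 * (dp.q_min_N + dp.q_max_N), 0.5 * (dp.q_min_P + dp.q_max_P)]
    )
    t, chunk, converged = 0.0, 250.0, False
    while t < t_max:
        t_end = min(t + chunk, t_max)
        sol = solve_ivp(fun, (t, t_end), y, method="LSODA", rtol=1e-8, atol=1e-12)
        if not sol.success:
            raise NumericalFailureError(f"Droop integrator failed at t={t:.1f}: {sol.message}")
        y = np.clip(sol.y[:, -1], 0.0, None)
        for i, (q, q_min) in enumerate(((y[3], dp.q_min_N), (y[4], dp.q_min_P)), start=3):
            if q < q_min:
                logger.warning("quota state %d fell below q_min (%.3g < %.3g); clipped", i, q, q_min)
                y[i] = q_min
        t = t_end
        derivs = droop_rhs(y, dp, supply)
        if max(abs(d) / (abs(v) + RATE_EPS) for d, v in zip(derivs, y)) < tol:
            converged = True
            break
    if not converged:
        logger.warning("Droop steady-state solve did not converge by t_max=%.0f d", t_max)

    A, N, P, q_N, q_P = y
    f_I = light_limitation(A, p)
    f_qN = max(0.0, 1.0 - dp.q_min_N / max(q_N, dp.q_min_N * 1e-9))
    f_qP = max(0.0, 1.0 - dp.q_min_P / max(q_P, dp.q_min_P * 1e-9))
    mu = dp.mu_max_inf * min(f_qN, f_qP) * f_I
    washout = A < WASHOUT_BIOMASS
    limiter = ("N", "P")[int(f_qP < f_qN)] if min(f_qN, f_qP) * 1.0 <= f_I else "light"
    gpp = 0.0 if washout else mu * A * p.o2_per_c / 1000.0
    return SteadyState(
        state=ModelState(A, N, P),
        f_N=f_qN,
        f_P=f_qP,
        f_I=f_I,
        limiter=limiter,
        mu=mu,
        gpp=gpp,
        converged=converged,
        washout=washout,
    )
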
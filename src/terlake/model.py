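"""Lake ecosystem ODE core: Liebig-minimum chemostat with algal self-shading.

The model tracks algal carbon ``A`` and dissolved nutrients ``N`` and ``P``
in a mixed layer flushed at dilution rate ``a``:

    dA/dt = (mu - a) * A,          mu = mu_max * min(f_N, f_P, f_I)
    dN/dt = a * (N_in - N) - c_N * mu * A
    dP/dt = a * (P_in - P) - c_P * mu * A

with Monod nutrient limitation factors and a depth-averaged saturating
light factor that decreases with biomass (self-shading).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InvalidParameterError, NumericalFailureError
from .params import WASHOUT_BIOMASS, ModelParams, ModelState, Supply

logger = logging.getLogger(__name__)

#: Scale floor used in the relative-rate convergence criterion.
RATE_EPS = 1e-6

#: Limitation-factor labels in fixed tie-break order.
LIMITER_ORDER = ("N", "P", "light")


@dataclass(frozen=True)
class SteadyState:
    """Converged model state plus derived physiological/ecosystem quantities.

    ``gpp`` is volumetric gross primary production in mg O2 L^-1 d^-1;
    ``mu`` is the realized specific growth rate (equals the dilution rate
    at any persistent steady state).
    """

    state: ModelState
    f_N: float
    f_P: float
    f_I: float
    limiter: str
    mu: float
    gpp: float
    converged: bool
    washout: bool


def monod(conc: float, halfsat: float) -> float:
    """Saturating limitation term ``conc / (halfsat + conc)``.

    Strictly increasing in ``conc``, 0 at zero concentration, 0.5 at the
    half-saturation constant, approaching 1 as ``conc`` grows.
    """
    if not halfsat > 0:
        raise InvalidParameterError(f"halfsat must be positive, got {halfsat!r}")
    if conc < 0:
        raise InvalidParameterError(f"conc must be non-negative, got {conc!r}")
    return conc / (halfsat + conc)


def light_limitation(A: float, params: ModelParams) -> float:
    """Depth-averaged light limitation factor in (0, 1].

    Irradiance decays as ``I(z) = I_in * exp(-k z)`` with total attenuation
    ``k = k_bg + k_A * A``; averaging the Monod factor ``I/(h_I + I)`` over
    the mixed layer gives the closed form

        f_I = 1/(k z_max) * ln((h_I + I_in) / (h_I + I_z)),

    where ``I_z`` is irradiance at ``z_max``. Strictly decreasing in ``A``.
    """
    if A < 0:
        raise InvalidParameterError(f"A must be non-negative, got {A!r}")
    k = params.k_bg + params.k_A * A
    kz = k * params.z_max
    I_z = params.I_in * math.exp(-kz)
    return math.log((params.h_I + params.I_in) / (params.h_I + I_z)) / kz


def growth_factors(
    state: ModelState, params: ModelParams
) -> tuple[float, float, float, str]:
    """Return ``(f_N, f_P, f_I, limiter)`` at a state.

    The limiter is the argmin of the three factors; exact ties resolve in
    the fixed order N < P < light.
    """
    f_N = monod(state.N, params.m_N)
    f_P = monod(state.P, params.m_P)
    f_I = light_limitation(state.A, params)
    limiter = LIMITER_ORDER[int(np.argmin([f_N, f_P, f_I]))]
    return f_N, f_P, f_I, limiter


def rhs(
    state: ModelState, params: ModelParams, supply: Supply
) -> tuple[float, float, float]:
    """Time derivatives ``(dA/dt, dN/dt, dP/dt)`` of the lake model."""
    f_N, f_P, f_I, _ = growth_factors(state, params)
    mu = params.mu_max * min(f_N, f_P, f_I)
    dA = (mu - params.a) * state.A
    dN = params.a * (supply.N_in - state.N) - params.c_N * mu * state.A
    dP = params.a * (supply.P_in - state.P) - params.c_P * mu * state.A
    for name, value in (("dA/dt", dA), ("dN/dt", dN), ("dP/dt", dP)):
        if not math.isfinite(value):
            raise NumericalFailureError(f"non-finite derivative in term {name}: {value!r}")
    return dA, dN, dP


def gpp_from_state(ss: SteadyState, params: ModelParams) -> float:
    """Volumetric GPP in mg O2 L^-1 d^-1 from a steady state.

    Gross carbon fixation ``mu * A`` (mg C m^-3 d^-1) converted to oxygen by
    ``o2_per_c`` and to per-litre by 1/1000; exactly zero at washout.
    """
    if ss.washout:
        return 0.0
    return ss.mu * ss.state.A * params.o2_per_c / 1000.0


def _rate_criterion(y: np.ndarray, params: ModelParams, supply: Supply) -> float:
    state = ModelState(*np.clip(y, 0.0, None))
    derivs = rhs(state, params, supply)
    return max(abs(d) / (abs(x) + RATE_EPS) for d, x in zip(derivs, y))


def solve_steady_state(
    params: ModelParams,
    supply: Supply,
    t_max: float = 4000.0,
    tol: float = 1e-6,
) -> SteadyState:
    """Integrate the model to steady state from (A=1, N=N_in, P=P_in).

    Integration uses a stiff-capable method (LSODA, rtol 1e-8 / atol 1e-10,
    robust across the non-smooth Liebig minimum) in chunks, stopping once
    ``max_i |dx_i/dt| / (|x_i| + 1e-6) < tol`` or ``t_max`` is reached. A
    non-converged run is returned flagged (with a logged warning), never
    silently accepted.
    """
    if t_max < 500:
        raise InvalidParameterError(f"t_max must be >= 500 d, got {t_max!r}")
    if not 0 < tol <= 1e-3:
        raise InvalidParameterError(f"tol must lie in (0, 1e-3], got {tol!r}")

    def fun(_t: float, y: np.ndarray) -> list[float]:
        state = ModelState(*np.clip(y, 0.0, None))
        return list(rhs(state, params, supply))

    y = np.array([1.0, supply.N_in, supply.P_in])
    t = 0.0
    chunk = 250.0
    converged = False
    while t < t_max:
        t_end = min(t + chunk, t_max)
        sol = solve_ivp(fun, (t, t_end), y, method="LSODA", rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise NumericalFailureError(f"integrator failed at t={t:.1f}: {sol.message}")
        y = np.clip(sol.y[:, -1], 0.0, None)
        t = t_end
        if _rate_criterion(y, params, supply) < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "steady-state solve did not converge by t_max=%.0f d "
            "(N_in=%.3g, P_in=%.3g); consider a larger t_max",
            t_max,
            supply.N_in,
            supply.P_in,
        )

    state = ModelState(*y)
    washout = state.A < WASHOUT_BIOMASS
    f_N, f_P, f_I, limiter = growth_factors(state, params)
    mu = params.mu_max * min(f_N, f_P, f_I)
    ss = SteadyState(
        state=state,
        f_N=f_N,
        f_P=f_P,
        f_I=f_I,
        limiter=limiter,
        mu=mu,
        gpp=0.0,
        converged=converged,
        washout=washout,
    )
    return dataclasses.replace(ss, gpp=gpp_from_state(ss, params))
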
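"""Supply-gradient experiments and response-curve sweeps.

Experiment 1 crosses nutrient identity (sweep N vs sweep P) with absolute
concentration (low vs high, a 10x scaling), holding the supply molar N:P
range identical across the four scenarios. Experiment 2 perturbs one
parameter at a time (dilution rate, depth, P half-saturation, P quota)
around the low-P scenario.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import CalibrationError, InvalidParameterError, NumericalFailureError
from .model import solve_steady_state
from .params import N_MOLAR_MASS, P_MOLAR_MASS, ModelParams, Supply

logger = logging.getLogger(__name__)

CURVE_COLUMNS = [
    "scenario_id",
    "param_name",
    "param_value",
    "N_in",
    "P_in",
    "molar_NP",
    "A_star",
    "N_star",
    "P_star",
    "mu",
    "f_N",
    "f_P",
    "f_I",
    "limiter",
    "gpp",
    "converged",
]

#: Units for each curve column, written to the CSV's sidecar metadata.
CURVE_UNITS = {
    "scenario_id": "label",
    "param_name": "label (perturbed parameter, empty for experiment-1 scenarios)",
    "param_value": "value of the perturbed parameter (see param_name)",
    "N_in": "mg N m^-3",
    "P_in": "mg P m^-3",
    "molar_NP": "dimensionless molar N:P of the supply",
    "A_star": "mg C m^-3",
    "N_star": "mg N m^-3",
    "P_star": "mg P m^-3",
    "mu": "d^-1",
    "f_N": "dimensionless [0,1]",
    "f_P": "dimensionless [0,1]",
    "f_I": "dimensionless (0,1]",
    "limiter": "one of N, P, light",
    "gpp": "mg O2 L^-1 d^-1",
    "converged": "boolean",
}


def supply_molar_ratio(N_in: float, P_in: float) -> float:
    """Molar N:P ratio of the supply, ``(N_in/14.007) / (P_in/30.974)``."""
    if not N_in > 0 or not P_in > 0:
        raise InvalidParameterError(
            f"N_in and P_in must be strictly positive, got {N_in!r}, {P_in!r}"
        )
    return (N_in / N_MOLAR_MASS) / (P_in / P_MOLAR_MASS)


@dataclass(frozen=True)
class Scenario:
    """One supply-gradient sweep: vary one input over [sweep_lo, sweep_hi]."""

    id: str
    params: ModelParams
    swept: str  # "N_in" or "P_in"
    sweep_lo: float
    sweep_hi: float
    fixed_value: float
    n_points: int = 100
    spacing: str = "log"
    param_name: Optional[str] = None  # perturbed parameter (experiment 2)
    param_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.swept not in ("N_in", "P_in"):
            raise InvalidParameterError(f"swept must be 'N_in' or 'P_in', got {self.swept!r}")
        if not self.sweep_lo < self.sweep_hi:
            raise InvalidParameterError("sweep_lo must be < sweep_hi")
        if self.n_points < 20:
            raise InvalidParameterError(f"n_points must be >= 20, got {self.n_points}")
        if self.spacing != "log":
            raise InvalidParameterError("only log spacing is supported")

    def sweep_values(self) -> np.ndarray:
        return np.geomspace(self.sweep_lo, self.sweep_hi, self.n_points)

    def supply_at(self, value: float) -> Supply:
        if self.swept == "N_in":
            return Supply(N_in=value, P_in=self.fixed_value)
        return Supply(N_in=self.fixed_value, P_in=value)


@dataclass
class ResponseCurve:
    """Steady-state samples along a supply gradient, sorted by molar N:P."""

    scenario_id: str
    data: pd.DataFrame = field(repr=False)

    @property
    def molar_np(self) -> np.ndarray:
        return self.data["molar_NP"].to_numpy()

    @property
    def gpp(self) -> np.ndarray:
        return self.data["gpp"].to_numpy()

    @property
    def mu(self) -> np.ndarray:
        return self.data["mu"].to_numpy()

    @property
    def limiter(self) -> np.ndarray:
        return self.data["limiter"].to_numpy()

    @property
    def converged(self) -> np.ndarray:
        return self.data["converged"].to_numpy(dtype=bool)

    @property
    def washout(self) -> np.ndarray:
        return self.data["washout"].to_numpy(dtype=bool)


# ---------------------------------------------------------------------------
# Experiment builders
# ---------------------------------------------------------------------------

def build_experiment1(params: Optional[ModelParams] = None, n_points: int = 100) -> list[Scenario]:
    """The four supply scenarios crossing nutrient identity and magnitude.

    high_N: N_in 700-14000 at P_in 300; low_N: N_in 70-1400 at P_in 30;
    high_P: P_in 150-2000 at N_in 7000; low_P: P_in 15-200 at N_in 700.
    All four span the same supply molar N:P interval (~5.2 to ~103).
    """
    params = params or ModelParams()
    return [
        Scenario("high_N", params, "N_in", 700.0, 14000.0, 300.0, n_points),
        Scenario("low_N", params, "N_in", 70.0, 1400.0, 30.0, n_points),
        Scenario("high_P", params, "P_in", 150.0, 2000.0, 7000.0, n_points),
        Scenario("low_P", params, "P_in", 15.0, 200.0, 700.0, n_points),
    ]


EXPERIMENT2_VALUES = {
    "a": (0.1, 0.6, 0.7),
    "z_max": (1.0, 2.5, 5.0),
    "m_P": (0.7, 1.5, 3.0),
    "c_P": (0.005, 0.015, 0.025),
}


def build_experiment2(params: Optional[ModelParams] = None, n_points: int = 100) -> list[Scenario]:
    """Twelve single-parameter perturbations of the low-P scenario (3 values x 4 parameters)."""
    params = params or ModelParams()
    low_p = next(s for s in build_experiment1(params, n_points) if s.id == "low_P")
    scenarios = []
    for name, values in EXPERIMENT2_VALUES.items():
        for value in values:
            scenarios.append(
                Scenario(
                    id=f"low_P_{name}={value:g}",
                    params=params.replace(**{name: value}),
                    swept=low_p.swept,
                    sweep_lo=low_p.sweep_lo,
                    sweep_hi=low_p.sweep_hi,
                    fixed_value=low_p.fixed_value,
                    n_points=n_points,
                    param_name=name,
                    param_value=value,
                )
            )
    return scenarios


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

def run_gradient(
    scenario: Scenario,
    t_max: float = 4000.0,
    tol: float = 1e-6,
    variant: str = "fixed_quota",
    droop_params=None,
) -> ResponseCurve:
    """Solve every point of a scenario's sweep and assemble a ResponseCurve.

    Non-converged points are flagged in the ``converged`` column rather than
    dropped; more than 10% of them is treated as a hard error. ``variant``
    selects the fixed-quota core (default) or the flexible-quota Droop
    variant (``droop_params`` optional, derived from the scenario otherwise).
    """
    if variant == "droop":
        from .droop import DroopParams, solve_droop_steady_state

        dp = droop_params if droop_params is not None else DroopParams(base=scenario.params)

        def solve(supply):
            return solve_droop_steady_state(dp, supply, t_max=t_max, tol=tol)

    elif variant == "fixed_quota":

        def solve(supply):
            return solve_steady_state(scenario.params, supply, t_max=t_max, tol=tol)

    else:
        raise InvalidParameterError(f"unknown model variant {variant!r}")

    rows = []
    for value in scenario.sweep_values():
        supply = scenario.supply_at(value)
        ss = solve(supply)
        rows.append(
            {
                "scenario_id": scenario.id,
                "param_name": scenario.param_name or "",
                "param_value": scenario.param_value if scenario.param_value is not None else np.nan,
                "N_in": supply.N_in,
                "P_in": supply.P_in,
                "molar_NP": supply_molar_ratio(supply.N_in, supply.P_in),
                "A_star": ss.state.A,
                "N_star": ss.state.N,
                "P_star": ss.state.P,
                "mu": ss.mu,
                "f_N": ss.f_N,
                "f_P": ss.f_P,
                "f_I": ss.f_I,
                "limiter": ss.limiter,
                "gpp": ss.gpp,
                "converged": ss.converged,
                "washout": ss.washout,
            }
        )
    df = pd.DataFrame(rows).sort_values("molar_NP", ignore_index=True)
    n_bad = int((~df["converged"]).sum())
    if n_bad > 0.1 * len(df):
        raise NumericalFailureError(
            f"{n_bad}/{len(df)} gradient points failed to converge in scenario "
            f"{scenario.id!r}; increase t_max"
        )
    n_limiters = df.loc[df["converged"], "limiter"].value_counts().to_dict()
    logger.info(
        "scenario %s: %d points, %d non-converged, limiter census %s",
        scenario.id,
        len(df),
        n_bad,
        n_limiters,
    )
    return ResponseCurve(scenario_id=scenario.id, data=df)


def calibrate_light(
    params: ModelParams,
    scenarios: Optional[list[Scenario]] = None,
    t_max: float = 4000.0,
    tol: float = 1e-6,
) -> ModelParams:
    """Validate that the light parameters produce the intended regime split.

    Checks (i) the low-N and low-P scenarios are nutrient limited at every
    converged point, and (ii) the high-N and high-P scenarios are light
    limited over at least 90% of converged points. Raises CalibrationError
    naming the offending scenario and points otherwise; returns ``params``
    unchanged on success.
    """
    scenarios = scenarios if scenarios is not None else build_experiment1(params)
    by_id = {s.id: s for s in scenarios}
    curves = {
        sid: run_gradient(by_id[sid], t_max=t_max, tol=tol)
        for sid in ("low_N", "low_P", "high_N", "high_P")
    }
    check_light_regimes(curves)
    return params


def check_light_regimes(curves: dict[str, ResponseCurve]) -> None:
    """Regime checks behind :func:`calibrate_light`, on precomputed curves."""
    for sid in ("low_N", "low_P"):
        curve = curves[sid]
        mask = curve.converged & (curve.limiter == "light")
        if mask.any():
            ratios = curve.molar_np[mask]
            raise CalibrationError(
                f"condition (i) violated: scenario {sid!r} is light limited at "
                f"{int(mask.sum())} point(s), molar N:P in "
                f"[{ratios.min():.3g}, {ratios.max():.3g}]"
            )
    for sid in ("high_N", "high_P"):
        curve = curves[sid]
        conv = curve.converged
        if conv.sum() == 0:
            raise CalibrationError(f"condition (ii) violated: no converged points in {sid!r}")
        frac_light = (curve.limiter[conv] == "light").mean()
        if frac_light < 0.9:
            raise CalibrationError(
                f"condition (ii) violated: scenario {sid!r} light limited over only "
                f"{100 * frac_light:.1f}% of points (>= 90% required)"
            )
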
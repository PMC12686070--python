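"""Threshold localization and response-shape classification.

A response curve (typically GPP vs supply molar N:P) is fitted on a
log10-transformed ratio axis with five candidate shapes — flat, linear,
saturating, hinge (continuous two-segment linear) and four-parameter
logistic — ranked by small-sample-corrected AIC. A threshold x/y location
is reported for the breakpoint shapes (hinge: the join point; logistic:
the inflection abscissa), always back-transformed to the natural ratio
scale. The mechanistic nutrient-limitation switch (f_N = f_P at steady
state) is located independently by bisection on the supply gradient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .errors import InsufficientDataError, InvalidParameterError, NumericalFailureError
from .model import solve_steady_state
from .scenarios import ResponseCurve, Scenario, supply_molar_ratio

logger = logging.getLogger(__name__)

SHAPES = ("flat", "linear", "saturating", "hinge", "logistic")

#: Number of free parameters per candidate shape.
SHAPE_NPARAMS = {"flat": 1, "linear": 2, "saturating": 3, "hinge": 4, "logistic": 4}

#: Shapes for which a threshold x location is defined.
THRESHOLD_SHAPES = ("hinge", "logistic")

#: Default AICc margin a complex model must clear over a simpler one.
SELECTION_MARGIN = 2.0

#: Breakpoint candidates confined to the central fraction of the x-range.
PSI_INNER_FRACTION = 0.90

#: A response spanning less than this fraction of its own magnitude across
#: the whole gradient is treated as flat outright (an essentially noiseless
#: but numerically jittery curve would otherwise let a breakpoint shape
#: "explain" sub-percent solver artifacts).
FLAT_RELATIVE_SPAN = 0.05


@dataclass(frozen=True)
class HingeFit:
    """Continuous two-segment linear fit y = b0 + b1*x + b2*max(0, x - psi)."""

    psi: float
    b0: float
    b1: float
    b2: float
    rss: float
    degenerate: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.b0 + self.b1 * x + self.b2 * np.maximum(0.0, x - self.psi)

    @property
    def slope_below(self) -> float:
        return self.b1

    @property
    def slope_above(self) -> float:
        return self.b1 + self.b2


@dataclass(frozen=True)
class ShapeFit:
    """One candidate shape fitted to (x, y): parameters, RSS and predictor."""

    shape: str
    params: tuple[float, ...]
    rss: float
    n_params: int
    predict: Callable[[np.ndarray], np.ndarray] = field(compare=False)
    detail: Optional[HingeFit] = None


@dataclass(frozen=True)
class Classification:
    shape: str
    scores: dict[str, float]
    delta_best: float
    fits: dict[str, ShapeFit]


@dataclass
class ThresholdEstimate:
    """Threshold location and characterization for one response curve.

    ``x_ter`` is on the natural molar N:P scale (None when the winning
    shape has no defined threshold); slopes are response change per unit
    log10(N:P).
    """

    x_ter: Optional[float]
    y_ter: Optional[float]
    shape: str
    scores: dict[str, float]
    delta_best: float
    slope_below: Optional[float]
    slope_above: Optional[float]
    mech_switch_x: Optional[float] = None

    @property
    def has_threshold(self) -> bool:
        return self.x_ter is not None

    def to_dict(self) -> dict:
        return {
            "x_ter": self.x_ter,
            "y_ter": self.y_ter,
            "shape": self.shape,
            "scores": {k: (None if not math.isfinite(v) else v) for k, v in self.scores.items()},
            "delta_best": self.delta_best,
            "slope_below": self.slope_below,
            "slope_above": self.slope_above,
            "mech_switch_x": self.mech_switch_x,
        }


# ---------------------------------------------------------------------------
# Hinge fit
# ---------------------------------------------------------------------------

def _hinge_rss_at(psi: float, x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    design = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - psi)])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), coef


def fit_hinge(
    x: Sequence[float],
    y: Sequence[float],
    n_grid: int = 201,
    inner_fraction: float = PSI_INNER_FRACTION,
) -> HingeFit:
    """Profile the breakpoint of a continuous two-segment linear model.

    The breakpoint psi is profiled over ``n_grid`` candidates confined to
    the central ``inner_fraction`` of the x-range (boundary breakpoints are
    unidentifiable), then refined by bounded golden-section search between
    the neighbours of the best grid candidate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise InvalidParameterError("x and y must be 1-D arrays of equal length")
    if len(x) < 8 or not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise InsufficientDataError(f"need >= 8 finite points, got {len(x)}")
    if not np.all(np.diff(x) > 0):
        raise InvalidParameterError("x must be strictly increasing")

    margin = (1.0 - inner_fraction) / 2.0
    span = x[-1] - x[0]
    lo, hi = x[0] + margin * span, x[-1] - margin * span
    grid = np.linspace(lo, hi, n_grid)
    rss_grid = np.array([_hinge_rss_at(p, x, y)[0] for p in grid])
    i_best = int(np.argmin(rss_grid))

    bracket_lo = grid[max(i_best - 1, 0)]
    bracket_hi = grid[min(i_best + 1, n_grid - 1)]
    if bracket_hi > bracket_lo:
        res = minimize_scalar(
            lambda p: _hinge_rss_at(p, x, y)[0],
            bounds=(bracket_lo, bracket_hi),
            method="bounded",
            options={"xatol": 1e-8 * max(span, 1.0)},
        )
        psi = float(res.x)
        if res.fun > rss_grid[i_best]:  # pragma: no cover - safety net
            psi = float(grid[i_best])
    else:
        psi = float(grid[i_best])

    rss, coef = _hinge_rss_at(psi, x, y)
    y_scale = float(np.var(y)) * len(y)
    degenerate = abs(coef[2]) * span < 1e-8 * (abs(coef[1]) * span + math.sqrt(max(y_scale, 1e-300)) + 1e-12)
    return HingeFit(psi=psi, b0=float(coef[0]), b1=float(coef[1]), b2=float(coef[2]), rss=rss, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Candidate shapes
# ---------------------------------------------------------------------------

def _fit_flat(x: np.ndarray, y: np.ndarray) -> ShapeFit:
    c = float(np.mean(y))
    resid = y - c
    return ShapeFit("flat", (c,), float(resid @ resid), 1, lambda t: np.full_like(np.asarray(t, float), c))


def _fit_linear(x: np.ndarray, y: np.ndarray) -> ShapeFit:
    b1, b0 = np.polyfit(x, y, 1)
    pred = b0 + b1 * x
    rss = float(np.sum((y - pred) ** 2))
    return ShapeFit("linear", (b0, b1), rss, 2, lambda t, b0=b0, b1=b1: b0 + b1 * np.asarray(t, float))


def _fit_saturating(x: np.ndarray, y: np.ndarray) -> ShapeFit:
    """Michaelis-Menten-type fit on the natural ratio scale: y = b + d*r/(K + r)."""
    r = 10.0 ** x

    def model(theta: np.ndarray, rr: np.ndarray) -> np.ndarray:
        b, d, log_k = theta
        return b + d * rr / (10.0 ** log_k + rr)

    y_span = float(y.max() - y.min()) or 1.0
    best = None
    for log_k0 in np.linspace(x[0], x[-1], 5):
        theta0 = np.array([float(y[0]), float(y[-1] - y[0]) or y_span, log_k0])
        try:
            res = least_squares(lambda th: model(th, r) - y, theta0, method="lm", max_nfev=2000)
        except Exception:  # pragma: no cover - optimizer edge cases
            continue
        rss = float(res.fun @ res.fun)
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        return ShapeFit("saturating", (), math.inf, 3, lambda t: np.full_like(np.asarray(t, float), np.nan))
    rss, theta = best
    return ShapeFit(
        "saturating",
        tuple(float(v) for v in theta),
        rss,
        3,
        lambda t, th=theta: model(th, 10.0 ** np.asarray(t, float)),
    )


def _logistic(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    lower, upper, x0, log_s = theta
    s = 10.0 ** min(max(log_s, -6.0), 6.0)
    t = np.clip(-(x - x0) / s, -500.0, 500.0)
    return lower + (upper - lower) / (1.0 + np.exp(t))


def _fit_logistic(x: np.ndarray, y: np.ndarray) -> ShapeFit:
    """Symmetric four-parameter logistic in x = log10 ratio; inflection at x0."""
    span = x[-1] - x[0]
    y_lo, y_hi = float(y[0]), float(y[-1])
    starts = []
    for x0 in np.quantile(x, [0.25, 0.5, 0.75]):
        for s_frac in (0.05, 0.15, 0.4):
            starts.append(np.array([y_lo, y_hi, x0, math.log10(s_frac * span)]))
    best = None
    for theta0 in starts:
        try:
            res = least_squares(
                lambda th: _logistic(th, x) - y, theta0, method="lm", max_nfev=4000
            )
        except Exception:  # pragma: no cover
            continue
        rss = float(res.fun @ res.fun)
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        logger.warning("logistic fit failed to converge from all starts")
        return ShapeFit("logistic", (), math.inf, 4, lambda t: np.full_like(np.asarray(t, float), np.nan))
    rss, theta = best
    return ShapeFit(
        "logistic",
        tuple(float(v) for v in theta),
        rss,
        4,
        lambda t, th=theta: _logistic(th, np.asarray(t, float)),
    )


def _fit_hinge_candidate(x: np.ndarray, y: np.ndarray, n_grid: int) -> ShapeFit:
    hf = fit_hinge(x, y, n_grid=n_grid)
    return ShapeFit("hinge", (hf.b0, hf.b1, hf.b2, hf.psi), hf.rss, 4, hf.predict, detail=hf)


def _aicc(rss: float, n: int, n_params: int, y_scale: float) -> float:
    """Small-sample-corrected AIC with Gaussian errors; k counts the variance too.

    RSS is floored at the square of a tiny fraction of the response
    magnitude so that exactly- and near-interpolating fits tie instead of
    ranking on numerical noise.
    """
    k = n_params + 1
    if n - k - 1 <= 0 or not math.isfinite(rss):
        return math.inf
    floor = n * (1e-7 * max(y_scale, 1e-12)) ** 2
    return n * math.log(max(rss, floor) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def classify_response(
    x: Sequence[float],
    y: Sequence[float],
    n_grid: int = 201,
    margin: float = SELECTION_MARGIN,
) -> Classification:
    """Fit all candidate shapes on (log10-axis x, y) and select a winner.

    Candidates are ranked by AICc; the winner is the simplest shape whose
    score lies within ``margin`` of the minimum, so a more complex shape
    must beat every simpler alternative by at least the margin. Breakpoint
    shapes whose threshold lies outside the observed x-range are excluded
    as unidentifiable. Fits that fail score +inf and are logged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise InsufficientDataError(f"need >= 10 points to classify, got {len(x)}")

    fits = {
        "flat": _fit_flat(x, y),
        "linear": _fit_linear(x, y),
        "saturating": _fit_saturating(x, y),
        "hinge": _fit_hinge_candidate(x, y, n_grid),
        "logistic": _fit_logistic(x, y),
    }
    y_scale = float(np.max(np.abs(y))) or 1.0
    scores = {
        name: _aicc(fit.rss, len(x), fit.n_params, y_scale) for name, fit in fits.items()
    }
    if float(np.ptp(y)) <= FLAT_RELATIVE_SPAN * y_scale:
        # Practically flat: the whole response varies by < 5% of its
        # magnitude, so no breakpoint can be ecologically meaningful.
        others = [s for name, s in scores.items() if name != "flat" and math.isfinite(s)]
        delta = max(0.0, min(others) - scores["flat"]) if others else math.inf
        return Classification(shape="flat", scores=scores, delta_best=delta, fits=fits)
    # A breakpoint estimate pinned near or beyond the data boundary is
    # unidentifiable; the same central-90% rule used to profile the hinge
    # breakpoint applies to the logistic inflection.
    edge = (1.0 - PSI_INNER_FRACTION) / 2.0 * (x[-1] - x[0])
    if fits["logistic"].params and not (
        x[0] + edge <= fits["logistic"].params[2] <= x[-1] - edge
    ):
        scores["logistic"] = math.inf
    if fits["hinge"].detail is not None and fits["hinge"].detail.degenerate:
        scores["hinge"] = math.inf

    finite = {name: s for name, s in scores.items() if math.isfinite(s)}
    if not finite:
        raise NumericalFailureError("all candidate shape fits failed")
    best_score = min(finite.values())
    # Simplest shape within the margin wins; ties at equal complexity go to
    # the better score.
    ordered = sorted(finite, key=lambda name: (SHAPE_NPARAMS[name], finite[name]))
    winner = next(name for name in ordered if finite[name] <= best_score + margin)
    others = [s for name, s in finite.items() if name != winner]
    delta_best = max(0.0, min(others) - finite[winner]) if others else math.inf
    return Classification(shape=winner, scores=scores, delta_best=delta_best, fits=fits)


# ---------------------------------------------------------------------------
# Asymmetric sigmoid refinement of the logistic threshold location
# ---------------------------------------------------------------------------

def _richards(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Generalized logistic with inflection exactly at ``m`` for any shape nu.

    ``y = lo + (up - lo) * (1 + nu * exp(-(x - m)/s))**(-1/nu)``; nu = 1
    recovers the symmetric logistic, nu far from 1 lets the bend sit
    asymmetrically between the asymptotes.
    """
    lo, up, m, log_s, log_nu = theta
    s = 10.0 ** min(max(log_s, -6.0), 6.0)
    nu = 10.0 ** min(max(log_nu, -4.0), 4.0)
    t = np.clip(-(x - m) / s, -500.0, 500.0)
    return lo + (up - lo) * (1.0 + nu * np.exp(t)) ** (-1.0 / nu)


def _fit_richards_oriented(x: np.ndarray, y: np.ndarray) -> Optional[tuple[float, float, np.ndarray]]:
    span = x[-1] - x[0]
    best = None
    for m0 in np.quantile(x, [0.25, 0.5, 0.75]):
        for s_frac in (0.05, 0.15, 0.4):
            for log_nu0 in (-1.0, 0.0, 1.0):
                theta0 = np.array([y[0], y[-1], m0, math.log10(s_frac * span), log_nu0])
                try:
                    res = least_squares(
                        lambda th: _richards(th, x) - y, theta0, method="lm", max_nfev=6000
                    )
                except Exception:  # pragma: no cover
                    continue
                rss = float(res.fun @ res.fun)
                if best is None or rss < best[0]:
                    best = (rss, float(res.x[2]), res.x)
    return best


def refine_threshold_location(x: np.ndarray, y: np.ndarray) -> Optional[tuple[float, float]]:
    """Inflection (log10 units) and fitted level of an asymmetric sigmoid.

    Fits the generalized logistic in both orientations (the asymmetry
    parameter only bends one shoulder, so the mirrored data covers the
    other case) and returns ``(u_ter, y_ter)`` from the better fit. For a
    symmetric sigmoid this is exactly the standard logistic inflection;
    for a curve with one sharp shoulder it tracks the bend rather than the
    midpoint of the asymptotes.
    """
    direct = _fit_richards_oriented(x, y)
    mirrored = _fit_richards_oriented(-x[::-1], y[::-1])
    candidates = []
    if direct is not None:
        candidates.append((direct[0], direct[1], direct[2], False))
    if mirrored is not None:
        candidates.append((mirrored[0], -mirrored[1], mirrored[2], True))
    if not candidates:
        return None
    rss, u_ter, theta, flipped = min(candidates, key=lambda c: c[0])
    y_ter = float(_richards(theta, np.array([-u_ter if flipped else u_ter]))[0])
    if not (x[0] <= u_ter <= x[-1]):
        return None
    return u_ter, y_ter


# ---------------------------------------------------------------------------
# Threshold estimation
# ---------------------------------------------------------------------------

def sensitivity_slopes(
    x_ter: float, x: np.ndarray, y: np.ndarray, min_points: int = 4
) -> tuple[Optional[float], Optional[float]]:
    """Least-squares slopes of y vs log10-axis x on each side of the threshold.

    A side with fewer than ``min_points`` points is reported as None.
    """
    u_ter = math.log10(x_ter)
    below = x <= u_ter
    above = ~below
    slopes = []
    for mask in (below, above):
        if mask.sum() >= min_points:
            slopes.append(float(np.polyfit(x[mask], y[mask], 1)[0]))
        else:
            slopes.append(None)
    return slopes[0], slopes[1]


CurveLike = Union[ResponseCurve, tuple]


def detect_threshold(
    x_ratio: Sequence[float],
    y: Sequence[float],
    n_grid: int = 201,
    margin: float = SELECTION_MARGIN,
) -> ThresholdEstimate:
    """Locate and characterize a threshold on (natural-scale ratio, response) data.

    Fits are performed against log10(x_ratio); the returned ``x_ter`` is on
    the natural ratio scale. Shapes without a defined threshold yield an
    estimate with ``x_ter`` absent (not an error).
    """
    x_ratio = np.asarray(x_ratio, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x_ratio <= 0):
        raise InvalidParameterError("ratio axis values must be strictly positive")
    order = np.argsort(x_ratio)
    u = np.log10(x_ratio[order])
    y = y[order]

    cls = classify_response(u, y, n_grid=n_grid, margin=margin)
    fit = cls.fits[cls.shape]
    if cls.shape in THRESHOLD_SHAPES:
        if cls.shape == "hinge":
            u_ter = fit.detail.psi
            y_ter = float(fit.predict(np.array([u_ter]))[0])
        else:
            # The symmetric logistic midpoint misplaces the threshold on
            # curves with one sharp shoulder; refit with an asymmetric
            # sigmoid whose inflection adapts (identical to the symmetric
            # inflection when the curve is symmetric).
            refined = refine_threshold_location(u, y)
            if refined is not None:
                u_ter, y_ter = refined
            else:
                u_ter = fit.params[2]
                y_ter = float(fit.predict(np.array([u_ter]))[0])
        x_ter = 10.0 ** u_ter
        slope_below, slope_above = sensitivity_slopes(x_ter, u, y)
    else:
        x_ter = y_ter = slope_below = slope_above = None
    return ThresholdEstimate(
        x_ter=x_ter,
        y_ter=y_ter,
        shape=cls.shape,
        scores=cls.scores,
        delta_best=cls.delta_best,
        slope_below=slope_below,
        slope_above=slope_above,
    )


def detect_ter(
    curve: ResponseCurve,
    scenario: Optional[Scenario] = None,
    n_grid: int = 201,
    margin: float = SELECTION_MARGIN,
    t_max: float = 4000.0,
    tol: float = 1e-6,
) -> ThresholdEstimate:
    """Threshold estimate for a model response curve (GPP vs supply molar N:P).

    Only converged points enter the fit. When the generating scenario is
    supplied, the mechanistic limitation-switch location is attached.
    """
    mask = curve.converged
    if mask.sum() < 10:
        raise InsufficientDataError(
            f"need >= 10 converged points, got {int(mask.sum())}"
        )
    est = detect_threshold(
        curve.molar_np[mask], curve.gpp[mask], n_grid=n_grid, margin=margin
    )
    if scenario is not None:
        est.mech_switch_x = mechanistic_switch(scenario, t_max=t_max, tol=tol)
    return est


# ---------------------------------------------------------------------------
# Mechanistic switch
# ---------------------------------------------------------------------------

def mechanistic_switch(
    scenario: Scenario,
    t_max: float = 4000.0,
    tol: float = 1e-6,
    max_iter: int = 60,
) -> Optional[float]:
    """Supply molar N:P at which steady-state f_N equals f_P, by bisection.

    Light is excluded from the comparison: the crossing exists (or not)
    regardless of whether self-shading masks it in the GPP response. Returns
    None when f_N - f_P does not change sign along the sweep.
    """

    def gap(value: float) -> float:
        ss = solve_steady_state(scenario.params, scenario.supply_at(value), t_max=t_max, tol=tol)
        return ss.f_N - ss.f_P

    lo, hi = scenario.sweep_lo, scenario.sweep_hi
    probes = np.geomspace(lo, hi, 9)
    gaps = [gap(v) for v in probes]
    bracket = None
    for (v0, g0), (v1, g1) in zip(zip(probes, gaps), zip(probes[1:], gaps[1:])):
        if g0 == 0.0:
            bracket = (v0, v0)
            break
        if g0 * g1 < 0:
            bracket = (v0, v1)
            break
    if bracket is None:
        if gaps[-1] == 0.0:
            bracket = (probes[-1], probes[-1])
        else:
            return None
    v_lo, v_hi = bracket
    if v_lo == v_hi:
        swept_value = v_lo
    else:
        g_lo = gap(v_lo)
        swept_value = None
        for _ in range(max_iter):
            mid = math.sqrt(v_lo * v_hi)
            g_mid = gap(mid)
            if g_mid == 0.0 or (v_hi - v_lo) / mid < 1e-6:
                swept_value = mid
                break
            if g_lo * g_mid < 0:
                v_hi = mid
            else:
                v_lo, g_lo = mid, g_mid
        if swept_value is None:
            swept_value = math.sqrt(v_lo * v_hi)
            if (v_hi - v_lo) / swept_value > 1e-4:
                raise NumericalFailureError(
                    f"bisection for the limitation switch did not converge in {max_iter} iterations"
                )
    supply = scenario.supply_at(swept_value)
    return supply_molar_ratio(supply.N_in, supply.P_in)
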
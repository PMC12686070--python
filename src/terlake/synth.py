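"""Synthetic response curves with known shape, breakpoint and noise.

Used to validate the detection stage without running the lake model: each
generator returns the curve together with its ground truth, and
:func:`recovery_experiment` summarizes detection accuracy over seeded
replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detect import SHAPES, detect_threshold
from .errors import InvalidParameterError

__all__ = ["CurveSpec", "GroundTruth", "gen_curve", "recovery_experiment"]


@dataclass(frozen=True)
class GroundTruth:
    shape: str
    x_ter: Optional[float]
    slope_below: Optional[float]
    slope_above: Optional[float]

    def to_dict(self) -> dict:
        return {
            "shape": self.shape,
            "x_ter": self.x_ter,
            "slope_below": self.slope_below,
            "slope_above": self.slope_above,
        }


@dataclass(frozen=True)
class CurveSpec:
    """Recipe for one synthetic curve.

    ``shape_params`` per shape (u denotes log10 x):
      flat:       level
      linear:     intercept, slope            (y = intercept + slope*u)
      hinge:      intercept, slope1, slope2, psi  (break at u = psi)
      logistic:   lower, upper, x0, scale     (inflection at u = x0)
      saturating: base, amplitude, half_x     (y = base + amplitude*x/(half_x+x))
    """

    shape: str
    shape_params: dict = field(default_factory=dict)
    x_lo: float = 2.0
    x_hi: float = 120.0
    n_points: int = 40
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise InvalidParameterError(f"unknown shape {self.shape!r}; choose from {SHAPES}")
        if not 0 < self.x_lo < self.x_hi:
            raise InvalidParameterError("need 0 < x_lo < x_hi")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be >= 0")
        for key, value in self.shape_params.items():
            if not math.isfinite(value):
                raise InvalidParameterError(f"shape parameter {key}={value!r} is not finite")


def _true_response(spec: CurveSpec, u: np.ndarray) -> np.ndarray:
    p = spec.shape_params
    if spec.shape == "flat":
        return np.full_like(u, p.get("level", 1.0))
    if spec.shape == "linear":
        return p.get("intercept", 0.0) + p.get("slope", 1.0) * u
    if spec.shape == "hinge":
        s1, s2 = p.get("slope1", 2.0), p.get("slope2", 0.0)
        psi = p.get("psi", math.log10(16.0))
        return p.get("intercept", 0.0) + s1 * u + (s2 - s1) * np.maximum(0.0, u - psi)
    if spec.shape == "logistic":
        lower, upper = p.get("lower", 0.0), p.get("upper", 1.0)
        x0, scale = p.get("x0", math.log10(16.0)), p.get("scale", 0.15)
        return lower + (upper - lower) / (1.0 + np.exp(-(u - x0) / scale))
    # saturating, on the natural ratio scale
    x = 10.0 ** u
    half = p.get("half_x", 16.0)
    return p.get("base", 0.0) + p.get("amplitude", 1.0) * x / (half + x)


def _ls_slope(u: np.ndarray, y: np.ndarray) -> Optional[float]:
    if len(u) < 2:
        return None
    return float(np.polyfit(u, y, 1)[0])


def _ground_truth(spec: CurveSpec, u: np.ndarray) -> GroundTruth:
    p = spec.shape_params
    if spec.shape == "hinge":
        psi = p.get("psi", math.log10(16.0))
        return GroundTruth("hinge", 10.0 ** psi, p.get("slope1", 2.0), p.get("slope2", 0.0))
    if spec.shape == "logistic":
        x0 = p.get("x0", math.log10(16.0))
        y_true = _true_response(spec, u)
        below, above = u <= x0, u > x0
        return GroundTruth(
            "logistic",
            10.0 ** x0,
            _ls_slope(u[below], y_true[below]),
            _ls_slope(u[above], y_true[above]),
        )
    return GroundTruth(spec.shape, None, None, None)


def gen_curve(spec: CurveSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate (x, y, ground_truth) for a curve spec.

    ``x`` is log-spaced on [x_lo, x_hi]; ``y`` is the shape evaluated at
    log10(x) plus Gaussian noise with the spec's seed (bit-reproducible).
    """
    x = np.geomspace(spec.x_lo, spec.x_hi, spec.n_points)
    u = np.log10(x)
    y = _true_response(spec, u)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sigma, size=spec.n_points)
    return x, y, _ground_truth(spec, u)


def recovery_experiment(
    specs: Sequence[CurveSpec],
    n_reps: int = 20,
    base_seed: int = 0,
    n_grid: int = 201,
) -> pd.DataFrame:
    """Round-trip detection accuracy over seeded replicates of each spec.

    For each spec, ``n_reps`` curves are generated with derived seeds and
    run through detection. Returns one row per spec with the classification
    accuracy, median and IQR of the relative x_ter error, and median
    absolute slope errors. Deterministic given ``base_seed``.
    """
    if n_reps < 20:
        raise InvalidParameterError(f"n_reps must be >= 20, got {n_reps}")
    rows = []
    for i, spec in enumerate(specs):
        seeds = np.random.SeedSequence([base_seed, i]).generate_state(n_reps)
        shape_hits = 0
        x_errors, slope_errors = [], []
        false_thresholds = 0
        for rep in range(n_reps):
            x, y, truth = gen_curve(replace(spec, seed=int(seeds[rep])))
            est = detect_threshold(x, y, n_grid=n_grid)
            shape_hits += est.shape == truth.shape
            if truth.x_ter is None:
                false_thresholds += est.has_threshold
            elif est.has_threshold:
                x_errors.append(abs(est.x_ter - truth.x_ter) / truth.x_ter)
                for t_slope, e_slope in (
                    (truth.slope_below, est.slope_below),
                    (truth.slope_above, est.slope_above),
                ):
                    if t_slope is not None and e_slope is not None:
                        slope_errors.append(abs(e_slope - t_slope))
        rows.append(
            {
                "shape": spec.shape,
                "noise_sigma": spec.noise_sigma,
                "n_points": spec.n_points,
                "n_reps": n_reps,
                "shape_accuracy": shape_hits / n_reps,
                "threshold_found_rate": (
                    false_thresholds / n_reps if truth.x_ter is None else len(x_errors) / n_reps
                ),
                "median_rel_x_error": float(np.median(x_errors)) if x_errors else np.nan,
                "iqr_rel_x_error": (
                    float(np.subtract(*np.percentile(x_errors, [75, 25]))) if x_errors else np.nan
                ),
                "median_abs_slope_error": (
                    float(np.median(slope_errors)) if slope_errors else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
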
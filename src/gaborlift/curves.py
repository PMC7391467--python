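"""Horizontal integral curves: the association-field model.

A horizontal curve follows a constant linear combination
``c1 X1 + c2 X2 + c3 X3 + c4 X4`` of the horizontal frame.  Component-wise,

    q1' = c1 cos(theta) - c3 sin(theta)
    q2' = c1 sin(theta) + c3 cos(theta)
    theta' = c2,   omega' = c4,   phi' = c3 * omega

which integrates in closed form: circular arcs of radius |c1/c2| in the
image plane when c2 != 0 (straight lines when c2 = 0), linear drift in
orientation and frequency, and a quadratic phase.  Fans of such curves with
one coefficient swept reproduce the association-field layouts of contour
integration psychophysics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bank import FeaturePoint

__all__ = [
    "CurveCoefficients",
    "HorizontalCurve",
    "velocity",
    "closed_form_curve",
    "numeric_curve",
    "curve_fan",
    "curve_to_dataframe",
]

#: below this |c2| the arc formulas are numerically unsafe and the straight
#: branch is used instead (the branches agree to ~1e-5 already at |c2|=1e-8)
EPS_SWITCH = 1e-10


@dataclass(frozen=True)
class CurveCoefficients:
    c1: float = 0.0
    c2: float = 0.0
    c3: float = 0.0
    c4: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "c3", "c4"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")

    def replace(self, **kwargs) -> "CurveCoefficients":
        data = {k: getattr(self, k) for k in ("c1", "c2", "c3", "c4")}
        data.update(kwargs)
        return CurveCoefficients(**data)


@dataclass
class HorizontalCurve:
    """A sampled trajectory (q1, q2, theta, omega, phi)(t).

    ``samples`` has shape (n, 5) with samples[0] equal to the initial point;
    samples with omega <= 0 are truncated away (positive frequency is a
    manifold constraint), so ``times`` may be shorter than requested.
    """

    times: np.ndarray
    samples: np.ndarray
    initial: FeaturePoint
    coefficients: CurveCoefficients


def velocity(point, coeffs: CurveCoefficients) -> np.ndarray:
    """Coordinate velocity (q1', q2', theta', omega', phi') at ``point``.

    ``point`` may be a FeaturePoint or a raw 5-vector (q1, q2, theta,
    omega, phi) — raw vectors are accepted so numerical integrators can
    pass through omega <= 0 transiently.
    """
    if isinstance(point, FeaturePoint):
        theta, omega = point.theta, point.omega
    else:
        theta, omega = point[2], point[3]
    ct, st = np.cos(theta), np.sin(theta)
    return np.array(
        [
            coeffs.c1 * ct - coeffs.c3 * st,
            coeffs.c1 * st + coeffs.c3 * ct,
            coeffs.c2,
            coeffs.c4,
            coeffs.c3 * omega,
        ]
    )


def _initial_state(init: FeaturePoint) -> np.ndarray:
    return np.array([init.q1, init.q2, init.theta, init.omega, init.phi])


def _truncate_positive_omega(times: np.ndarray, samples: np.ndarray):
    bad = np.nonzero(samples[:, 3] <= 0.0)[0]
    if bad.size:
        stop = int(bad[0])
        if stop == 0:
            raise ValueError("initial point must have omega > 0")
        return times[:stop], samples[:stop]
    return times, samples


def closed_form_curve(
    init: FeaturePoint, coeffs: CurveCoefficients, times
) -> HorizontalCurve:
    """Exact constant-coefficient horizontal curve sampled at ``times``.

    Uses the rotating (arc) branch when |c2| > EPS_SWITCH and the straight
    branch otherwise; theta, omega and phi follow the same closed forms in
    both branches.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0 or t[0] != 0.0:
        raise ValueError("times must start at 0")
    c1, c2, c3, c4 = coeffs.c1, coeffs.c2, coeffs.c3, coeffs.c4
    th0, w0, ph0 = init.theta, init.omega, init.phi
    theta = c2 * t + th0
    omega = c4 * t + w0
    phi = 0.5 * (c3 * c4 * t**2 + 2.0 * t * c3 * w0 + 2.0 * ph0)
    if abs(c2) > EPS_SWITCH:
        q1 = init.q1 + (
            -c3 * np.cos(th0) + c3 * np.cos(theta) - c1 * np.sin(th0) + c1 * np.sin(theta)
        ) / c2
        q2 = init.q2 + (
            c1 * np.cos(th0) - c1 * np.cos(theta) - c3 * np.sin(th0) + c3 * np.sin(theta)
        ) / c2
    else:
        q1 = init.q1 + t * (c1 * np.cos(th0) - c3 * np.sin(th0))
        q2 = init.q2 + t * (c3 * np.cos(th0) + c1 * np.sin(th0))
    samples = np.column_stack([q1, q2, theta, omega, phi])
    t, samples = _truncate_positive_omega(t, samples)
    return HorizontalCurve(times=t, samples=samples, initial=init, coefficients=coeffs)


def _rk4_step(state: np.ndarray, h: float, coeffs: CurveCoefficients) -> np.ndarray:
    k1 = velocity(state, coeffs)
    k2 = velocity(state + 0.5 * h * k1, coeffs)
    k3 = velocity(state + 0.5 * h * k2, coeffs)
    k4 = velocity(state + h * k3, coeffs)
    return state + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def numeric_curve(
    init: FeaturePoint,
    coeffs: CurveCoefficients,
    times,
    step: float = 1e-3,
) -> HorizontalCurve:
    """Classical 4th-order Runge-Kutta integration of the curve ODE.

    Serves as an independent oracle for the closed forms; the global error
    decreases as O(step^4).  Each interval between requested sample times is
    covered by uniform substeps no longer than ``step``.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0 or t[0] != 0.0:
        raise ValueError("times must start at 0")
    if step <= 0:
        raise ValueError("step must be positive")
    state = _initial_state(init)
    samples = [state.copy()]
    for a, b in zip(t[:-1], t[1:]):
        span = b - a
        n = max(1, int(math.ceil(span / step)))
        h = span / n
        for _ in range(n):
            state = _rk4_step(state, h, coeffs)
        samples.append(state.copy())
    samples = np.array(samples)
    t, samples = _truncate_positive_omega(t, samples)
    return HorizontalCurve(times=t, samples=samples, initial=init, coefficients=coeffs)


def curve_fan(
    init: FeaturePoint,
    base_coeffs: CurveCoefficients,
    vary: str,
    values,
    times=None,
) -> list[HorizontalCurve]:
    """One closed-form curve per value of the swept coefficient ``vary``.

    ``vary`` is one of "c1".."c4".  Sweeping c2 around a straight X1 curve
    produces the fan of circular arcs mirror-symmetric across the initial
    axis; sweeping c4 around an X3 curve fans out in frequency with theta
    constant along each curve.
    """
    if vary not in ("c1", "c2", "c3", "c4"):
        raise ValueError(f"vary must be one of c1..c4, got {vary!r}")
    if times is None:
        times = np.linspace(0.0, 1.0, 101)
    return [
        closed_form_curve(init, base_coeffs.replace(**{vary: float(v)}), times)
        for v in values
    ]


def curve_to_dataframe(curve: HorizontalCurve) -> pd.DataFrame:
    """Sampled curve as a DataFrame with columns t, q1, q2, theta, omega, phi."""
    return pd.DataFrame(
        {
            "t": curve.times,
            "q1": curve.samples[:, 0],
            "q2": curve.samples[:, 1],
            "theta": curve.samples[:, 2],
            "omega": curve.samples[:, 3],
            "phi": curve.samples[:, 4],
        }
    )
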
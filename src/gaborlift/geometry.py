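"""The sub-Riemannian engine of the lifted feature space.

Coordinates on the 5D manifold are ordered ``(x, y, theta, omega, s)``.
The contact form

    Theta = -omega*sin(theta) dx + omega*cos(theta) dy - ds

annihilates the horizontal frame

    X1 = cos(theta) dx + sin(theta) dy
    X2 = d/dtheta
    X3 = -sin(theta) dx + cos(theta) dy + omega d/ds
    X4 = d/domega

whose iterated brackets span the full tangent space (Hormander condition),
so any two feature points are joined by horizontal curves.  Each fixed
frequency carries a Lie group of rototranslations + phase shifts, and the
evolving coefficient field induces a rank-one-perturbed metric
``g = I + w w^T`` (``w_i = sqrt(c_i) X_i u``) whose determinant and inverse
have closed forms used throughout the diffusion flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import sympy as sp

from .bank import FeaturePoint, _wrap_angle

__all__ = [
    "COORD_NAMES",
    "HorizontalFrame",
    "MetricField",
    "GroupElement",
    "horizontal_frame",
    "contact_form",
    "contact_form_value",
    "commutator_coefficients",
    "commutator_apply",
    "printed_commutator_table",
    "bracket_rank",
    "volume_form_coefficient",
    "induced_metric",
    "group_multiply",
    "group_inverse",
    "left_translation_differential",
    "test_fields",
]

COORD_NAMES = ("x", "y", "theta", "omega", "s")


# ---------------------------------------------------------------------------
# horizontal frame and contact form
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HorizontalFrame:
    """Coefficient rows of X1..X4 in the coordinate basis (dx, dy, dtheta, domega, ds)."""

    coefficients: np.ndarray  # shape (4, 5)

    def __getitem__(self, i: int) -> np.ndarray:
        """Coordinate vector of X_{i+1}."""
        return self.coefficients[i]


def horizontal_frame(point: FeaturePoint) -> HorizontalFrame:
    ct, st = math.cos(point.theta), math.sin(point.theta)
    coeff = np.array(
        [
            [ct, st, 0.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0, 0.0],
            [-st, ct, 0.0, 0.0, point.omega],
            [0.0, 0.0, 0.0, 1.0, 0.0],
        ]
    )
    return HorizontalFrame(coeff)


def contact_form(point) -> np.ndarray:
    """Covector of Theta at ``point`` (accepts complex coordinates for
    complex-step differentiation)."""
    if isinstance(point, FeaturePoint):
        theta, omega = point.theta, point.omega
    else:
        _, _, theta, omega, _ = point
    sin, cos = (np.sin, np.cos)
    return np.array([-omega * sin(theta), omega * cos(theta), 0.0, 0.0, -1.0])


def contact_form_value(point, tangent) -> float | complex:
    """Theta evaluated on a coordinate tangent 5-vector."""
    return np.dot(contact_form(point), np.asarray(tangent))


def volume_form_coefficient(point: FeaturePoint) -> float:
    """Evaluate Theta ^ dTheta ^ dTheta on the coordinate basis.

    ``dTheta`` is obtained by complex-step differentiation of the contact
    form's coefficient functions (exact to machine precision), and the wedge
    is evaluated by summing over the 120 permutations of the basis with the
    determinant normalization 1/(1! 2! 2!).  In this convention the result
    is exactly ``-2 * omega`` (other wedge/orientation conventions quote the
    coefficient as ``omega``); what matters is that it is proportional to
    omega and never vanishes on omega > 0, so Theta is a contact form and
    the 5-form is a volume form.
    """
    p0 = np.array([point.q1, point.q2, point.theta, point.omega, 0.0], dtype=complex)
    h = 1e-100
    jac = np.empty((5, 5))  # jac[i, j] = d a_j / d coord_i
    for i in range(5):
        p = p0.copy()
        p[i] += 1j * h
        jac[i] = np.imag(contact_form(p)) / h
    B = jac - jac.T  # dTheta(e_i, e_j) = B[i, j]
    a = contact_form(point).astype(float)
    total = 0.0
    for perm in permutations(range(5)):
        sign = _perm_sign(perm)
        total += sign * a[perm[0]] * B[perm[1], perm[2]] * B[perm[3], perm[4]]
    # wedge normalization 1/(1! * 2! * 2!) for the (1, 2, 2) factor degrees
    return total / 4.0


def _perm_sign(perm) -> int:
    sign = 1
    seen = [False] * len(perm)
    for i in range(len(perm)):
        if seen[i]:
            continue
        j, cycle = i, 0
        while not seen[j]:
            seen[j] = True
            j = perm[j]
            cycle += 1
        if cycle % 2 == 0:
            sign = -sign
    return sign


# ---------------------------------------------------------------------------
# commutators (symbolic, exact)
# ---------------------------------------------------------------------------

_SYMS = sp.symbols("x y theta omega s", real=True)


@lru_cache(maxsize=None)
def _symbolic_frame() -> tuple:
    x, y, theta, omega, s = _SYMS
    return (
        (sp.cos(theta), sp.sin(theta), 0, 0, 0),
        (0, 0, 1, 0, 0),
        (-sp.sin(theta), sp.cos(theta), 0, 0, omega),
        (0, 0, 0, 1, 0),
    )


def _apply_field(coeffs, f: sp.Expr) -> sp.Expr:
    return sum(c * sp.diff(f, v) for c, v in zip(coeffs, _SYMS))


@lru_cache(maxsize=None)
def commutator_coefficients(i: int, j: int) -> tuple:
    """Coordinate coefficients of [X_i, X_j] (1-based indices), derived symbolically.

    Computed from [X, Y]^k = X(Y^k) - Y(X^k) applied to each coordinate
    function, so the result is exact and independent of any printed table.
    """
    Xi = _symbolic_frame()[i - 1]
    Xj = _symbolic_frame()[j - 1]
    out = []
    for k, v in enumerate(_SYMS):
        lead = _apply_field(Xi, Xj[k]) - _apply_field(Xj, Xi[k])
        out.append(sp.simplify(lead))
    return tuple(out)


def printed_commutator_table() -> dict:
    """The three nonzero brackets of the frame, as closed-form expressions."""
    x, y, theta, omega, s = _SYMS
    return {
        (1, 2): (sp.sin(theta), -sp.cos(theta), 0, 0, 0),
        (2, 3): (-sp.cos(theta), -sp.sin(theta), 0, 0, 0),
        (3, 4): (0, 0, 0, 0, -1),
    }


def commutator_apply(i: int, j: int, point: FeaturePoint, test_field: sp.Expr) -> float:
    """Numeric value of [X_i, X_j] f at ``point`` for a symbolic test field.

    The bracket is computed as the second-order expression
    X_i(X_j f) - X_j(X_i f) symbolically and then evaluated, so the result
    is exact to floating point (no finite differences).
    """
    Xi = _symbolic_frame()[i - 1]
    Xj = _symbolic_frame()[j - 1]
    expr = _apply_field(Xi, _apply_field(Xj, test_field)) - _apply_field(
        Xj, _apply_field(Xi, test_field)
    )
    func = sp.lambdify(_SYMS, expr, "numpy")
    return float(func(point.q1, point.q2, point.theta, point.omega, 0.0))


def test_fields() -> list:
    """Smooth symbolic scalar fields used to exercise the bracket algebra."""
    x, y, theta, omega, s = _SYMS
    return [
        x * y + s * omega,
        sp.sin(x) * sp.cos(y) + theta**2,
        x**2 * s + omega * sp.sin(theta),
        sp.exp(x / 10) * y + s**2 + omega**2 * theta,
    ]


def bracket_rank(point: FeaturePoint) -> int:
    """Rank of span(X1..X4, [X1, X2]) at ``point`` (5 everywhere: Hormander)."""
    frame = horizontal_frame(point).coefficients
    lie = np.array(
        [float(c.evalf(subs={_SYMS[2]: point.theta, _SYMS[3]: point.omega}))
         for c in commutator_coefficients(1, 2)]
    )
    return int(np.linalg.matrix_rank(np.vstack([frame, lie])))


# ---------------------------------------------------------------------------
# induced metric
# ---------------------------------------------------------------------------


@dataclass
class MetricField:
    """Per-point induced metric g = I + w w^T with w_i = sqrt(c_i) X_i u.

    ``matrices`` has shape (..., m, m); ``determinant`` and ``inverse`` are
    computed from the rank-one identities
    det g = 1 + |w|^2  and  g^{-1} = I - w w^T / (1 + |w|^2).
    """

    matrices: np.ndarray
    determinant: np.ndarray
    inverse: np.ndarray
    weights: tuple


def induced_metric(gradients: np.ndarray, weights) -> MetricField:
    """Metric field from horizontal gradients (..., m) and weights c_1..c_m.

    ``gradients[..., i]`` holds X_{i+1} u at each grid point; ``weights``
    are the nonnegative diffusion weights c_i.  Entries of g are
    ``delta_ij + sqrt(c_i c_j) X_i u X_j u``.
    """
    grads = np.asarray(gradients, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.shape[0] != grads.shape[-1]:
        raise ValueError("weights must be a vector matching the gradient count")
    if np.any(w < 0):
        raise ValueError("metric weights must be nonnegative")
    wv = np.sqrt(w) * grads  # (..., m)
    outer = wv[..., :, None] * wv[..., None, :]
    m = grads.shape[-1]
    eye = np.eye(m)
    matrices = eye + outer
    det = 1.0 + np.sum(wv**2, axis=-1)
    inverse = eye - outer / det[..., None, None]
    return MetricField(matrices=matrices, determinant=det, inverse=inverse, weights=tuple(w))


# ---------------------------------------------------------------------------
# group structure of a frequency layer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupElement:
    """Element (q1, q2, theta, phi) of the rototranslation + phase group of a layer."""

    q1: float
    q2: float
    theta: float
    phi: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", _wrap_angle(self.theta))
        object.__setattr__(self, "phi", _wrap_angle(self.phi))

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.q1, self.q2, self.theta, self.phi])


def _rotation(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def group_multiply(g: GroupElement, h: GroupElement, printed: bool = False) -> GroupElement:
    """Compose two layer elements.

    The standard rigid-motion law rotates the second spatial part by the
    *first* element's angle: ``g h = (q^g + R_{theta1} q^h, theta1+theta2,
    phi1+phi2)``; this satisfies the group axioms.  ``printed=True``
    switches to the variant that rotates by theta1+theta2, kept only for
    comparison — it violates the identity axiom and is not a group law.
    """
    angle = g.theta + h.theta if printed else g.theta
    q = np.array([g.q1, g.q2]) + _rotation(angle) @ np.array([h.q1, h.q2])
    return GroupElement(q[0], q[1], g.theta + h.theta, g.phi + h.phi)


def group_inverse(g: GroupElement) -> GroupElement:
    q = -(_rotation(-g.theta) @ np.array([g.q1, g.q2]))
    return GroupElement(q[0], q[1], -g.theta, -g.phi)


def left_translation_differential(theta: float, omega: float) -> np.ndarray:
    """The 4x4 differential of left translation, as printed in the source model.

    Provided for inspection/reproduction only (its last column is zero and
    its bases are not part of this package's computations).
    """
    c, s = math.cos(theta), math.sin(theta)
    return np.array(
        [
            [c, 0.0, -s, 0.0],
            [s, 0.0, c, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, omega, 0.0],
        ]
    )
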
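"""Extended Gabor receptive profiles and the discrete filter bank.

A model simple cell of the primary visual cortex is parameterized by its
retinal position ``q = (q1, q2)``, preferred orientation ``theta``, preferred
spatial frequency ``omega`` and reference phase ``phi``.  Its receptive
profile is an oriented complex Gabor function: a plane wave with wave vector
``r = (-omega*sin(theta), omega*cos(theta))`` under an isotropic Gaussian
window of scale ``sigma``.  Every profile is a rototranslated, frequency
modulated and phase shifted copy of a single *mother* profile, which is what
makes the family a group orbit and gives the lifted feature space its
geometry.

The discrete filter bank samples this family on uniform orientation and
phase grids and an arbitrary strictly increasing frequency grid.  The phase
axis never needs to be materialized: with the wave evaluated at ``s = 0``
the phase enters only as the unit complex factor ``exp(-i*phi)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FeaturePoint",
    "BankSpec",
    "FilterStack",
    "mother_profile",
    "profile",
    "inverse_frame_coordinates",
    "build_bank",
    "spectral_coverage",
    "save_bank",
    "load_bank",
]

TWO_PI = 2.0 * math.pi


def _wrap_angle(a: float) -> float:
    """Reduce an angle to [0, 2*pi)."""
    return float(np.mod(a, TWO_PI))


@dataclass(frozen=True)
class FeaturePoint:
    """A point of the 5D feature manifold R^2 x S^1 x R^+ x S^1.

    ``q1, q2`` are retinal coordinates in pixels, ``theta`` the orientation
    in radians, ``omega`` the spatial frequency in radians/pixel (strictly
    positive) and ``phi`` the phase in radians.  Angles are stored reduced
    to [0, 2*pi).  The wave vector is derived, never stored.
    """

    q1: float
    q2: float
    theta: float
    omega: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        if not self.omega > 0:
            raise ValueError(f"omega must be positive, got {self.omega}")
        object.__setattr__(self, "theta", _wrap_angle(self.theta))
        object.__setattr__(self, "phi", _wrap_angle(self.phi))

    @property
    def wave_vector(self) -> tuple[float, float]:
        """(r1, r2) = (-omega*sin(theta), omega*cos(theta))."""
        return (-self.omega * math.sin(self.theta), self.omega * math.cos(self.theta))


@dataclass(frozen=True)
class BankSpec:
    """Sampling specification for a Gabor filter bank.

    Parameters
    ----------
    sigma : Gaussian scale in pixels (the envelope is exp(-|d|^2/sigma^2)).
    trunc_factor : spatial half-width of the sampled window in units of
        sigma, so the window is (2*trunc_factor*sigma + 1)^2 pixels.
    K : number of uniform orientation samples on [0, 2*pi).
    omegas : strictly increasing positive frequencies in radians/pixel.
    M : number of uniform phase samples (handled analytically downstream).
    theta_offset : rotation of the orientation grid, radians.
    """

    K: int
    omegas: tuple[float, ...]
    sigma: float = 2.0
    trunc_factor: float = 6.0
    M: int = 1
    theta_offset: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "omegas", tuple(float(w) for w in self.omegas))
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.trunc_factor <= 0:
            raise ValueError("trunc_factor must be positive")
        if len(self.omegas) == 0:
            raise ValueError("omegas must be nonempty")
        if any(w <= 0 for w in self.omegas):
            raise ValueError("all frequencies must be positive")
        if any(b <= a for a, b in zip(self.omegas, self.omegas[1:])):
            raise ValueError("omegas must be strictly increasing")

    @property
    def thetas(self) -> np.ndarray:
        return self.theta_offset + TWO_PI * np.arange(self.K) / self.K

    @property
    def phis(self) -> np.ndarray:
        return TWO_PI * np.arange(self.M) / self.M

    @property
    def half_width(self) -> int:
        return int(round(self.trunc_factor * self.sigma))


def mother_profile(x, y, s, omega: float, sigma: float = 1.0):
    """Mother Gabor profile exp(-i*(omega*y - s)) * exp(-(x^2+y^2)/sigma^2).

    ``x, y`` are offsets from the profile center in pixels, ``s`` is the
    phase coordinate.  ``sigma = 1`` recovers the unit-width profile; the
    general sigma rescales the Gaussian window only, not the wave.
    """
    if not omega > 0:
        raise ValueError(f"omega must be positive, got {omega}")
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    x = np.asarray(x)
    y = np.asarray(y)
    s = np.asarray(s)
    wave = omega * y - s
    return np.exp(-1j * wave) * np.exp(-(x**2 + y**2) / sigma**2)


def inverse_frame_coordinates(point: FeaturePoint, x, y, s):
    """Pull back ambient coordinates to the mother frame of ``point``.

    Applies the inverse of the rigid motion (rotation by theta about the
    center (q1, q2), phase shift by phi):  returns (x~, y~, s~) with
    (x~, y~) = R_{-theta} (x - q1, y - q2) and s~ = s - phi.
    """
    ct, st = math.cos(point.theta), math.sin(point.theta)
    dx = np.asarray(x) - point.q1
    dy = np.asarray(y) - point.q2
    return (ct * dx + st * dy, -st * dx + ct * dy, np.asarray(s) - point.phi)


def profile(point: FeaturePoint, x, y, s, sigma: float = 1.0):
    """Receptive profile at ``point`` evaluated at ambient (x, y, s).

    Equals the mother profile composed with the inverse rigid motion of
    ``point`` (rotation + translation + phase shift), written directly as
    exp(-i*(r.(x-q1, y-q2) - (s - phi))) * Gaussian(|x-q|, sigma).
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    r1, r2 = point.wave_vector
    dx = np.asarray(x) - point.q1
    dy = np.asarray(y) - point.q2
    wave = r1 * dx + r2 * dy - (np.asarray(s) - point.phi)
    return np.exp(-1j * wave) * np.exp(-(dx**2 + dy**2) / sigma**2)


@dataclass(frozen=True)
class FilterStack:
    """The sampled complex Gabor bank at phase coordinate s = 0.

    ``filters`` has shape (K, L, H, W): one centered complex window per
    (orientation, frequency) pair, sampled at phi = 0.  Filters at any other
    phase are the unit factor exp(-i*phi) times these and are materialized
    on demand via :meth:`filter_at`.
    """

    filters: np.ndarray
    thetas: np.ndarray
    omegas: np.ndarray
    sigma: float
    spec: BankSpec = field(repr=False)

    @property
    def K(self) -> int:
        return self.filters.shape[0]

    @property
    def L(self) -> int:
        return self.filters.shape[1]

    @property
    def window_shape(self) -> tuple[int, int]:
        return self.filters.shape[2:]

    @property
    def half_width(self) -> int:
        return self.filters.shape[2] // 2

    def filter_at(self, k: int, l: int, phi: float = 0.0) -> np.ndarray:
        """Filter for orientation index k, frequency index l, phase phi."""
        if phi == 0.0:
            return self.filters[k, l]
        return np.exp(-1j * phi) * self.filters[k, l]

    def restrict_frequencies(self, indices: Sequence[int]) -> "FilterStack":
        """Sub-bank keeping only the frequency channels in ``indices``."""
        idx = list(indices)
        sub_spec = BankSpec(
            K=self.spec.K,
            omegas=tuple(self.omegas[i] for i in idx),
            sigma=self.spec.sigma,
            trunc_factor=self.spec.trunc_factor,
            M=self.spec.M,
            theta_offset=self.spec.theta_offset,
        )
        return FilterStack(
            filters=self.filters[:, idx],
            thetas=self.thetas,
            omegas=self.omegas[idx],
            sigma=self.sigma,
            spec=sub_spec,
        )


def build_bank(spec: BankSpec) -> FilterStack:
    """Sample the Gabor family on the grids of ``spec`` at s = 0, phi = 0.

    The spatial window is (2*round(trunc_factor*sigma)+1)^2 pixels centered
    on the origin; orientations are K uniform samples of [0, 2*pi) starting
    at ``theta_offset``.
    """
    half = spec.half_width
    coords = np.arange(-half, half + 1, dtype=float)
    X, Y = np.meshgrid(coords, coords, indexing="xy")  # X: column offset, Y: row offset
    thetas = spec.thetas
    omegas = np.asarray(spec.omegas, dtype=float)
    filters = np.empty((spec.K, len(omegas), 2 * half + 1, 2 * half + 1), dtype=complex)
    for k, th in enumerate(thetas):
        for l, w in enumerate(omegas):
            pt = FeaturePoint(0.0, 0.0, th, w, 0.0)
            filters[k, l] = profile(pt, X, Y, 0.0, sigma=spec.sigma)
    return FilterStack(filters=filters, thetas=thetas, omegas=omegas, sigma=spec.sigma, spec=spec)


def _embedded_fft(kernel: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """DFT of a centered kernel zero-embedded into ``shape`` (center at (0,0))."""
    H, W = shape
    kh, kw = kernel.shape
    if kh > H or kw > W:
        raise ValueError(f"filter window {kernel.shape} larger than grid {shape}")
    big = np.zeros(shape, dtype=complex)
    big[:kh, :kw] = kernel
    # roll so the kernel center sits at index (0, 0)
    big = np.roll(big, (-(kh // 2), -(kw // 2)), axis=(0, 1))
    return np.fft.fft2(big)


def spectral_coverage(bank: FilterStack, shape: tuple[int, int]) -> np.ndarray:
    """Sum of squared filter spectra over all (theta, omega) channels.

    Returns the nonnegative real field sum_{k,l} |F Psi_{k,l}|^2 on the
    discrete Fourier grid of ``shape`` (unshifted DFT layout; frequency
    (0,0) at the corner).  Phase factors have unit modulus so the phase
    axis only multiplies counts and is omitted.  A bank must cover the
    spectral support of the image band for the lift to be invertible.
    """
    cov = np.zeros(shape, dtype=float)
    for k in range(bank.K):
        for l in range(bank.L):
            cov += np.abs(_embedded_fft(bank.filters[k, l], shape)) ** 2
    return cov


def save_bank(path, bank: FilterStack) -> None:
    """Persist a bank as an .npz container with a JSON metadata block."""
    meta = {
        "K": bank.spec.K,
        "omegas": list(bank.spec.omegas),
        "sigma": bank.spec.sigma,
        "trunc_factor": bank.spec.trunc_factor,
        "M": bank.spec.M,
        "theta_offset": bank.spec.theta_offset,
    }
    np.savez(
        path,
        filters_real=bank.filters.real,
        filters_imag=bank.filters.imag,
        thetas=bank.thetas,
        omegas=bank.omegas,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_bank(path) -> FilterStack:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        spec = BankSpec(
            K=int(meta["K"]),
            omegas=tuple(meta["omegas"]),
            sigma=float(meta["sigma"]),
            trunc_factor=float(meta["trunc_factor"]),
            M=int(meta["M"]),
            theta_offset=float(meta["theta_offset"]),
        )
        filters = data["filters_real"] + 1j * data["filters_imag"]
        return FilterStack(
            filters=filters,
            thetas=data["thetas"],
            omegas=data["omegas"],
            sigma=spec.sigma,
            spec=spec,
        )
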
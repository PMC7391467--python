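"""Seeded synthetic test images and fidelity metrics.

Everything here emulates the test conditions of the enhancement
experiments without external data: oriented multi-frequency gratings in
[0, 1] intensity, additive white Gaussian noise, and PSNR.  All generators
are deterministic given their spec and seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FixtureSpec",
    "grating",
    "composite",
    "add_noise",
    "psnr",
    "bandlimited_image",
    "default_fixture",
    "make_pair",
]

NYQUIST = math.pi  # radians/pixel


@dataclass(frozen=True)
class FixtureSpec:
    """A synthetic grating scene: components are (theta0, omega0, phase, contrast).

    The composite image is 0.5 + sum 0.5*contrast_i*cos(...), so the total
    contrast must not exceed 1 to stay in [0, 1].  ``noise_sigma`` is the
    std of the additive Gaussian noise in intensity units.
    """

    shape: tuple[int, int] = (64, 64)
    components: tuple = ()
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 16:
            raise ValueError("shape must be at least 16x16")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        total = 0.0
        for theta0, omega0, phase, contrast in self.components:
            if not 0.0 <= omega0 < NYQUIST:
                raise ValueError(f"omega0={omega0} is at or above Nyquist (pi rad/pixel)")
            if not 0.0 < contrast <= 1.0:
                raise ValueError("contrast must be in (0, 1]")
            total += contrast
        if total > 1.0 + 1e-12:
            raise ValueError("total contrast exceeds 1; image would leave [0, 1]")

    def to_json(self) -> str:
        return json.dumps(
            {
                "shape": list(self.shape),
                "components": [list(c) for c in self.components],
                "noise_sigma": self.noise_sigma,
                "seed": self.seed,
            }
        )


def _phase_field(shape, theta0: float, omega0: float, phase: float) -> np.ndarray:
    H, W = shape
    y, x = np.mgrid[0:H, 0:W].astype(float)
    return omega0 * (-x * math.sin(theta0) + y * math.cos(theta0)) + phase


def grating(
    shape,
    theta0: float,
    omega0: float,
    phase: float = 0.0,
    contrast: float = 1.0,
) -> np.ndarray:
    """Sinusoidal grating 0.5 + 0.5*contrast*cos(omega0*(-x sin + y cos) + phase).

    Values lie in [0, 1]; ``omega0`` must be below the Nyquist frequency
    pi rad/pixel.
    """
    if not 0.0 <= omega0 < NYQUIST:
        raise ValueError(f"omega0={omega0} is at or above Nyquist (pi rad/pixel)")
    if not 0.0 < contrast <= 1.0:
        raise ValueError("contrast must be in (0, 1]")
    return 0.5 + 0.5 * contrast * np.cos(_phase_field(shape, theta0, omega0, phase))


def composite(spec: FixtureSpec) -> np.ndarray:
    """Superpose the spec's grating components around the 0.5 gray level."""
    img = np.full(spec.shape, 0.5)
    for theta0, omega0, phase, contrast in spec.components:
        img += 0.5 * contrast * np.cos(_phase_field(spec.shape, theta0, omega0, phase))
    return img


def add_noise(image: np.ndarray, sigma_n: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Add zero-mean Gaussian noise, reproducibly; no clipping is applied."""
    if sigma_n < 0:
        raise ValueError("sigma_n must be nonnegative")
    image = np.asarray(image, dtype=float)
    if sigma_n == 0:
        return image.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return image + sigma_n * rng.standard_normal(image.shape)


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio 10*log10(peak^2/MSE) in decibels.

    Identical inputs return ``inf``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * math.log10(peak**2 / mse)


def bandlimited_image(n: int = 64) -> np.ndarray:
    """Deterministic band-limited test image (synthetic stand-in).

    A superposition of DFT-commensurate gratings (integer cycle counts, so
    the image is exactly periodic and its spectrum is a finite set of
    frequencies within roughly [0.5, 2.3] rad/pixel) around the 0.5 gray
    level.  Used for transform round-trip experiments where contamination
    from boundary effects or out-of-band content must be excluded.
    """
    y, x = np.mgrid[0:n, 0:n].astype(float)
    waves = [  # (cycles_x, cycles_y, amplitude, phase)
        (0, 8, 0.12, 0.0),
        (7, 3, 0.10, 1.0),
        (-5, 11, 0.08, 2.2),
        (12, -6, 0.07, 0.7),
        (3, 16, 0.06, 1.9),
    ]
    img = np.full((n, n), 0.5)
    for mx, my, amp, ph in waves:
        img += amp * np.cos(2.0 * math.pi * (mx * x + my * y) / n + ph)
    return img


def default_fixture() -> FixtureSpec:
    """The standard two-grating noisy scene used across the test suite."""
    return FixtureSpec(
        shape=(64, 64),
        components=(
            (0.0, 0.75, 0.0, 0.5),
            (math.pi / 3.0, 1.5, 0.0, 0.5),
        ),
        noise_sigma=0.1,
        seed=42,
    )


def make_pair(spec: FixtureSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(clean, noisy) pair for a fixture spec (default: the standard scene)."""
    spec = default_fixture() if spec is None else spec
    clean = composite(spec)
    noisy = add_noise(clean, spec.noise_sigma, spec.seed)
    return clean, noisy
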
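"""Named sampling protocols for the standard experiments.

Each preset bundles the bank sampling grids and flow parameters of one of
the reference experimental configurations:

``transform-dense``
    Dense transform/inverse-transform protocol on 64x64 images: 32
    orientations, a 29-value frequency grid from 0.25 to 3.25 rad/pixel
    (step 0.25 up to 1.25, 0.125 up to 2.25, 0.0625 up to 3.25), 16 phases,
    scale 2 px.  Used for round-trip quality studies.
``denoise-64``
    Enhancement protocol for 64x64 images: 16 orientations, frequencies
    0.25..1 step 0.25 then 1.125..2.25 step 0.125 (14 values), 5 phases,
    dt = 0.1, 15 iterations, c1 = 1 and c2 = beta^2 with beta = K/N = 0.25.
``texture-256``
    Enhancement protocol for 256x256 texture images: 16 orientations, the
    10-value frequency list 1.45..2.19, a 48-pixel filter window at scale 2
    (trunc_factor 12), dt = 0.1.
"""

from __future__ import annotations


from .bank import BankSpec
from .flow import FlowConfig

__all__ = ["PRESETS", "get_preset", "Preset"]


def _arange(start: float, stop: float, step: float) -> list[float]:
    n = int(round((stop - start) / step)) + 1
    return [start + i * step for i in range(n)]


#: 29-value dense frequency grid, 0.25 .. 3.25 rad/pixel
DENSE_OMEGAS = tuple(
    _arange(0.25, 1.25, 0.25) + _arange(1.375, 2.25, 0.125) + _arange(2.3125, 3.25, 0.0625)
)

#: 14-value enhancement grid, 0.25 .. 2.25 rad/pixel
DENOISE_OMEGAS = tuple(_arange(0.25, 1.0, 0.25) + _arange(1.125, 2.25, 0.125))

#: 10-value texture grid, geometric-ish spacing 1.45 .. 2.19 rad/pixel
TEXTURE_OMEGAS = (1.45, 1.51, 1.58, 1.66, 1.74, 1.82, 1.91, 2.0, 2.09, 2.19)


class Preset:
    def __init__(self, name: str, bank: BankSpec, flow: FlowConfig, image_size: int):
        self.name = name
        self.bank = bank
        self.flow = flow
        self.image_size = image_size


PRESETS: dict[str, Preset] = {
    "transform-dense": Preset(
        "transform-dense",
        BankSpec(K=32, omegas=DENSE_OMEGAS, sigma=2.0, trunc_factor=6.0, M=16),
        FlowConfig(dt=0.1, iterations=0),
        64,
    ),
    "denoise-64": Preset(
        "denoise-64",
        BankSpec(K=16, omegas=DENOISE_OMEGAS, sigma=2.0, trunc_factor=6.0, M=5),
        FlowConfig(dt=0.1, iterations=15),
        64,
    ),
    "texture-256": Preset(
        "texture-256",
        BankSpec(K=16, omegas=TEXTURE_OMEGAS, sigma=2.0, trunc_factor=12.0, M=5),
        FlowConfig(dt=0.1, iterations=75),
        256,
    ),
}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
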
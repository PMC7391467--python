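"""Image and array I/O helpers.

Images are exchanged as 8/16-bit PNG or TIFF and converted to floats in
[0, 1]; lifted coefficient fields persist as .npz containers holding real
and imaginary parts plus grid metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .bank import BankSpec, FilterStack, build_bank
from .transform import LiftedImage

__all__ = ["read_image", "write_image", "save_lifted", "load_lifted"]


def read_image(path) -> np.ndarray:
    """Read a grayscale image as floats in [0, 1] (color inputs are averaged)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path))
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    arr = arr.astype(float)
    if np.issubdtype(np.asarray(arr).dtype, np.floating) and arr.max() > 1.0:
        info_max = 65535.0 if arr.max() > 255.0 else 255.0
        arr = arr / info_max
    return arr


def write_image(path, image: np.ndarray, bits: int = 8) -> None:
    """Write a float image, clipping to [0, 1] only at export."""
    path = Path(path)
    clipped = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if bits == 16:
        data = (clipped * 65535.0 + 0.5).astype(np.uint16)
    elif bits == 8:
        data = (clipped * 255.0 + 0.5).astype(np.uint8)
    else:
        raise ValueError("bits must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, data)


def save_lifted(path, lifted: LiftedImage) -> None:
    spec = lifted.bank.spec
    meta = {
        "boundary": lifted.boundary,
        "K": spec.K,
        "omegas": list(spec.omegas),
        "sigma": spec.sigma,
        "trunc_factor": spec.trunc_factor,
        "M": spec.M,
        "theta_offset": spec.theta_offset,
    }
    np.savez(
        path,
        coeffs_real=lifted.coeffs.real,
        coeffs_imag=lifted.coeffs.imag,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_lifted(path, bank: FilterStack | None = None) -> LiftedImage:
    """Load a lifted field; the generating bank is rebuilt from metadata if not given."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if bank is None:
            spec = BankSpec(
                K=int(meta["K"]),
                omegas=tuple(meta["omegas"]),
                sigma=float(meta["sigma"]),
                trunc_factor=float(meta["trunc_factor"]),
                M=int(meta["M"]),
                theta_offset=float(meta["theta_offset"]),
            )
            bank = build_bank(spec)
        coeffs = data["coeffs_real"] + 1j * data["coeffs_imag"]
    return LiftedImage(coeffs=coeffs, bank=bank, boundary=meta["boundary"])
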
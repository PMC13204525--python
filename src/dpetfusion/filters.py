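"""Derived-image bank for radiomics extraction.

The default bank contains the original image plus 17 derived images:

* 8 single-level stationary-wavelet sub-bands (one low/high split per axis,
  ``coif1`` kernel) — stationary so sub-bands keep the input shape;
* Laplacian-of-Gaussian at 5 scales (sigma = 1..5 mm, physical units);
* 4 pointwise intensity transforms (square, square root, logarithm,
  exponential) applied to the min-max normalized image, so the whole bank
  is invariant to adding a constant to the input.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

WAVELET_NAMES = ["LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"]
LOG_SIGMAS_MM = (1.0, 2.0, 3.0, 4.0, 5.0)
POINTWISE_NAMES = ["square", "squareroot", "logarithm", "exponential"]


def default_image_names() -> list[str]:
    return (
        ["original"]
        + [f"wavelet-{n}" for n in WAVELET_NAMES]
        + [f"log-sigma-{s:g}mm" for s in LOG_SIGMAS_MM]
        + POINTWISE_NAMES
    )


def _pad_to_even(data: np.ndarray) -> tuple[np.ndarray, tuple[slice, ...]]:
    pads = [(0, s % 2) for s in data.shape]
    unpad = tuple(slice(0, s) for s in data.shape)
    if any(p[1] for p in pads):
        data = np.pad(data, pads, mode="symmetric")
    return data, unpad


def wavelet_bands(data: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Single-level stationary (undecimated) wavelet sub-bands, input-shaped."""
    padded, unpad = _pad_to_even(data.astype(np.float64))
    coeffs = pywt.swtn(padded, wavelet=wavelet, level=1, norm=True)[0]
    out = {}
    for name in WAVELET_NAMES:
        key = "".join("a" if c == "L" else "d" for c in name)
        out[f"wavelet-{name}"] = coeffs[key][unpad]
    return out


def log_images(data: np.ndarray, spacing: tuple[float, ...]) -> dict[str, np.ndarray]:
    """Laplacian-of-Gaussian responses at the default physical scales."""
    out = {}
    for sigma_mm in LOG_SIGMAS_MM:
        sig_vox = [sigma_mm / s for s in spacing]
        out[f"log-sigma-{sigma_mm:g}mm"] = ndimage.gaussian_laplace(
            data.astype(np.float64), sigma=sig_vox, mode="nearest"
        )
    return out


def pointwise_images(data: np.ndarray) -> dict[str, np.ndarray]:
    """Monotone pointwise transforms of the min-max normalized image."""
    lo, hi = float(data.min()), float(data.max())
    u = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data, dtype=np.float64)
    return {
        "square": u**2,
        "squareroot": np.sqrt(u),
        "logarithm": np.log1p(u) / np.log(2.0),
        "exponential": (np.expm1(u)) / (np.e - 1.0),
    }


def image_bank(
    data: np.ndarray,
    spacing: tuple[float, ...],
    names: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Compute the requested derived images (default: the full 18-image bank)."""
    names = default_image_names() if names is None else list(names)
    out: dict[str, np.ndarray] = {}
    need_wavelet = any(n.startswith("wavelet-") for n in names)
    wav = wavelet_bands(data) if need_wavelet else {}
    pw = pointwise_images(data) if any(n in POINTWISE_NAMES for n in names) else {}
    for name in names:
        if name == "original":
            out[name] = np.asarray(data, dtype=np.float64)
        elif name.startswith("wavelet-"):
            out[name] = wav[name]
        elif name.startswith("log-sigma-"):
            sigma_mm = float(name.removeprefix("log-sigma-").removesuffix("mm"))
            sig_vox = [sigma_mm / s for s in spacing]
            out[name] = ndimage.gaussian_laplace(
                np.asarray(data, dtype=np.float64), sigma=sig_vox, mode="nearest"
            )
        elif name in POINTWISE_NAMES:
            out[name] = pw[name]
        else:
            raise KeyError(f"unknown derived image {name!r}")
    return out
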
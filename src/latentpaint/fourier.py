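"""Centered low-pass projection used by the band-limited prior machinery."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["passband_mask", "lowpass_project"]


def passband_mask(height: int, width: int, passband_fraction: float) -> np.ndarray:
    """Boolean keep-mask over the unshifted 2-D DFT grid.

    The passband is the centered rectangle holding roughly
    ``passband_fraction`` of all coefficients (side fractions
    ``sqrt(passband_fraction)`` per axis).  The mask is conjugate-symmetric,
    so projecting a real image yields a real image.
    """
    if not 0.0 < passband_fraction <= 1.0:
        raise ValueError("passband_fraction must lie in (0, 1]")
    side = math.sqrt(passband_fraction)
    cut_h = height * side / 2.0 + 1e-9
    cut_w = width * side / 2.0 + 1e-9
    fh = np.abs(np.fft.fftfreq(height) * height)
    fw = np.abs(np.fft.fftfreq(width) * width)
    return (fh[:, None] <= cut_h) & (fw[None, :] <= cut_w)


def lowpass_project(image: np.ndarray, passband_fraction: float) -> np.ndarray:
    """Project a real 2-D (or channel-last 3-D) image onto the passband."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        return np.stack(
            [lowpass_project(image[..., c], passband_fraction)
             for c in range(image.shape[-1])], axis=-1)
    keep = passband_mask(*image.shape, passband_fraction)
    spectrum = np.fft.fft2(image)
    spectrum[~keep] = 0.0
    return np.real(np.fft.ifft2(spectrum))
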
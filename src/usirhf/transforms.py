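"""Linear operators used by the iterative reconstruction.

Centred unitary Fourier transforms, the orthogonal wavelet pair
(analysis/synthesis), the high-frequency preserving transform (a binary
central-tile low-pass in k-space: penalizing only its output leaves
high-frequency image content unpenalized), and complex soft thresholding,
the proximal map of the L1 norm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .errors import DimensionError, InvalidParameterError


# ---------------------------------------------------------------------------
# Fourier
# ---------------------------------------------------------------------------

def fft_centered(image: np.ndarray, axes=None) -> np.ndarray:
    """Unitary FFT with DC at the grid centre (index ``n // 2``)."""
    if axes is None:
        axes = tuple(range(image.ndim))
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(image, axes=axes), axes=axes,
                    norm="ortho"),
        axes=axes,
    )


def ifft_centered(kspace: np.ndarray, axes=None) -> np.ndarray:
    """Inverse of :func:`fft_centered` (also unitary)."""
    if axes is None:
        axes = tuple(range(kspace.ndim))
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(kspace, axes=axes), axes=axes,
                     norm="ortho"),
        axes=axes,
    )


# ---------------------------------------------------------------------------
# High-frequency preserving transform
# ---------------------------------------------------------------------------

@dataclass
class HFPreserveFilter:
    """Binary central-tile k-space low-pass.

    The pass band is 1 inside a centred tile whose side length is
    ``tile_fraction`` of each k-space dimension (default one half) and 0
    outside.  For even dimensions the tile is the half-open index range
    ``[n//2 - L//2, n//2 - L//2 + L)`` with ``L = round(tile_fraction * n)``,
    which always contains DC.
    """

    grid_shape: tuple
    tile_fraction: float = 0.5
    pass_mask: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if not (0 < self.tile_fraction <= 1):
            raise InvalidParameterError("tile_fraction must be in (0, 1]")
        slices = []
        for n in self.grid_shape:
            L = max(1, int(round(self.tile_fraction * n)))
            start = n // 2 - L // 2
            slices.append((start, start + L))
        pass_mask = np.zeros(self.grid_shape, dtype=bool)
        pass_mask[tuple(slice(a, b) for a, b in slices)] = True
        self.pass_mask = pass_mask


def apply_hf_preserve(x: np.ndarray, filt: HFPreserveFilter) -> np.ndarray:
    """Low-pass an image through the filter's k-space tile.

    Returns ``ifft_centered(pass_mask * fft_centered(x))``; a projection
    (applying twice equals applying once).
    """
    if x.shape != tuple(filt.grid_shape):
        raise DimensionError(
            f"image shape {x.shape} != filter shape {filt.grid_shape}"
        )
    return ifft_centered(filt.pass_mask * fft_centered(x))


# ---------------------------------------------------------------------------
# Wavelets
# ---------------------------------------------------------------------------

@dataclass
class WaveletSpec:
    """Wavelet family, decomposition depth and boundary handling.

    Defaults to Daubechies-4 at 3 levels with periodized boundaries; the
    periodized transform is exactly orthonormal, so the wavelet analysis
    operator satisfies Parseval and its adjoint equals its inverse.
    """

    family: str = "db4"
    levels: int = 3
    boundary: str = "periodization"

    def validate_for(self, shape):
        if self.levels < 1:
            raise InvalidParameterError("levels must be >= 1")
        max_lev = int(np.log2(min(shape)))
        if self.levels > max_lev:
            raise InvalidParameterError(
                f"levels={self.levels} too deep for shape {tuple(shape)} "
                f"(max {max_lev})"
            )


def wavelet_analysis(x: np.ndarray, spec: WaveletSpec):
    """2D multilevel wavelet decomposition packed into a single array.

    Returns ``(coeff_array, slices)``; ``slices`` is the bookkeeping needed
    by :func:`wavelet_synthesis`.
    """
    spec.validate_for(x.shape)
    coeffs = pywt.wavedec2(x, spec.family, mode=spec.boundary,
                           level=spec.levels)
    return pywt.coeffs_to_array(coeffs)


def wavelet_synthesis(coeff_array: np.ndarray, slices, spec: WaveletSpec,
                      shape=None) -> np.ndarray:
    """Inverse of :func:`wavelet_analysis` (perfect reconstruction)."""
    coeffs = pywt.array_to_coeffs(coeff_array, slices,
                                  output_format="wavedec2")
    out = pywt.waverec2(coeffs, spec.family, mode=spec.boundary)
    if shape is not None and out.shape != tuple(shape):
        out = out[tuple(slice(0, n) for n in shape)]
    return out


# ---------------------------------------------------------------------------
# Shrinkage
# ---------------------------------------------------------------------------

def soft_threshold(v: np.ndarray, tau: float) -> np.ndarray:
    """Complex soft thresholding: shrink magnitudes by ``tau``, keep phase.

    The exact proximal map of ``tau * || . ||_1``.
    """
    if tau < 0:
        raise InvalidParameterError(f"tau must be >= 0, got {tau}")
    if tau == 0:
        return np.asarray(v).copy()
    v = np.asarray(v)
    mag = np.abs(v)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(mag > tau, 1.0 - tau / np.maximum(mag, 1e-300), 0.0)
    return v * scale
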
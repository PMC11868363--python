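"""Digital slit phantom and simulated multi-coil k-space acquisition.

The phantom emulates a resolution test object: seven horizontal strips of
vertical bar patterns at 1.0-10.0 line pairs per centimetre (bright
saline-filled slits on a dimmer NiCl2-solution background) inside a 280 mm
field of view, plus a dedicated slightly slanted high-contrast edge block
for edge-method MTF estimation.

Acquisition is emulated in the band-limited sense of an MR scanner: the
continuous phantom is rasterized on a fine grid, its k-space is computed,
and the central region corresponding to the acquisition matrix is extracted
(k-space sample spacing 1/FOV is matrix independent).  A coarser matrix
therefore truncates high spatial frequencies rather than aliasing them --
the mechanism by which a 288 x 208 scan cannot show a 5.0 lp/cm gauge that
a 320 x 320 scan can.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, InvalidParameterError
from .recon import ImageVolume, KSpaceVolume
from .sampling import SamplingMask
from .transforms import fft_centered, ifft_centered

DEFAULT_GAUGE_FREQS = (1.0, 1.7, 2.5, 3.3, 5.0, 6.7, 10.0)


def gap_width_mm(freq_lp_cm: float) -> float:
    """Gap (slit) width in mm for a bar pattern of ``freq_lp_cm``.

    One line pair per cycle (bar + gap), so the gap is half the period:
    10 / (2 f) mm for f in lp/cm.  1.0 lp/cm -> 5.0 mm; 10 lp/cm -> 0.5 mm.
    """
    if freq_lp_cm <= 0:
        raise InvalidParameterError("frequency must be > 0 lp/cm")
    return 10.0 / (2.0 * freq_lp_cm)


@dataclass
class GaugeRegion:
    """Axis-aligned rectangle in mm (centre-of-FOV origin, y down rows)."""

    y0: float
    y1: float
    x0: float
    x1: float
    freq_lp_cm: float = 0.0


@dataclass
class SlitPhantomSpec:
    """Geometry and intensities of the digital slit phantom.

    ``foreground_si`` is the saline (slit) intensity, ``background_si`` the
    NiCl2 surround; both arbitrary units with foreground > background > 0 so
    relative signal intensity is finite.  Strips are ``strip_height_mm``
    tall with vertical bars spanning ``strip_width_mm``; frequencies chosen
    so an integer number of cycles fits the strip width.
    """

    gauge_freqs_lp_cm: tuple = DEFAULT_GAUGE_FREQS
    fov_mm: float = 280.0
    foreground_si: float = 1.0
    background_si: float = 0.2
    strip_height_mm: float = 20.0
    strip_gap_mm: float = 5.0
    strip_width_mm: float = 200.0
    edge_block: GaugeRegion = field(
        default_factory=lambda: GaugeRegion(82.0, 122.0, -30.0, 30.0)
    )
    edge_slant_deg: float = 5.0

    def __post_init__(self):
        freqs = tuple(self.gauge_freqs_lp_cm)
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise InvalidParameterError("gauge frequencies must increase")
        if not (self.foreground_si > self.background_si > 0):
            raise InvalidParameterError(
                "need foreground_si > background_si > 0"
            )
        self.gauge_freqs_lp_cm = freqs

    def gauge_layout(self):
        """Strip rectangles (mm), one per gauge frequency, top to bottom."""
        n = len(self.gauge_freqs_lp_cm)
        total = n * self.strip_height_mm + (n - 1) * self.strip_gap_mm
        y = -total / 2.0 - 30.0  # shifted up to leave room for edge block
        regions = []
        for f in self.gauge_freqs_lp_cm:
            regions.append(GaugeRegion(
                y, y + self.strip_height_mm,
                -self.strip_width_mm / 2.0, self.strip_width_mm / 2.0, f,
            ))
            y += self.strip_height_mm + self.strip_gap_mm
        return regions


def _phantom_values(spec: SlitPhantomSpec, x_mm, y_mm):
    """Continuous phantom intensity at mm coordinates (vectorized)."""
    out = np.full(np.broadcast(x_mm, y_mm).shape, spec.background_si)
    for reg in spec.gauge_layout():
        period = 10.0 / reg.freq_lp_cm
        inside = (
            (y_mm >= reg.y0) & (y_mm < reg.y1)
            & (x_mm >= reg.x0) & (x_mm < reg.x1)
        )
        phase = ((x_mm - reg.x0) / period) % 1.0
        slit = inside & (phase < 0.5)
        out[slit] = spec.foreground_si
    eb = spec.edge_block
    slope = np.tan(np.deg2rad(spec.edge_slant_deg))
    yc = 0.5 * (eb.y0 + eb.y1)
    xc = 0.5 * (eb.x0 + eb.x1)
    edge_x = xc + (y_mm - yc) * slope
    in_block = (
        (y_mm >= eb.y0) & (y_mm < eb.y1) & (x_mm >= eb.x0) & (x_mm < eb.x1)
    )
    out[in_block & (x_mm < edge_x)] = spec.foreground_si
    return out


def make_slit_phantom(spec: SlitPhantomSpec, matrix,
                      supersample: int = 4) -> ImageVolume:
    """Rasterize the phantom at ``matrix = (ny, nx)`` pixels.

    Pixels are anti-aliased by area-weighted coverage, approximated with a
    ``supersample x supersample`` sub-grid average.  Pixel centres sit at
    ``(i - n//2) * fov/n`` mm, matching the centred-FFT convention.
    """
    ny, nx = matrix
    coarsest = min(spec.gauge_freqs_lp_cm)
    px = spec.fov_mm / min(ny, nx)
    if 10.0 / coarsest < 4 * px:
        raise InvalidParameterError(
            "matrix too small: coarsest gauge needs >= 4 pixels per cycle"
        )
    dy, dx = spec.fov_mm / ny, spec.fov_mm / nx
    sub = (np.arange(supersample) + 0.5) / supersample - 0.5
    ys = ((np.arange(ny) - ny // 2)[:, None] + sub[None, :]) * dy
    xs = ((np.arange(nx) - nx // 2)[:, None] + sub[None, :]) * dx
    vals = np.zeros((ny, nx))
    for iy in range(supersample):
        for ix in range(supersample):
            vals += _phantom_values(
                spec, xs[None, :, ix], ys[:, iy, None]
            )
    vals /= supersample ** 2
    return ImageVolume(values=vals, fov_mm=spec.fov_mm,
                       voxel_spacing_mm=(dy, dx),
                       provenance={"kind": "slit_phantom",
                                   "matrix": (ny, nx)})


@dataclass
class CoilProfile:
    """Smooth complex coil sensitivity maps, one per channel."""

    maps: np.ndarray  # (n_coils, ny, nx) complex
    n_coils: int


def simulate_coil_profiles(matrix, n_coils: int, seed: int,
                           fov_mm: float = 280.0,
                           uniform: bool = False) -> CoilProfile:
    """Gaussian-lobe sensitivities on a ring around the FOV.

    The coil model lives in continuous mm coordinates: centres, widths and
    phase ramps depend only on ``seed`` and ``n_coils``, so evaluating the
    same seed on different matrices yields the same physical coils.
    Deterministic given ``seed``.
    """
    if n_coils < 1:
        raise InvalidParameterError("n_coils must be >= 1")
    ny, nx = matrix
    if uniform and n_coils == 1:
        return CoilProfile(np.ones((1, ny, nx), dtype=complex), 1)
    rng = np.random.default_rng(seed)
    radius = 0.55 * fov_mm
    sigma = 0.45 * fov_mm
    base_angles = 2 * np.pi * np.arange(n_coils) / n_coils
    jitter = rng.uniform(-0.1, 0.1, size=n_coils)
    phases = rng.uniform(0, 2 * np.pi, size=n_coils)
    ramps = rng.uniform(-0.5, 0.5, size=(n_coils, 2)) / fov_mm  # cycles/mm

    dy, dx = fov_mm / ny, fov_mm / nx
    y = (np.arange(ny) - ny // 2)[:, None] * dy
    x = (np.arange(nx) - nx // 2)[None, :] * dx
    maps = np.empty((n_coils, ny, nx), dtype=complex)
    for c in range(n_coils):
        ang = base_angles[c] + jitter[c]
        cy, cx = radius * np.sin(ang), radius * np.cos(ang)
        mag = np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2 * sigma ** 2))
        ph = phases[c] + 2 * np.pi * (ramps[c, 0] * y + ramps[c, 1] * x)
        maps[c] = mag * np.exp(1j * ph)
    return CoilProfile(maps, n_coils)


def _central_crop(k: np.ndarray, shape):
    """Centred k-space crop, preserving the DC index convention."""
    slices = []
    for n, m in zip(k.shape, shape):
        if m > n:
            raise DimensionError("crop shape larger than source")
        start = n // 2 - m // 2
        slices.append(slice(start, start + m))
    return k[tuple(slices)]


def acquire_kspace(truth: ImageVolume, coils: CoilProfile,
                   mask: SamplingMask, noise_sigma: float,
                   seed: int) -> KSpaceVolume:
    """Simulate a multi-coil acquisition of ``truth`` under ``mask``.

    Per coil: multiply by the sensitivity, Fourier transform, extract the
    central k-space region matching ``mask.grid_shape`` (band-limited
    acquisition when the truth grid is finer), apply the sampling mask, and
    add i.i.d. complex Gaussian noise (std ``noise_sigma`` per real/imag
    part) at the sampled points only.  Amplitudes are rescaled so images
    reconstructed at the acquisition matrix keep the truth intensity scale.
    """
    if noise_sigma < 0:
        raise InvalidParameterError("noise_sigma must be >= 0")
    if coils.maps.shape[1:] != truth.values.shape:
        raise DimensionError("coil maps must match the truth grid")
    ny, nx = mask.grid_shape
    hy, hx = truth.values.shape
    scale = np.sqrt((ny * nx) / (hy * hx))
    rng = np.random.default_rng(seed)
    data = np.zeros((coils.n_coils, ny, nx), dtype=complex)
    m = mask.sampled
    n_sampled = int(np.count_nonzero(m))
    for c in range(coils.n_coils):
        k_full = fft_centered(coils.maps[c] * truth.values)
        k = _central_crop(k_full, (ny, nx)) * scale
        if noise_sigma > 0:
            noise = noise_sigma * (
                rng.standard_normal(n_sampled)
                + 1j * rng.standard_normal(n_sampled)
            )
            k = k.copy()
            k[m] += noise
        data[c][m] = k[m]
    return KSpaceVolume(data=data, mask=mask, n_coils=coils.n_coils)


def sigma_for_snr(kspace_clean: np.ndarray, mask: SamplingMask,
                  snr_db: float) -> float:
    """Noise std per real/imag part giving a target mean k-space SNR.

    SNR is mean sampled-point signal power over total complex noise power
    ``2 sigma^2``.
    """
    p = float(np.mean(np.abs(kspace_clean[..., mask.sampled]) ** 2))
    return float(np.sqrt(p * 10 ** (-snr_db / 10.0) / 2.0))


def zero_filled_recon(kspace: KSpaceVolume) -> np.ndarray:
    """Root-sum-of-squares of per-coil inverse FFTs (baseline image)."""
    imgs = ifft_centered(kspace.data, axes=(-2, -1))
    return np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0))
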
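"""k-space sampling patterns for the ky--kz (phase x slice encode) plane.

Two schemes are provided: Golden-Angle radial under-sampling, in which
successive diameters through the k-space centre are rotated by the golden
angle (~111.25 deg) and rasterized onto the Cartesian encode grid from the
outside inwards, and regular Cartesian under-sampling as used by parallel
imaging.  Radial schemes sample the low-frequency centre densely, which is
what makes them robust to motion and suitable for compressed-sensing-style
reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InfeasiblePatternError, InvalidParameterError

GOLDEN_ANGLE_DEG = 111.246
"""Small golden angle (180 / golden-ratio^2) standard in radial MRI."""

SCHEME_GOLDEN = "golden_angle_radial"
SCHEME_CARTESIAN = "cartesian_regular"
SCHEME_FULL = "full"


@dataclass
class SamplingMask:
    """Binary sampling pattern over the (ky, kz) encode grid.

    Attributes
    ----------
    grid_shape : (n_phase, n_slice)
    sampled : bool array of ``grid_shape``
    undersampling_factor : ratio >= 1 that was requested
    acquisition_order : list of ``(m, 2)`` int arrays, one group per radial
        line (or per retained Cartesian row), outermost point first.
    golden_angle_deg : angle increment used (radial schemes only)
    scheme : one of ``golden_angle_radial``, ``cartesian_regular``, ``full``
    line_angles_deg : angles (deg, mod 180) of the radial lines laid down
    metadata : free-form dict (records warnings, effective factors, ...)
    """

    grid_shape: tuple
    sampled: np.ndarray
    undersampling_factor: float
    acquisition_order: list
    golden_angle_deg: float = GOLDEN_ANGLE_DEG
    scheme: str = SCHEME_GOLDEN
    line_angles_deg: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_phase(self):
        return self.grid_shape[0]

    @property
    def n_slice(self):
        return self.grid_shape[1]

    @property
    def dc_index(self):
        """Centre of the grid under the centred-spectrum convention."""
        return (self.grid_shape[0] // 2, self.grid_shape[1] // 2)


def sampling_fraction(mask: SamplingMask) -> float:
    """Fraction of encode-grid points that are sampled, in [0, 1]."""
    return float(np.count_nonzero(mask.sampled)) / float(
        mask.grid_shape[0] * mask.grid_shape[1]
    )


def _line_points(n_phase, n_slice, angle_deg):
    """Rasterize one diameter through the exact grid centre.

    The line spans the inscribed ellipse of the grid and is stepped at
    half-pixel increments; duplicates are removed preserving an
    outside-to-inside ordering (alternating the two outer ends).
    """
    cy, cz = n_phase // 2, n_slice // 2
    a, b = (n_phase - 1) / 2.0, (n_slice - 1) / 2.0
    theta = np.deg2rad(angle_deg)
    dy, dz = np.cos(theta), np.sin(theta)
    n_steps = max(4, int(np.ceil(4 * max(a, b))))
    ts = np.linspace(1.0, 0.0, n_steps + 1)
    pts = []
    seen = set()
    for t in ts:
        for s in ((+1, -1) if t > 0 else (+1,)):
            iy = int(round(cy + s * t * a * dy))
            iz = int(round(cz + s * t * b * dz))
            iy = min(max(iy, 0), n_phase - 1)
            iz = min(max(iz, 0), n_slice - 1)
            if (iy, iz) not in seen:
                seen.add((iy, iz))
                pts.append((iy, iz))
    return pts


def generate_golden_angle_mask(
    n_phase: int,
    n_slice: int,
    undersampling_factor: float,
    golden_angle_deg: float = GOLDEN_ANGLE_DEG,
) -> SamplingMask:
    """Golden-Angle radial under-sampling mask on an (n_phase, n_slice) grid.

    Whole radial lines (diameters through the grid centre at successive
    multiples of ``golden_angle_deg``, mod 180) are added, outermost point
    first, until the sampled fraction first reaches ``1/undersampling_factor``.
    Fully deterministic.
    """
    if n_phase < 4 or n_slice < 4:
        raise InvalidParameterError("grid must be at least 4 x 4")
    if undersampling_factor < 1:
        raise InvalidParameterError(
            f"undersampling_factor must be >= 1, got {undersampling_factor}"
        )
    target = 1.0 / undersampling_factor
    sampled = np.zeros((n_phase, n_slice), dtype=bool)
    order: list = []
    angles: list = []

    if undersampling_factor == 1.0:
        # factor-1 identity: every encode acquired (radial lines alone cannot
        # cover grid corners)
        sampled[:] = True
        iy, iz = np.meshgrid(
            np.arange(n_phase), np.arange(n_slice), indexing="ij"
        )
        order = [np.stack([iy.ravel(), iz.ravel()], axis=1).astype(np.int32)]
        return SamplingMask(
            (n_phase, n_slice), sampled, 1.0, order,
            golden_angle_deg, SCHEME_GOLDEN, [],
        )

    n_total = n_phase * n_slice
    k = 0
    stale = 0
    stale_limit = 8 * max(n_phase, n_slice)
    while np.count_nonzero(sampled) < target * n_total:
        angle = (k * golden_angle_deg) % 180.0
        pts = _line_points(n_phase, n_slice, angle)
        new = [(iy, iz) for (iy, iz) in pts if not sampled[iy, iz]]
        if new:
            for iy, iz in new:
                sampled[iy, iz] = True
            order.append(np.asarray(new, dtype=np.int32))
            angles.append(angle)
            stale = 0
        else:
            stale += 1
            if stale > stale_limit:
                raise InfeasiblePatternError(
                    f"cannot reach sampled fraction {target:.3f} on a "
                    f"{n_phase} x {n_slice} grid with radial lines"
                )
        k += 1

    return SamplingMask(
        (n_phase, n_slice), sampled, float(undersampling_factor), order,
        golden_angle_deg, SCHEME_GOLDEN, angles,
    )


def generate_cartesian_mask(
    n_phase: int,
    n_slice: int,
    phase_factor: float,
    slice_factor: float = 1.0,
) -> SamplingMask:
    """Equally spaced Cartesian (parallel-imaging) under-sampling mask.

    Every ``round(phase_factor)``-th phase row is retained, starting at the
    row containing DC; analogously in the slice direction.  If rounding the
    spacing changes the effective factor by more than 10 %, a warning is
    recorded in the mask metadata.
    """
    for name, fac, dim in (
        ("phase_factor", phase_factor, n_phase),
        ("slice_factor", slice_factor, n_slice),
    ):
        if not (1 <= fac <= dim):
            raise InvalidParameterError(
                f"{name} must be in [1, {dim}], got {fac}"
            )
    sp = max(1, int(round(phase_factor)))
    ss = max(1, int(round(slice_factor)))
    dcp, dcs = n_phase // 2, n_slice // 2
    rows = np.arange(n_phase)[(np.arange(n_phase) - dcp) % sp == 0]
    cols = np.arange(n_slice)[(np.arange(n_slice) - dcs) % ss == 0]
    sampled = np.zeros((n_phase, n_slice), dtype=bool)
    sampled[np.ix_(rows, cols)] = True

    metadata = {"phase_spacing": sp, "slice_spacing": ss}
    warnings = []
    for name, fac, spacing in (
        ("phase", phase_factor, sp),
        ("slice", slice_factor, ss),
    ):
        if fac > 0 and abs(spacing - fac) / fac > 0.10:
            warnings.append(
                f"{name} spacing {spacing} deviates from requested factor "
                f"{fac} by more than 10%"
            )
    if warnings:
        metadata["warnings"] = warnings

    order = [
        np.stack(
            [np.full(cols.size, r, dtype=np.int32), cols.astype(np.int32)],
            axis=1,
        )
        for r in rows
    ]
    return SamplingMask(
        (n_phase, n_slice), sampled, float(phase_factor * slice_factor),
        order, golden_angle_deg=float("nan"), scheme=SCHEME_CARTESIAN,
        metadata=metadata,
    )


def generate_full_mask(n_phase: int, n_slice: int) -> SamplingMask:
    """Fully sampled mask (scheme ``full``)."""
    sampled = np.ones((n_phase, n_slice), dtype=bool)
    iy, iz = np.meshgrid(np.arange(n_phase), np.arange(n_slice), indexing="ij")
    order = [np.stack([iy.ravel(), iz.ravel()], axis=1).astype(np.int32)]
    return SamplingMask(
        (n_phase, n_slice), sampled, 1.0, order,
        golden_angle_deg=float("nan"), scheme=SCHEME_FULL,
    )


def compose_masks(a: SamplingMask, b: SamplingMask) -> SamplingMask:
    """Element-wise AND of two masks on the same grid (hybrid patterns)."""
    if a.grid_shape != b.grid_shape:
        raise InvalidParameterError("masks must share a grid shape")
    sampled = a.sampled & b.sampled
    order = []
    for group in a.acquisition_order:
        keep = sampled[group[:, 0], group[:, 1]]
        if np.any(keep):
            order.append(group[keep])
    frac = sampled.mean()
    factor = float("inf") if frac == 0 else 1.0 / frac
    return SamplingMask(
        a.grid_shape, sampled, factor, order, a.golden_angle_deg,
        scheme=f"{a.scheme}+{b.scheme}",
        line_angles_deg=list(a.line_angles_deg),
        metadata={"composed_from": (a.scheme, b.scheme)},
    )


def regular_phase_spacing(mask: SamplingMask) -> int:
    """Regular (parallel-imaging) row spacing of a mask's phase direction.

    Returns 1 for radial/full schemes; used to decide SENSE unfolding and
    g-factor weighting.
    """
    if mask.scheme == SCHEME_CARTESIAN:
        return int(mask.metadata.get("phase_spacing", 1))
    return 1
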
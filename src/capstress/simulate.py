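"""Synthetic uOCT B-scans and plaque-morphology sampling.

The B-scan generator renders each crystal as two bright horizontal ridges
(top/bottom surface reflections) separated by its optical thickness,
convolves with a Gaussian point-spread function at the instrument resolution
(1.3 um axial x 2.5 um transverse FWHM), and applies fully developed
multiplicative speckle — unit-mean exponential intensity noise — blended by
a contrast parameter, plus an additive background.  Exact physical ground
truth accompanies every image, so measurement tests never infer truth from
pixels.  The morphology sampler draws cap thickness uniformly over the
printed 25-370 um range and jitters the remaining parameters about their
printed means, resampling any draw that cannot be realized geometrically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import CAP_THICKNESS_RANGE_MM, GeometryError, MorphologyParams, derive_geometry
from .uoct import (
    AXIAL_PITCH_UM,
    AXIAL_RESOLUTION_UM,
    LATERAL_PITCH_UM,
    LATERAL_RESOLUTION_UM,
    REFRACTIVE_INDEX,
    BScan,
    CrystalMeasurement,
)

#: printed cohort statistics (mean, sample SD) of 20 measured crystals, um
COHORT_LENGTH_UM = (269.1, 80.16)
COHORT_THICKNESS_UM = (3.0, 0.33)

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

DEFAULT_SHAPE = (1024, 512)  # rows (depth) x cols (A-lines)


@dataclass(frozen=True)
class CrystalRender:
    """One crystal's placement on the pixel grid (rows/cols inclusive)."""

    row_top: int
    col_start: int
    col_end: int
    optical_thickness_px: int
    reflectivity: float = 1.0

    def __post_init__(self) -> None:
        if self.optical_thickness_px < 1 or self.col_end < self.col_start:
            raise ValueError("crystal must be at least 1 px thick and 1 px long")
        if self.reflectivity <= 0:
            raise ValueError("reflectivity must be > 0")


@dataclass
class SimSpec:
    """Scene + noise + calibration for one synthetic B-scan."""

    crystals: list[CrystalRender] = field(default_factory=list)
    background: float = 0.02
    speckle_contrast: float = 0.5
    axial_psf_um: float = AXIAL_RESOLUTION_UM  # FWHM, optical
    lateral_psf_um: float = LATERAL_RESOLUTION_UM  # FWHM
    lateral_pitch: float = LATERAL_PITCH_UM
    axial_pitch_optical: float = AXIAL_PITCH_UM
    refractive_index: float = REFRACTIVE_INDEX
    shape: tuple[int, int] = DEFAULT_SHAPE
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.speckle_contrast <= 1.0:
            raise ValueError("speckle_contrast must lie in [0, 1]")
        if self.background < 0:
            raise ValueError("background must be >= 0")


def render_crystal(
    length_um: float,
    thickness_um: float,
    row_top: int,
    col_start: int,
    reflectivity: float = 1.0,
    lateral_pitch: float = LATERAL_PITCH_UM,
    axial_pitch_optical: float = AXIAL_PITCH_UM,
    refractive_index: float = REFRACTIVE_INDEX,
) -> CrystalRender:
    """Quantize physical dimensions onto the pixel grid.

    The optical separation is ``thickness * n`` (axial pixels measure optical
    path); both extents round to whole pixels, the generator's ground truth
    reports the quantized values.
    """
    n_cols = max(1, round(length_um / lateral_pitch))
    sep_px = max(1, round(thickness_um * refractive_index / axial_pitch_optical))
    return CrystalRender(
        row_top=row_top,
        col_start=col_start,
        col_end=col_start + n_cols - 1,
        optical_thickness_px=sep_px,
        reflectivity=reflectivity,
    )


def simulate_bscan(spec: SimSpec) -> tuple[BScan, list[CrystalMeasurement]]:
    """Render a B-scan and return it with the exact physical ground truth."""
    rows, cols = spec.shape
    img = np.full((rows, cols), float(spec.background))
    truths: list[CrystalMeasurement] = []
    for c in spec.crystals:
        bottom = c.row_top + c.optical_thickness_px
        if not (0 <= c.row_top and bottom < rows and 0 <= c.col_start and c.col_end < cols):
            raise ValueError(f"crystal {c} out of bounds for image shape {spec.shape}")
        img[c.row_top, c.col_start : c.col_end + 1] += c.reflectivity
        img[bottom, c.col_start : c.col_end + 1] += c.reflectivity
        truths.append(
            CrystalMeasurement(
                length=(c.col_end - c.col_start + 1) * spec.lateral_pitch,
                thickness=c.optical_thickness_px * spec.axial_pitch_optical / spec.refractive_index,
                bbox=(c.row_top, bottom + 1, c.col_start, c.col_end + 1),
            )
        )
    sigma_ax = spec.axial_psf_um * FWHM_TO_SIGMA / spec.axial_pitch_optical
    sigma_lat = spec.lateral_psf_um * FWHM_TO_SIGMA / spec.lateral_pitch
    img = gaussian_filter(img, sigma=(sigma_ax, sigma_lat))
    if spec.speckle_contrast > 0:
        rng = np.random.default_rng(spec.seed)
        gain = (1.0 - spec.speckle_contrast) + spec.speckle_contrast * rng.exponential(
            1.0, size=img.shape
        )
        img = img * gain
    bscan = BScan(
        intensity=img,
        lateral_pitch=spec.lateral_pitch,
        axial_pitch_optical=spec.axial_pitch_optical,
        refractive_index=spec.refractive_index,
    )
    return bscan, truths


def sample_crystal_cohort(
    n: int = 20,
    seed: int = 0,
    length_um: tuple[float, float] = COHORT_LENGTH_UM,
    thickness_um: tuple[float, float] = COHORT_THICKNESS_UM,
    shape: tuple[int, int] = (256, 512),
    speckle_contrast: float = 0.5,
) -> list[SimSpec]:
    """One-crystal scenes with dimensions drawn from the cohort statistics.

    Lengths/thicknesses are normal draws at the printed mean and SD
    (truncated to stay physical and inside the frame); placement is uniform
    with a margin.  Each scene gets its own derived seed, so a cohort is
    reproducible from one (n, seed) pair.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    specs = []
    for i in range(n):
        length = float(np.clip(rng.normal(*length_um), 30.0, (cols - 8) * LATERAL_PITCH_UM))
        thickness = float(np.clip(rng.normal(*thickness_um), 1.2, 12.0))
        n_cols = max(1, round(length / LATERAL_PITCH_UM))
        col_start = int(rng.integers(4, cols - 4 - n_cols))
        row_top = int(rng.integers(16, rows - 32))
        specs.append(
            SimSpec(
                crystals=[
                    render_crystal(length, thickness, row_top=row_top, col_start=col_start)
                ],
                shape=shape,
                speckle_contrast=speckle_contrast,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def sample_morphology(
    seed: int,
    jitter: float = 0.1,
    base: MorphologyParams | None = None,
    max_retries: int = 100,
) -> MorphologyParams:
    """Random plaque morphology within the printed ranges.

    Cap thickness is uniform over the printed 25-370 um range; lumen area,
    core arc/area and stenosis severity are jittered uniformly +/- ``jitter``
    about their printed means.  Draws that cannot be realized (core annulus
    not fitting inside the vessel) are resampled up to ``max_retries``.
    """
    base = base or MorphologyParams()
    rng = np.random.default_rng(seed)
    lo, hi = CAP_THICKNESS_RANGE_MM
    for _ in range(max_retries):
        u = lambda v: v * (1.0 + jitter * (2.0 * rng.random() - 1.0))
        try:
            params = MorphologyParams(
                cap_thickness=float(lo + (hi - lo) * rng.random()),
                lumen_area=u(base.lumen_area),
                core_arc=min(u(base.core_arc), 359.0),
                core_area=u(base.core_area),
                relative_core_area=base.relative_core_area,
                relative_core_thickness=base.relative_core_thickness,
                stenosis_severity=min(u(base.stenosis_severity), 0.95),
                wall_thickness=base.wall_thickness,
            )
            derive_geometry(params)  # feasibility check
            return params
        except (GeometryError, ValueError):
            continue
    raise GeometryError(f"no feasible morphology found in {max_retries} draws (seed {seed})")
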
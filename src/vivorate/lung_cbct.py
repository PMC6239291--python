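"""Lung densitometry and healthy-lung volumetry on CT-like volumes.

Healthy lung tissue is delineated by auto-threshold contouring on mass
density (default window 0-0.7 g/cm^3, half-open), intersected with a body
mask and morphologically cleaned; its volume is the voxel count times the
voxel volume. Lung density is summarized by seven square regions of
interest in fixed fractional positions of the lung bounding box — four
1.5 mm ROIs in the apex, three 2.4 mm ROIs in the base — so that the same
anatomical locations are sampled at every timepoint. Digital two-lung
phantoms with analytic ground truth make the chain testable without
animal scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import brentq

__all__ = [
    "DensityVolume",
    "HuCalibration",
    "LungMask",
    "RoiBox",
    "VoxelRoi",
    "LungMetrics",
    "PhantomSpec",
    "PhantomTruth",
    "hu_to_density",
    "make_body_mask",
    "segment_healthy_lung",
    "compute_volume",
    "default_roi_spec",
    "place_rois",
    "measure_density",
    "compute_lung_metrics",
    "make_phantom",
]


@dataclass
class DensityVolume:
    """3-D grid of mass density in g/cm^3 with voxel spacing in mm.

    Axes are ordered (slice, row, col); world position = index x spacing.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if np.any(self.values < 0):
            raise ValueError("densities must be non-negative")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be 3 strictly positive values")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class HuCalibration:
    """Two-point linear HU -> density calibration (air and water anchors)."""

    hu_air: float = -1000.0
    hu_water: float = 0.0
    density_air: float = 0.0
    density_water: float = 1.0

    def __post_init__(self) -> None:
        if not self.hu_air < self.hu_water:
            raise ValueError("hu_air must be below hu_water")
        if not self.density_air < self.density_water:
            raise ValueError("density_air must be below density_water")


@dataclass
class LungMask:
    """Boolean voxel mask congruent with its source volume."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class RoiBox:
    """ROI request: fractional center within the lung bounding box.

    ``center`` is (slice, row, col) in [0, 1] fractions of the mask
    bounding box; ``size_mm`` is the in-plane square edge on the nearest
    axial slice.
    """

    label: str
    center: tuple[float, float, float]
    size_mm: float
    region: str = "apex"

    def __post_init__(self) -> None:
        if not all(0.0 <= c <= 1.0 for c in self.center):
            raise ValueError("fractional coordinates must lie in [0, 1]")
        if self.size_mm <= 0:
            raise ValueError("size_mm must be positive")
        if self.region not in ("apex", "base"):
            raise ValueError("region must be 'apex' or 'base'")


@dataclass
class VoxelRoi:
    """Placed ROI in voxel space: one axial slice, a square in-plane."""

    label: str
    slice_index: int
    row_slice: slice
    col_slice: slice
    clipped: bool = False


@dataclass
class LungMetrics:
    healthy_volume_cm3: float
    roi_densities: dict[str, float]
    mean_density: float


def hu_to_density(values_hu: np.ndarray, cal: HuCalibration | None = None) -> np.ndarray:
    """Map HU to mass density through the two calibration anchors, clipped at 0."""
    cal = cal or HuCalibration()
    slope = (cal.density_water - cal.density_air) / (cal.hu_water - cal.hu_air)
    density = cal.density_air + slope * (np.asarray(values_hu, dtype=float) - cal.hu_air)
    return np.maximum(density, 0.0)


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def make_body_mask(vol: DensityVolume, threshold: float = 0.9) -> LungMask:
    """Body = largest 26-connected component above ``threshold``, hole-filled.

    Hole filling (3-D) pulls the low-density lungs into the body mask,
    which separates them from the air surrounding the animal.
    """
    dense = vol.values >= threshold
    labels, n = ndi.label(dense, structure=_CONN26)
    if n == 0:
        return LungMask(np.zeros_like(dense), vol.spacing_mm)
    sizes = np.bincount(labels.ravel())[1:]
    body = labels == (1 + int(np.argmax(sizes)))
    body = ndi.binary_fill_holes(body)
    return LungMask(body, vol.spacing_mm)


def segment_healthy_lung(
    vol: DensityVolume,
    body: LungMask | None = None,
    lo: float = 0.0,
    hi: float = 0.7,
    max_components: int = 2,
) -> LungMask:
    """Auto-threshold healthy-lung segmentation.

    Voxels with ``lo <= density < hi`` (half-open, so exactly-soft-tissue
    voxels are excluded deterministically) inside the body mask, with
    slice-wise hole filling and retention of at most ``max_components``
    largest 26-connected components (two lungs).
    """
    if body is None:
        body = make_body_mask(vol)
    if body.values.shape != vol.values.shape:
        raise ValueError("body mask must be congruent with the volume")
    mask = (vol.values >= lo) & (vol.values < hi) & body.values
    if not mask.any():
        warnings.warn("healthy-lung segmentation is empty", stacklevel=2)
        return LungMask(mask, vol.spacing_mm)
    for k in range(mask.shape[0]):
        mask[k] = ndi.binary_fill_holes(mask[k])
    labels, n = ndi.label(mask, structure=_CONN26)
    if n > max_components:
        sizes = np.bincount(labels.ravel())[1:]
        keep = 1 + np.argsort(sizes)[::-1][:max_components]
        mask = np.isin(labels, keep)
    return LungMask(mask, vol.spacing_mm)


def compute_volume(mask: LungMask, spacing_mm: tuple[float, float, float] | None = None) -> float:
    """Mask volume in cm^3 (voxel count x voxel volume)."""
    spacing = spacing_mm or mask.spacing_mm
    return mask.voxel_count * float(np.prod(spacing)) / 1000.0


def default_roi_spec() -> list[RoiBox]:
    """Seven-ROI protocol: 4 x 1.5 mm in the apex, 3 x 2.4 mm in the base."""
    # Column fractions sit on the two lung axes (~0.21 and ~0.79 of the
    # bounding box), clear of the mediastinum; row offsets keep the square
    # ROIs inside the tapering elliptical cross-sections.
    apex = [
        RoiBox("apex_left_ant", (0.2, 0.40, 0.26), 1.5, "apex"),
        RoiBox("apex_right_ant", (0.2, 0.40, 0.74), 1.5, "apex"),
        RoiBox("apex_left_post", (0.2, 0.60, 0.26), 1.5, "apex"),
        RoiBox("apex_right_post", (0.2, 0.60, 0.74), 1.5, "apex"),
    ]
    base = [
        RoiBox("base_left", (0.75, 0.50, 0.21), 2.4, "base"),
        RoiBox("base_left_post", (0.75, 0.64, 0.21), 2.4, "base"),
        RoiBox("base_right", (0.75, 0.50, 0.79), 2.4, "base"),
    ]
    return apex + base


def place_rois(mask: LungMask, spec: list[RoiBox] | None = None) -> list[VoxelRoi]:
    """Anchor ROI requests to the lung-mask bounding box.

    Placement is deterministic for a given mask and equivariant under
    whole-voxel translations, which realizes the "same positions at every
    timepoint" contract without manual input.
    """
    spec = spec if spec is not None else default_roi_spec()
    if not mask.values.any():
        raise ValueError("cannot place ROIs on an empty mask")
    nz = np.nonzero(mask.values)
    lo = np.array([c.min() for c in nz], dtype=float)
    hi = np.array([c.max() for c in nz], dtype=float)
    shape = mask.values.shape
    placed: list[VoxelRoi] = []
    for box in spec:
        center = lo + np.asarray(box.center) * (hi - lo)
        k = int(round(center[0]))
        n_r = max(1, int(round(box.size_mm / mask.spacing_mm[1])))
        n_c = max(1, int(round(box.size_mm / mask.spacing_mm[2])))
        r0 = int(round(center[1] - n_r / 2.0))
        c0 = int(round(center[2] - n_c / 2.0))
        r1, c1 = r0 + n_r, c0 + n_c
        clipped = r0 < 0 or c0 < 0 or r1 > shape[1] or c1 > shape[2] or k < 0 or k >= shape[0]
        if clipped:
            warnings.warn(f"ROI {box.label} extends outside the volume; clipping", stacklevel=2)
        k = int(np.clip(k, 0, shape[0] - 1))
        placed.append(
            VoxelRoi(
                label=box.label,
                slice_index=k,
                row_slice=slice(max(r0, 0), min(r1, shape[1])),
                col_slice=slice(max(c0, 0), min(c1, shape[2])),
                clipped=bool(clipped),
            )
        )
    return placed


def measure_density(vol: DensityVolume, rois: list[VoxelRoi]) -> tuple[dict[str, float], float]:
    """Per-ROI mean density and their unweighted mean."""
    densities: dict[str, float] = {}
    for roi in rois:
        patch = vol.values[roi.slice_index, roi.row_slice, roi.col_slice]
        if patch.size == 0:
            raise ValueError(f"ROI {roi.label} is empty after clipping")
        densities[roi.label] = float(patch.mean())
    return densities, float(np.mean(list(densities.values())))


def compute_lung_metrics(
    vol: DensityVolume,
    body: LungMask | None = None,
    roi_spec: list[RoiBox] | None = None,
    lo: float = 0.0,
    hi: float = 0.7,
) -> LungMetrics:
    """Full per-scan summary: segment, measure volume, place and read ROIs."""
    mask = segment_healthy_lung(vol, body=body, lo=lo, hi=hi)
    volume = compute_volume(mask)
    rois = place_rois(mask, roi_spec)
    densities, mean_density = measure_density(vol, rois)
    return LungMetrics(
        healthy_volume_cm3=volume, roi_densities=densities, mean_density=mean_density
    )


# ---------------------------------------------------------------------------
# Digital phantom


@dataclass(frozen=True)
class PhantomSpec:
    """Two-lung ellipsoid phantom inside a soft-tissue body ellipsoid.

    Lungs are prolate ellipsoids with their long axis along the slice
    axis; geometry in mm. ``injury_fraction`` converts the apex-side cap
    of the chosen lung (that volume fraction of it) to ``injury_density``,
    emulating the dense consolidation of radiation pneumonitis.
    """

    spacing_mm: tuple[float, float, float] = (0.2, 0.2, 0.2)
    extent_mm: tuple[float, float, float] = (24.0, 16.0, 20.0)
    body_semiaxes_mm: tuple[float, float, float] = (11.0, 6.5, 8.5)
    lung_semiaxes_mm: tuple[float, float, float] = (8.0, 3.0, 3.0)
    lung_offset_mm: float = 4.0          # lateral (col) offset of each lung center
    body_density: float = 1.06
    lung_density: float = 0.40
    injury_fraction: float = 0.0         # volume fraction of the injured lung
    injured_lung: str = "left"
    injury_density: float = 0.90
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.injury_fraction <= 1.0:
            raise ValueError("injury_fraction must lie in [0, 1]")
        if self.injured_lung not in ("left", "right"):
            raise ValueError("injured_lung must be 'left' or 'right'")
        if self.lung_offset_mm < self.lung_semiaxes_mm[2]:
            raise ValueError("lungs overlap: offset smaller than lateral semi-axis")
        for ax in range(3):
            if 2 * self.body_semiaxes_mm[ax] > self.extent_mm[ax]:
                raise ValueError("body ellipsoid does not fit in the grid extent")


@dataclass
class PhantomTruth:
    """Closed-form ground truth for a rendered phantom."""

    lung_volume_cm3: float          # analytic healthy-lung volume (both lungs)
    single_lung_volume_cm3: float
    injured_volume_cm3: float
    lung_density: float
    body_density: float
    lung_centers_mm: list[tuple[float, float, float]]


def _cap_height_fraction(volume_fraction: float) -> float:
    """Normalized plane position u in [-1, 1] cutting off ``volume_fraction``.

    The fraction of an ellipsoid's volume with normalized axial coordinate
    below u is F(u) = (2 + 3u - u^3) / 4; this inverts F.
    """
    if volume_fraction <= 0.0:
        return -1.0
    if volume_fraction >= 1.0:
        return 1.0
    return brentq(lambda u: (2 + 3 * u - u**3) / 4 - volume_fraction, -1.0, 1.0)


def make_phantom(spec: PhantomSpec | None = None) -> tuple[DensityVolume, PhantomTruth]:
    """Render a phantom volume and its analytic ground truth.

    Identical specs (including seed) produce identical volumes.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(round(e / s)) for e, s in zip(spec.extent_mm, spec.spacing_mm))
    # Broadcastable world-coordinate grids keep memory use modest.
    world = [
        (np.arange(shape[a]) * spec.spacing_mm[a]).reshape(
            [-1 if ax == a else 1 for ax in range(3)]
        )
        for a in range(3)
    ]
    center = [0.5 * (n - 1) * s for n, s in zip(shape, spec.spacing_mm)]

    def ellipsoid(c, semi):
        return (
            ((world[0] - c[0]) / semi[0]) ** 2
            + ((world[1] - c[1]) / semi[1]) ** 2
            + ((world[2] - c[2]) / semi[2]) ** 2
            <= 1.0
        )

    vol = np.zeros(shape)
    body = ellipsoid(center, spec.body_semiaxes_mm)
    vol[body] = spec.body_density

    a, b, c = spec.lung_semiaxes_mm  # (slice, row, col) semi-axes
    centers = {
        "left": (center[0], center[1], center[2] - spec.lung_offset_mm),
        "right": (center[0], center[1], center[2] + spec.lung_offset_mm),
    }
    lung_masks = {side: ellipsoid(cc, (a, b, c)) for side, cc in centers.items()}
    for m in lung_masks.values():
        vol[m] = spec.lung_density

    single_vol_mm3 = 4.0 / 3.0 * np.pi * a * b * c
    injured_mm3 = spec.injury_fraction * single_vol_mm3
    if spec.injury_fraction > 0:
        u = _cap_height_fraction(spec.injury_fraction)
        cc = centers[spec.injured_lung]
        cap = lung_masks[spec.injured_lung] & ((world[0] - cc[0]) / a <= u)
        vol[cap] = spec.injury_density

    if spec.noise_sd > 0:
        vol = vol + spec.noise_sd * rng.standard_normal(shape)
    vol = np.maximum(vol, 0.0)

    truth = PhantomTruth(
        lung_volume_cm3=(2 * single_vol_mm3 - injured_mm3) / 1000.0,
        single_lung_volume_cm3=single_vol_mm3 / 1000.0,
        injured_volume_cm3=injured_mm3 / 1000.0,
        lung_density=spec.lung_density,
        body_density=spec.body_density,
        lung_centers_mm=list(centers.values()),
    )
    return DensityVolume(vol, spec.spacing_mm), truth
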
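"""Canonical analysis grid, the synthetic 23-region striatal atlas, and region masking.

The quantification workflow lives on a fixed, MNI152-like voxel grid
(91 x 109 x 91 voxels, 2 mm isotropic, right-anterior-superior axis order).
Because the anatomical atlas used by real dopamine-transporter pipelines is not
redistributable, this module builds a geometric stand-in: per hemisphere, nine
basal-ganglia subregions (pre/post caudate, four putamen subdivisions,
accumbens, globus pallidus, ventral pallidum) painted as ellipsoids inside
nested tissue shells (grey matter, cerebral white matter, CSF, skull, soft
tissue), for 23 base regions in total.  All downstream mathematics (template
construction, registration, specific-binding-ratio quantification) is
shape-agnostic; the ellipsoid geometry is configuration, not science.

Regions are painted in a fixed, documented order and later paint never
overwrites earlier labels, so base regions are disjoint by construction.
Composites (caudate, pre-/post-commissural putamen, putamen, striatum) are
defined as unions of base-region label codes, available per side or bilateral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "GridSpec",
    "Volume",
    "RegionInfo",
    "RegionAtlas",
    "AtlasError",
    "RegionLookupError",
    "build_synthetic_atlas",
    "region_mask",
    "REPORT_REGIONS",
    "REFERENCE_REGION",
]


class AtlasError(ValueError):
    """Raised when an atlas cannot be constructed on the requested grid."""


class RegionLookupError(KeyError):
    """Raised when a region name/side pair is not defined in the atlas."""


@dataclass(frozen=True)
class GridSpec:
    """A fixed voxel grid with isotropic-or-not physical voxel size.

    World coordinates are millimetres with the origin at the grid centre,
    x increasing to the right, y to anterior, z to superior.
    """

    shape: tuple[int, int, int] = (91, 109, 91)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")

    @property
    def center_voxel(self) -> np.ndarray:
        return (np.asarray(self.shape, dtype=float) - 1.0) / 2.0

    @property
    def fov_mm(self) -> np.ndarray:
        """Physical field of view per axis."""
        return np.asarray(self.shape, dtype=float) * np.asarray(self.voxel_size_mm)

    def world_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world (mm) coordinates of voxel centres."""
        c = self.center_voxel
        v = self.voxel_size_mm
        return tuple(
            (np.arange(n, dtype=float) - c[i]) * v[i] for i, n in enumerate(self.shape)
        )

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return (ijk - self.center_voxel) * np.asarray(self.voxel_size_mm)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz / np.asarray(self.voxel_size_mm) + self.center_voxel

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (NIfTI convention)."""
        a = np.eye(4)
        a[:3, :3] = np.diag(self.voxel_size_mm)
        a[:3, 3] = -self.center_voxel * np.asarray(self.voxel_size_mm)
        return a


@dataclass
class Volume:
    """A 3-D scalar field on a :class:`GridSpec`."""

    data: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got ndim={self.data.ndim}")
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite values")

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return self.grid.voxel_size_mm

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.grid)

    def sum(self) -> float:
        return float(self.data.sum())


@dataclass(frozen=True)
class RegionInfo:
    code: int
    name: str
    side: str  # "left" | "right" | "none"
    region_class: str  # "target-subregion" | "reference" | "other-tissue"


# The 5 regions reported by the quantification pipeline, coarsest to finest.
REPORT_REGIONS = (
    "striatum",
    "putamen",
    "caudate",
    "pre_commissural_putamen",
    "post_commissural_putamen",
)
REFERENCE_REGION = "cerebral_white_matter"

# Head geometry (mm, semi-axes of nested ellipsoids centred on the grid origin).
# Chosen so that even the outermost soft-tissue shell keeps a >= 25 mm margin to
# the default grid edge: with 12 mm FWHM smoothing that margin is ~5 sigma, so
# zero boundary effects reach the head and smoothing conserves mass.
BRAIN_RADII = np.array([58.0, 72.0, 58.0])
_GREY_INNER = 17.0  # grey-matter ribbon: brain surface - 17 .. - 5 mm
_CSF_INNER = 5.0
_SKULL_OUTER = 4.0
_SOFT_OUTER = 8.0

# Basal-ganglia ellipsoids: (name, |x|-centre, y, z, rx, ry, rz), right side;
# the left side mirrors x.  Proportions loosely follow basal-ganglia anatomy.
_BG_BLOBS: tuple[tuple[str, float, float, float, float, float, float], ...] = (
    ("pre_caudate", 13.0, 12.0, 8.0, 5.0, 8.0, 7.0),
    ("post_caudate", 16.0, -6.0, 12.0, 4.5, 9.0, 6.0),
    ("pre_dorsal_putamen", 24.0, 6.0, 6.0, 5.0, 7.0, 6.0),
    ("pre_ventral_putamen", 24.0, 6.0, -4.0, 5.0, 7.0, 5.0),
    ("post_dorsal_putamen", 28.0, -6.0, 6.0, 5.0, 7.0, 6.0),
    ("post_ventral_putamen", 28.0, -6.0, -4.0, 5.0, 7.0, 5.0),
    ("accumbens", 9.0, 12.0, -8.0, 4.0, 5.0, 4.0),
    ("globus_pallidus", 19.0, -2.0, 0.0, 4.5, 6.0, 5.0),
    ("ventral_pallidum", 11.0, 2.0, -8.0, 4.0, 5.0, 4.0),
)

_TISSUE_REGIONS = (
    "grey_matter",
    "cerebral_white_matter",
    "csf",
    "skull",
    "soft_tissue",
)

# Composite -> member base-region names (per side).
_COMPOSITES: dict[str, tuple[str, ...]] = {
    "caudate": ("pre_caudate", "post_caudate"),
    "pre_commissural_putamen": ("pre_dorsal_putamen", "pre_ventral_putamen"),
    "post_commissural_putamen": ("post_dorsal_putamen", "post_ventral_putamen"),
    "putamen": (
        "pre_dorsal_putamen",
        "pre_ventral_putamen",
        "post_dorsal_putamen",
        "post_ventral_putamen",
    ),
    "striatum": (
        "pre_caudate",
        "post_caudate",
        "pre_dorsal_putamen",
        "pre_ventral_putamen",
        "post_dorsal_putamen",
        "post_ventral_putamen",
    ),
    # union of every target subregion; used e.g. for registration weighting
    "basal_ganglia": tuple(name for name, *_ in _BG_BLOBS),
}


@dataclass
class RegionAtlas:
    """Integer label field plus region table and composite hierarchy."""

    labels: np.ndarray
    grid: GridSpec
    region_table: dict[int, RegionInfo]
    composites: dict[str, dict[str, frozenset[int]]]  # name -> side -> codes

    def codes_for(self, region: str, side: str = "bilateral") -> frozenset[int]:
        """Label codes making up ``region`` on ``side``.

        ``side`` may be "left", "right" or "bilateral"; tissue classes carry no
        side and are returned for any side request.
        """
        if side not in ("left", "right", "bilateral"):
            raise RegionLookupError(f"unknown side {side!r}")
        if region in self.composites:
            per_side = self.composites[region]
            if side == "bilateral":
                return frozenset().union(*per_side.values())
            return per_side[side]
        # base region lookup by (name, side)
        codes = [
            info.code
            for info in self.region_table.values()
            if info.name == region
            and (info.side == "none" or side == "bilateral" or info.side == side)
        ]
        if not codes:
            raise RegionLookupError(f"unknown region {region!r} (side={side!r})")
        return frozenset(codes)

    def mask(self, region: str, side: str = "bilateral") -> np.ndarray:
        """Boolean voxel mask for a base or composite region."""
        codes = self.codes_for(region, side)
        return np.isin(self.labels, list(codes))

    @property
    def target_codes(self) -> frozenset[int]:
        return frozenset(
            info.code
            for info in self.region_table.values()
            if info.region_class == "target-subregion"
        )

    def head_mask(self) -> np.ndarray:
        return self.labels > 0

    def region_names(self) -> list[str]:
        seen: list[str] = []
        for info in self.region_table.values():
            if info.name not in seen:
                seen.append(info.name)
        return seen


def _ellipsoid_level(axes: tuple[np.ndarray, np.ndarray, np.ndarray],
                     center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    x, y, z = axes
    return (
        ((x[:, None, None] - center[0]) / radii[0]) ** 2
        + ((y[None, :, None] - center[1]) / radii[1]) ** 2
        + ((z[None, None, :] - center[2]) / radii[2]) ** 2
    )


def build_synthetic_atlas(grid: GridSpec | None = None) -> RegionAtlas:
    """Build the synthetic 23-region atlas on ``grid`` (default canonical grid).

    Deterministic: identical grids yield identical label fields.  Raises
    :class:`AtlasError` if the grid cannot hold the head with a smoothing-safe
    margin.
    """
    grid = grid or GridSpec()
    outer = BRAIN_RADII + _SOFT_OUTER
    half_fov = grid.fov_mm / 2.0
    margin = half_fov - outer
    if np.any(margin < 2.0 * np.asarray(grid.voxel_size_mm)):
        raise AtlasError(
            f"grid {grid.shape} @ {grid.voxel_size_mm} mm too small: head extent "
            f"{outer} mm needs a margin inside half-FOV {half_fov} mm"
        )

    axes = grid.world_axes()
    labels = np.zeros(grid.shape, dtype=np.int16)
    table: dict[int, RegionInfo] = {}
    code = 0

    # 1) basal-ganglia subregions, right then left per blob, fixed order
    for name, cx, cy, cz, rx, ry, rz in _BG_BLOBS:
        for side, sx in (("right", 1.0), ("left", -1.0)):
            code += 1
            center = np.array([sx * cx, cy, cz])
            radii = np.array([rx, ry, rz])
            lev = _ellipsoid_level(axes, center, radii)
            sel = (lev <= 1.0) & (labels == 0)
            if not sel.any():
                raise AtlasError(f"region {name} ({side}) is empty on this grid")
            labels[sel] = code
            table[code] = RegionInfo(code, name, side, "target-subregion")

    brain = _ellipsoid_level(axes, np.zeros(3), BRAIN_RADII)
    grey_in = _ellipsoid_level(axes, np.zeros(3), BRAIN_RADII - _GREY_INNER)
    csf_in = _ellipsoid_level(axes, np.zeros(3), BRAIN_RADII - _CSF_INNER)
    skull_out = _ellipsoid_level(axes, np.zeros(3), BRAIN_RADII + _SKULL_OUTER)
    soft_out = _ellipsoid_level(axes, np.zeros(3), BRAIN_RADII + _SOFT_OUTER)

    shells = {
        "grey_matter": (grey_in > 1.0) & (csf_in <= 1.0),
        "cerebral_white_matter": grey_in <= 1.0,
        "csf": (csf_in > 1.0) & (brain <= 1.0),
        "skull": (brain > 1.0) & (skull_out <= 1.0),
        "soft_tissue": (skull_out > 1.0) & (soft_out <= 1.0),
    }
    for name in _TISSUE_REGIONS:
        code += 1
        sel = shells[name] & (labels == 0)
        if not sel.any():
            raise AtlasError(f"tissue class {name} is empty on this grid")
        labels[sel] = code
        cls = "reference" if name == REFERENCE_REGION else "other-tissue"
        table[code] = RegionInfo(code, name, "none", cls)

    name_side_to_code = {(info.name, info.side): info.code for info in table.values()}
    composites: dict[str, dict[str, frozenset[int]]] = {}
    for comp, members in _COMPOSITES.items():
        composites[comp] = {
            side: frozenset(name_side_to_code[(m, side)] for m in members)
            for side in ("left", "right")
        }

    atlas = RegionAtlas(labels, grid, table, composites)
    # sanity: the reference region must not touch any target subregion
    assert not (atlas.mask(REFERENCE_REGION) & atlas.mask("basal_ganglia")).any()
    return atlas


def region_mask(atlas: RegionAtlas, region: str, side: str = "bilateral") -> Volume:
    """Binary mask as a :class:`Volume` (1 inside the region, 0 elsewhere)."""
    return Volume(atlas.mask(region, side).astype(float), atlas.grid)
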
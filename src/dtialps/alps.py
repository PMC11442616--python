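"""ALPS-index and tumor-ADC extraction from fitted tensor fields.

The ALPS (analysis along the perivascular space) index summarises water
diffusivity along the perivascular direction at the level of the lateral
ventricles.  With x = right-left, the periventricular medullary veins (and
their perivascular spaces) run along x; projection fibers run along z and
association fibers along y.  The index is

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

i.e. the mean of the two diffusivities perpendicular to the dominant fiber
direction but along the perivascular direction, over the mean of the two
perpendicular-to-both diffusivities.  An index near 1 means no preferential
diffusion along the perivascular axis.

ROIs are explicit inputs: 0-based voxel start corners with half-open
extents.  Projection/association ROIs default to the standard 2 x 2 voxels
on one slice; a heuristic :func:`suggest_roi` is provided as an advisory
helper only and is never applied when explicit ROIs are given.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io import ScalarMap
from .tensor import DiffusionTensorField

__all__ = [
    "RoiSpec",
    "AlpsMeasurement",
    "roi_mean_diffusivities",
    "compute_alps_index",
    "alps_from_rois",
    "tumor_roi_adc",
    "suggest_roi",
    "read_roi_sidecar",
    "write_roi_sidecar",
]

ROI_KINDS = ("projection", "association", "tumor")
HEMISPHERES = ("ipsilateral", "contralateral", "left", "right")
STANDARD_ALPS_ROI_SIZE = (2, 2, 1)


@dataclass(frozen=True)
class RoiSpec:
    """A box ROI: 0-based start corner, half-open size in voxels.

    Projection and association ROIs are pinned to 2 x 2 voxels on a single
    slice (the standard 4 x 4 mm in-plane footprint at 2 mm voxels) unless
    ``allow_nonstandard_size`` is set.
    """

    kind: str
    start_voxel: tuple
    size_voxels: tuple
    hemisphere: str = "left"
    allow_nonstandard_size: bool = False

    def __post_init__(self):
        if self.kind not in ROI_KINDS:
            raise ValueError(f"unknown ROI kind {self.kind!r}; expected one of {ROI_KINDS}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        start = tuple(int(v) for v in self.start_voxel)
        size = tuple(int(v) for v in self.size_voxels)
        object.__setattr__(self, "start_voxel", start)
        object.__setattr__(self, "size_voxels", size)
        if len(start) != 3 or len(size) != 3:
            raise ValueError("start_voxel and size_voxels must have 3 components")
        if any(s < 1 for s in size):
            raise ValueError("size_voxels must be >= 1 in every dimension")
        if any(v < 0 for v in start):
            raise ValueError("start_voxel must be non-negative (0-based indexing)")
        if (self.kind in ("projection", "association")
                and size != STANDARD_ALPS_ROI_SIZE and not self.allow_nonstandard_size):
            raise ValueError(
                f"{self.kind} ROI must be {STANDARD_ALPS_ROI_SIZE} voxels "
                "(set allow_nonstandard_size to override)"
            )

    @property
    def slices(self) -> tuple:
        return tuple(slice(a, a + s) for a, s in zip(self.start_voxel, self.size_voxels))

    def check_within(self, grid_shape: tuple) -> None:
        for axis, (a, s, n) in enumerate(zip(self.start_voxel, self.size_voxels, grid_shape)):
            if a + s > n:
                raise ValueError(
                    f"ROI out of bounds on axis {axis}: [{a}, {a + s}) exceeds grid size {n}"
                )


@dataclass(frozen=True)
class AlpsMeasurement:
    """The four ROI-mean diffusivities (mm^2/s) and the resulting index."""

    dxx_proj: float
    dxx_assoc: float
    dyy_proj: float
    dzz_assoc: float
    index: float


def roi_mean_diffusivities(tensors: DiffusionTensorField, roi: RoiSpec) -> dict:
    """Arithmetic mean of each tensor element over the ROI voxels."""
    roi.check_within(tensors.grid_shape)
    sl = roi.slices
    if not np.all(tensors.mask[sl]):
        raise ValueError("ROI intersects voxels outside the fitted mask")
    return {
        name: float(tensors.element(name)[sl].mean())
        for name in ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")
    }


def compute_alps_index(proj: dict, assoc: dict) -> AlpsMeasurement:
    """ALPS index from projection- and association-ROI element means.

    ``proj`` and ``assoc`` are mappings with at least ``Dxx``/``Dyy`` resp.
    ``Dxx``/``Dzz`` entries, as produced by :func:`roi_mean_diffusivities`.
    """
    try:
        dxx_p, dyy_p = float(proj["Dxx"]), float(proj["Dyy"])
        dxx_a, dzz_a = float(assoc["Dxx"]), float(assoc["Dzz"])
    except KeyError as exc:
        raise ValueError(f"missing diffusivity {exc} in ROI means") from None
    vals = (dxx_p, dxx_a, dyy_p, dzz_a)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("non-finite diffusivity in ROI means")
    denominator = (dyy_p + dzz_a) / 2.0
    if denominator <= 0:
        raise ValueError(f"non-positive denominator mean(Dyy_proj, Dzz_assoc) = {denominator:g}")
    numerator = (dxx_p + dxx_a) / 2.0
    return AlpsMeasurement(
        dxx_proj=dxx_p, dxx_assoc=dxx_a, dyy_proj=dyy_p, dzz_assoc=dzz_a,
        index=numerator / denominator,
    )


def alps_from_rois(tensors: DiffusionTensorField, projection_roi: RoiSpec,
                   association_roi: RoiSpec) -> AlpsMeasurement:
    """Convenience: ROI means of both regions, then the index."""
    proj = roi_mean_diffusivities(tensors, projection_roi)
    assoc = roi_mean_diffusivities(tensors, association_roi)
    return compute_alps_index(proj, assoc)


def tumor_roi_adc(adc: ScalarMap, center_mm, area_mm2: float = 5.3) -> float:
    """Mean ADC over a circular in-plane ROI centred on the tumor.

    The circle of the given area (default 5.3 mm^2) lies on the single slice
    nearest ``center_mm[2]``; it is rasterized to voxels whose in-plane
    centers fall within the circle radius, and the voxel containing the
    center is always included — so a sub-voxel area yields exactly the
    center voxel's value.
    """
    center = np.asarray(center_mm, dtype=float).ravel()
    if center.shape != (3,):
        raise ValueError("center_mm must be a 3-vector (mm)")
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be positive")
    vs = adc.voxel_size
    shape = adc.data.shape
    idx_center = np.floor(center / vs).astype(int)
    if np.any(idx_center < 0) or np.any(idx_center >= np.asarray(shape)):
        raise ValueError(f"ROI center {center.tolist()} mm lies outside the image grid")

    radius = math.sqrt(area_mm2 / math.pi)
    k = int(idx_center[2])
    # in-plane voxel-center coordinates on the slice
    xs = (np.arange(shape[0]) + 0.5) * vs[0]
    ys = (np.arange(shape[1]) + 0.5) * vs[1]
    dist2 = (xs[:, None] - center[0]) ** 2 + (ys[None, :] - center[1]) ** 2
    inside = dist2 <= radius**2
    inside[idx_center[0], idx_center[1]] = True  # center voxel always counts
    return float(adc.data[:, :, k][inside].mean())


def suggest_roi(fa: ScalarMap, tensors: DiffusionTensorField, hemisphere: str,
                slice_index: int, fa_threshold: float = 0.2) -> tuple:
    """Advisory 2x2 ROI placement from fiber orientation on one slice.

    Scans all 2x2 windows in the requested hemisphere half of the slice
    (x axis runs right -> left: the 'right' hemisphere is the low-x half)
    whose four voxels all pass ``FA >= fa_threshold``, and returns the pair
    (projection, association) of :class:`RoiSpec` maximizing the mean
    absolute alignment of the principal eigenvector with z resp. y.

    Advisory only: pipelines must never substitute this for explicit ROIs.
    """
    if hemisphere not in ("left", "right"):
        raise ValueError("hemisphere must be 'left' or 'right'")
    nx, ny, nz = tensors.grid_shape
    if not 0 <= slice_index < nz:
        raise ValueError(f"slice_index {slice_index} outside grid of {nz} slices")
    x_range = range(0, nx // 2 - 1) if hemisphere == "right" else range(nx - nx // 2, nx - 1)

    fa_slice = fa.data[:, :, slice_index]
    v1 = tensors.principal_direction()[:, :, slice_index]  # (nx, ny, 3)
    best = {"projection": (-1.0, None), "association": (-1.0, None)}
    for x0 in x_range:
        for y0 in range(ny - 1):
            window_fa = fa_slice[x0:x0 + 2, y0:y0 + 2]
            if not np.all(window_fa >= fa_threshold):
                continue
            w = v1[x0:x0 + 2, y0:y0 + 2]  # (2, 2, 3)
            score_z = float(np.abs(w[..., 2]).mean())
            score_y = float(np.abs(w[..., 1]).mean())
            if score_z > best["projection"][0]:
                best["projection"] = (score_z, (x0, y0))
            if score_y > best["association"][0]:
                best["association"] = (score_y, (x0, y0))
    if best["projection"][1] is None or best["association"][1] is None:
        raise ValueError(
            f"no candidate window: no 2x2 region with FA >= {fa_threshold} "
            f"in the {hemisphere} half of slice {slice_index}"
        )
    out = []
    for kind in ("projection", "association"):
        x0, y0 = best[kind][1]
        out.append(RoiSpec(kind=kind, start_voxel=(x0, y0, slice_index),
                           size_voxels=STANDARD_ALPS_ROI_SIZE, hemisphere=hemisphere))
    return tuple(out)


def write_roi_sidecar(rois, destination) -> None:
    """Serialize ROIs as the JSON sidecar list of {kind, hemisphere, start, size}."""
    payload = [
        {"kind": r.kind, "hemisphere": r.hemisphere,
         "start_voxel": list(r.start_voxel), "size_voxels": list(r.size_voxels)}
        for r in rois
    ]
    Path(destination).write_text(json.dumps(payload, indent=1))


def read_roi_sidecar(source) -> list:
    entries = json.loads(Path(source).read_text())
    return [
        RoiSpec(kind=e["kind"], hemisphere=e.get("hemisphere", "left"),
                start_voxel=tuple(e["start_voxel"]), size_voxels=tuple(e["size_voxels"]),
                allow_nonstandard_size=bool(e.get("allow_nonstandard_size", False)))
        for e in entries
    ]
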
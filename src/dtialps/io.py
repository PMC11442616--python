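"""Reading and writing of DWI data in standard neuroimaging formats.

Volumes are NIfTI-1 (via nibabel); diffusion-encoding schemes are FSL-style
``.bval``/``.bvec`` text files.  b-vectors are interpreted in the image
coordinate frame with the fixed axis convention x = right-left,
y = anterior-posterior, z = feet-head; no reorientation by the NIfTI affine
is performed, so phantom simulation and tensor fitting share one frame.
Voxel indexing is 0-based throughout, with half-open box extents
``[start, start + size)``.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

import nibabel as nib
import numpy as np

__all__ = [
    "GradientTable",
    "DWIVolume",
    "ScalarMap",
    "SCALAR_KINDS",
    "read_gradient_table",
    "write_gradient_table",
    "read_dwi",
    "write_dwi",
    "read_scalar_map",
    "write_scalar_map",
]

#: tolerance on the Euclidean norm of a diffusion-weighted b-vector
BVEC_NORM_TOL = 1e-3

SCALAR_KINDS = ("FA", "ADC", "S0", "Dxx", "Dyy", "Dzz", "MD")

PathOrStream = Union[str, Path, IO]


class GradientTableError(ValueError):
    """Invalid or inconsistent diffusion-encoding scheme."""


@dataclass(frozen=True)
class GradientTable:
    """A diffusion-encoding scheme: b-values (s/mm^2) and unit directions.

    Directions are direction cosines in the image frame.  Entries with
    ``bval == 0`` may carry zero vectors; every diffusion-weighted entry
    must be a unit vector to within ``BVEC_NORM_TOL``.
    """

    bvals: np.ndarray
    bvecs: np.ndarray  # shape (n, 3)

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise GradientTableError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise GradientTableError(
                f"count mismatch: {len(bvals)} b-values vs {len(bvecs)} b-vectors"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        norms = np.linalg.norm(bvecs, axis=1)
        dw = bvals > 0
        bad = dw & (np.abs(norms - 1.0) > BVEC_NORM_TOL)
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise GradientTableError(
                f"b-vector {i} has norm {norms[i]:.6f}, expected 1 within {BVEC_NORM_TOL}"
            )

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0

    def validate_for_fit(self) -> None:
        """Require >= 1 b=0 entry and a full-rank tensor design.

        The log-linear tensor fit needs at least six diffusion-weighted
        directions whose outer-product design matrix has rank 6 (i.e. six
        non-collinear directions).
        """
        if not np.any(self.b0_mask):
            raise GradientTableError("scheme has no b=0 entry")
        g = self.bvecs[self.dwi_mask]
        if len(g) < 6:
            raise GradientTableError(
                f"scheme has only {len(g)} diffusion-weighted directions, need >= 6"
            )
        design = _tensor_design(g)
        if np.linalg.matrix_rank(design) < 6:
            raise GradientTableError("rank-deficient: directions do not span 6 tensor dof")


def _tensor_design(g: np.ndarray) -> np.ndarray:
    """Rows [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz] for each direction."""
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz]
    )


def _read_numeric_rows(source: PathOrStream, what: str) -> list[list[float]]:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
        if isinstance(text, bytes):
            text = text.decode()
    rows = []
    for line in text.splitlines():
        tokens = line.split()
        if not tokens:
            continue
        try:
            rows.append([float(t) for t in tokens])
        except ValueError as exc:
            raise GradientTableError(f"non-numeric token in {what}: {exc}") from None
    return rows


def read_gradient_table(bval_source: PathOrStream, bvec_source: PathOrStream) -> GradientTable:
    """Read an FSL-dialect ``.bval``/``.bvec`` pair.

    The bval file is one whitespace-separated row of N numbers; the bvec
    file is three rows of N numbers (x, y, z components).  Directions that
    are already unit-norm are kept verbatim — no re-normalisation.
    """
    bval_rows = _read_numeric_rows(bval_source, "bval file")
    bvec_rows = _read_numeric_rows(bvec_source, "bvec file")
    if len(bval_rows) != 1:
        raise GradientTableError(f"bval file must have 1 row, got {len(bval_rows)}")
    if len(bvec_rows) != 3:
        raise GradientTableError(f"bvec file must have 3 rows, got {len(bvec_rows)}")
    bvals = np.asarray(bval_rows[0])
    lengths = {len(r) for r in bvec_rows}
    if len(lengths) != 1 or lengths.pop() != len(bvals):
        raise GradientTableError(
            f"count mismatch: {len(bvals)} b-values vs bvec rows of lengths "
            f"{[len(r) for r in bvec_rows]}"
        )
    bvecs = np.asarray(bvec_rows).T
    return GradientTable(bvals=bvals, bvecs=bvecs)


def write_gradient_table(table: GradientTable, bval_dest: PathOrStream, bvec_dest: PathOrStream) -> None:
    """Write a scheme as an FSL ``.bval``/``.bvec`` pair (full precision)."""

    def _write(dest: PathOrStream, text: str) -> None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text)
        else:
            dest.write(text)

    _write(bval_dest, " ".join(repr(float(b)) for b in table.bvals) + "\n")
    rows = [" ".join(repr(float(v)) for v in table.bvecs[:, i]) for i in range(3)]
    _write(bvec_dest, "\n".join(rows) + "\n")


@dataclass
class DWIVolume:
    """A 4D diffusion-weighted image series in the fixed image frame."""

    data: np.ndarray  # (x, y, z, measurement), intensities >= 0
    voxel_size: np.ndarray  # (3,) mm
    axis_labels: tuple = ("right-left", "anterior-posterior", "feet-head")

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).ravel()
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be 3 strictly positive numbers (mm)")
        if np.any(self.data < 0):
            raise ValueError("DWI intensities must be non-negative")

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]

    def check_scheme(self, gradients: GradientTable) -> None:
        if self.data.shape[3] != len(gradients):
            raise ValueError(
                f"count mismatch: {self.data.shape[3]} volumes vs "
                f"{len(gradients)} gradient entries"
            )


@dataclass
class ScalarMap:
    """A 3D scalar map derived from DWI (FA, ADC, S0 or a tensor element).

    Diffusivity-like kinds are in mm^2/s; FA is dimensionless and clipped
    to [0, 1].
    """

    data: np.ndarray
    kind: str
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    units: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).ravel()
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        if self.kind not in SCALAR_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}; expected one of {SCALAR_KINDS}")
        if not self.units:
            self.units = "dimensionless" if self.kind == "FA" else "mm^2/s"
        if self.kind == "FA":
            self.data = np.clip(self.data, 0.0, 1.0)


def _affine(voxel_size: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def read_dwi(volume_source: PathOrStream, gradients: GradientTable | None = None) -> DWIVolume:
    """Load a 4D NIfTI as a :class:`DWIVolume`.

    Voxel size is taken from the header zooms; if ``gradients`` is given the
    4th-dimension length is checked against the scheme.
    """
    img = nib.load(str(volume_source)) if isinstance(volume_source, (str, Path)) else nib.Nifti1Image.from_stream(volume_source)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4D image, got {data.ndim}D")
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    vol = DWIVolume(data=data, voxel_size=voxel_size)
    if gradients is not None:
        vol.check_scheme(gradients)
    return vol


def write_dwi(volume: DWIVolume, destination: str | Path) -> None:
    """Write a DWI series as a float64 NIfTI-1 file (round-trip exact)."""
    img = nib.Nifti1Image(volume.data.astype(np.float64), _affine(volume.voxel_size))
    nib.save(img, str(destination))


def write_scalar_map(scalar_map: ScalarMap, destination: str | Path) -> None:
    """Write a scalar map as a float32 NIfTI-1 plus a JSON metadata sidecar.

    The sidecar (``<stem>.json`` next to the NIfTI) records ``kind`` and
    ``units`` so maps remain self-describing.
    """
    dest = Path(destination)
    img = nib.Nifti1Image(scalar_map.data.astype(np.float32), _affine(scalar_map.voxel_size))
    nib.save(img, str(dest))
    stem = dest.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    sidecar = dest.with_name(stem + ".json")
    sidecar.write_text(json.dumps({"kind": scalar_map.kind, "units": scalar_map.units}, indent=1))


def read_scalar_map(source: str | Path) -> ScalarMap:
    """Load a scalar map written by :func:`write_scalar_map` (sidecar aware)."""
    src = Path(source)
    img = nib.load(str(src))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected 3D image, got {data.ndim}D")
    stem = src.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    sidecar = src.with_name(stem + ".json")
    kind, units = "S0", ""
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        kind = meta.get("kind", kind)
        units = meta.get("units", "")
    return ScalarMap(data=data, kind=kind, voxel_size=np.asarray(img.header.get_zooms()[:3]), units=units)
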
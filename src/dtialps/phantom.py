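"""Digital DWI phantoms with known per-voxel tensors.

The default phantom emulates the periventricular geometry the ALPS method
relies on: a projection-fiber compartment whose dominant diffusion axis is
z (feet-head), an association-fiber compartment dominant along y
(anterior-posterior), a CSF-filled ventricle, an isotropic tumor, and an
isotropic background.  The perivascular (x) contribution appears as an
elevated Dxx in the two fiber compartments, which is exactly what a
single-tensor fit interprets as the perivascular proxy — the signal model
is deliberately mono-exponential per voxel:

    S = S0 * exp(-b * g^T D g),   then Rician corruption
    S_noisy = |S + n1 + i n2|,  n1, n2 ~ N(0, sigma^2)

Every phantom carries its ground truth (the designed tensor field and the
ALPS index implied by the fiber-compartment tensors), so the full
fit -> ROI -> index pipeline can be validated end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .alps import RoiSpec
from .io import DWIVolume, GradientTable, read_gradient_table, write_gradient_table, write_dwi
from .tensor import DiffusionTensorField

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "build_phantom_tensors",
    "simulate_signal",
    "default_phantom_spec",
    "isotropic_phantom_spec",
    "default_alps_rois",
    "default_gradient_table",
    "electrostatic_directions",
    "write_phantom_dataset",
]

REGION_LABELS = ("projection_area", "association_area", "ventricle_CSF", "tumor", "background")

# mm^2/s; fiber compartments share perpendicular diffusivities 0.8e-3 and a
# dominant-axis diffusivity 1.6e-3, so designed ALPS = Dxx / 0.8e-3.
_FIBER_PERP = 0.8e-3
_FIBER_MAIN = 1.6e-3
_CSF_D = 3.0e-3
_TUMOR_D = 1.6e-3
_BACKGROUND_D = 0.8e-3


@dataclass
class PhantomSpec:
    """Blueprint of a phantom: geometry, compartment tensors, noise.

    ``region_layout`` maps a label to a (start, size) voxel box (0-based,
    half-open); ``background`` needs no box — it is the remainder of the
    grid.  Boxes must be disjoint and inside the grid; every compartment
    tensor must be symmetric with non-negative eigenvalues.
    """

    grid_shape: tuple = (18, 18, 6)
    voxel_size: tuple = (2.0, 2.0, 2.0)
    region_layout: dict = field(default_factory=dict)
    compartment_tensors: dict = field(default_factory=dict)
    s0: float = 1000.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        shape = np.asarray(self.grid_shape, int)
        filled = np.zeros(self.grid_shape, dtype=bool)
        for label, (start, size) in self.region_layout.items():
            if label not in REGION_LABELS:
                raise ValueError(f"unknown region label {label!r}")
            start, size = np.asarray(start, int), np.asarray(size, int)
            if np.any(start < 0) or np.any(start + size > shape):
                raise ValueError(f"region {label!r} box exceeds the grid")
            sl = tuple(slice(a, a + s) for a, s in zip(start, size))
            if np.any(filled[sl]):
                raise ValueError(f"region {label!r} overlaps another region")
            filled[sl] = True
        for label, tensor in self.compartment_tensors.items():
            t = np.asarray(tensor, float)
            if t.shape != (3, 3) or not np.allclose(t, t.T, atol=1e-15):
                raise ValueError(f"compartment tensor for {label!r} is not symmetric 3x3")
            if np.min(np.linalg.eigvalsh(t)) < -1e-15:
                raise ValueError(f"compartment tensor for {label!r} has a negative eigenvalue")
        for label in self.region_layout:
            if label not in self.compartment_tensors:
                raise ValueError(f"region {label!r} has no compartment tensor")
        if "background" not in self.compartment_tensors:
            raise ValueError("a 'background' compartment tensor is required")

    @property
    def designed_alps(self) -> float | None:
        """ALPS index implied by the fiber-compartment tensors (None if the
        phantom has no fiber compartments)."""
        try:
            proj = np.asarray(self.compartment_tensors["projection_area"])
            assoc = np.asarray(self.compartment_tensors["association_area"])
        except KeyError:
            return None
        num = (proj[0, 0] + assoc[0, 0]) / 2.0
        den = (proj[1, 1] + assoc[2, 2]) / 2.0
        return float(num / den)


@dataclass
class PhantomTruth:
    """Ground truth of a built phantom: the tensor field and designed index."""

    tensor_field: DiffusionTensorField
    labels: np.ndarray  # per-voxel region label index into REGION_LABELS
    designed_alps: float | None
    spec: PhantomSpec


def build_phantom_tensors(spec: PhantomSpec) -> PhantomTruth:
    """Paint every voxel with its compartment tensor."""
    shape = tuple(spec.grid_shape)
    tensors = np.empty(shape + (3, 3))
    tensors[...] = np.asarray(spec.compartment_tensors["background"], float)
    labels = np.full(shape, REGION_LABELS.index("background"), dtype=int)
    for label, (start, size) in spec.region_layout.items():
        sl = tuple(slice(a, a + s) for a, s in zip(start, size))
        tensors[sl] = np.asarray(spec.compartment_tensors[label], float)
        labels[sl] = REGION_LABELS.index(label)
    fld = DiffusionTensorField(
        dxx=tensors[..., 0, 0], dyy=tensors[..., 1, 1], dzz=tensors[..., 2, 2],
        dxy=tensors[..., 0, 1], dxz=tensors[..., 0, 2], dyz=tensors[..., 1, 2],
        s0_map=np.full(shape, spec.s0), mask=np.ones(shape, dtype=bool),
        voxel_size=np.asarray(spec.voxel_size, float),
    )
    return PhantomTruth(tensor_field=fld, labels=labels,
                        designed_alps=spec.designed_alps, spec=spec)


def simulate_signal(truth: PhantomTruth, gradients: GradientTable,
                    s0: float | None = None, noise_sigma: float | None = None,
                    seed: int | None = None) -> DWIVolume:
    """Mono-exponential tensor signal with optional Rician noise.

    Per measurement i, ``S_i = s0 * exp(-b_i * g_i^T D g_i)``; with
    ``noise_sigma > 0`` the magnitude of a two-channel complex Gaussian
    perturbation is returned (seed required for reproducibility).
    """
    spec = truth.spec
    s0 = spec.s0 if s0 is None else float(s0)
    noise_sigma = spec.noise_sigma if noise_sigma is None else float(noise_sigma)
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if seed is None:
        seed = spec.seed
    if noise_sigma > 0 and seed is None:
        raise ValueError("a seed is required when noise_sigma > 0")

    d = truth.tensor_field.tensors()  # (..., 3, 3)
    g = gradients.bvecs  # (n, 3)
    quad = np.einsum("ni,...ij,nj->...n", g, d, g)
    signal = s0 * np.exp(-gradients.bvals * quad)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, noise_sigma, signal.shape)
        n2 = rng.normal(0.0, noise_sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)
    return DWIVolume(data=signal, voxel_size=np.asarray(spec.voxel_size, float))


def _diag(dx, dy, dz):
    return np.diag([dx, dy, dz])


def default_phantom_spec(kind: str = "contralateral", noise_sigma: float = 0.0,
                         seed: int = 0) -> PhantomSpec:
    """The standard periventricular phantom.

    ``kind`` selects the fiber-compartment Dxx: the 'contralateral'-like
    phantom is designed at ALPS = 1.4 (Dxx = 1.12e-3) and the
    'ipsilateral'-like one at ALPS = 1.25 (Dxx = 1.0e-3), echoing the
    hemisphere-level magnitudes a tumor cohort exhibits.  Geometry: a CSF
    ventricle body flanked (towards the subject's left, higher x) by the
    projection and association areas; an isotropic tumor sits in the
    opposite hemisphere.
    """
    dxx = {"contralateral": 1.4 * _FIBER_PERP, "ipsilateral": 1.25 * _FIBER_PERP}
    if kind not in dxx:
        raise ValueError(f"kind must be 'contralateral' or 'ipsilateral', got {kind!r}")
    layout = {
        "ventricle_CSF": ((7, 4, 0), (4, 10, 6)),
        "projection_area": ((11, 4, 0), (4, 5, 6)),
        "association_area": ((11, 9, 0), (4, 5, 6)),
        "tumor": ((2, 4, 1), (3, 3, 3)),
    }
    tensors = {
        "projection_area": _diag(dxx[kind], _FIBER_PERP, _FIBER_MAIN),
        "association_area": _diag(dxx[kind], _FIBER_MAIN, _FIBER_PERP),
        "ventricle_CSF": _diag(_CSF_D, _CSF_D, _CSF_D),
        "tumor": _diag(_TUMOR_D, _TUMOR_D, _TUMOR_D),
        "background": _diag(_BACKGROUND_D, _BACKGROUND_D, _BACKGROUND_D),
    }
    return PhantomSpec(region_layout=layout, compartment_tensors=tensors,
                       noise_sigma=noise_sigma, seed=seed)


def isotropic_phantom_spec(diffusivity: float = _BACKGROUND_D, noise_sigma: float = 0.0,
                           seed: int = 0) -> PhantomSpec:
    """A phantom whose fiber compartments are isotropic: designed ALPS = 1."""
    spec = default_phantom_spec(noise_sigma=noise_sigma, seed=seed)
    iso = _diag(diffusivity, diffusivity, diffusivity)
    tensors = dict(spec.compartment_tensors)
    tensors["projection_area"] = iso
    tensors["association_area"] = iso
    return PhantomSpec(region_layout=spec.region_layout, compartment_tensors=tensors,
                       noise_sigma=noise_sigma, seed=seed)


def default_alps_rois() -> tuple:
    """The standard 2x2x1 ROI pair inside the default phantom's fiber boxes."""
    proj = RoiSpec(kind="projection", start_voxel=(12, 6, 3), size_voxels=(2, 2, 1),
                   hemisphere="left")
    assoc = RoiSpec(kind="association", start_voxel=(12, 11, 3), size_voxels=(2, 2, 1),
                    hemisphere="left")
    return proj, assoc


def electrostatic_directions(n: int = 64, seed: int = 7, maxiter: int = 2000) -> np.ndarray:
    """Deterministic electrostatic-repulsion layout of n unit directions.

    Minimises the Coulomb energy of n antipodally symmetric point pairs on
    the sphere from a seeded random start; used once to produce the shipped
    64-direction scheme fixture.
    """
    rng = np.random.default_rng(seed)
    x0 = rng.normal(size=(n, 3))
    x0 /= np.linalg.norm(x0, axis=1, keepdims=True)

    def energy(flat):
        p = flat.reshape(n, 3)
        p = p / np.linalg.norm(p, axis=1, keepdims=True)
        diff = p[:, None, :] - p[None, :, :]
        summ = p[:, None, :] + p[None, :, :]
        dd = np.linalg.norm(diff, axis=-1)
        ds = np.linalg.norm(summ, axis=-1)
        iu = np.triu_indices(n, k=1)
        return float(np.sum(1.0 / dd[iu]) + np.sum(1.0 / ds[iu]))

    res = minimize(energy, x0.ravel(), method="L-BFGS-B", options={"maxiter": maxiter})
    p = res.x.reshape(n, 3)
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    # canonical hemisphere and ordering for reproducibility of the fixture
    flip = (p[:, 2] < 0) | ((p[:, 2] == 0) & (p[:, 1] < 0))
    p[flip] *= -1
    order = np.lexsort((p[:, 1], p[:, 0], -p[:, 2]))
    return p[order]


def default_gradient_table(b: float = 1000.0) -> GradientTable:
    """The shipped 65-entry scheme: one b=0 plus 64 directions at b (s/mm^2)."""
    pkg = resources.files("dtialps") / "datasets"
    table = read_gradient_table(str(pkg / "scheme64.bval"), str(pkg / "scheme64.bvec"))
    if b != 1000.0:
        bvals = np.where(table.bvals > 0, b, 0.0)
        table = GradientTable(bvals=bvals, bvecs=table.bvecs)
    return table


def write_phantom_dataset(truth: PhantomTruth, gradients: GradientTable,
                          dwi: DWIVolume, out_dir) -> None:
    """Write NIfTI + bval/bvec + a JSON ground-truth file for a phantom."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_dwi(dwi, out / "phantom_dwi.nii")
    write_gradient_table(gradients, out / "phantom.bval", out / "phantom.bvec")
    spec = truth.spec
    payload = {
        "grid_shape": list(spec.grid_shape),
        "voxel_size": list(np.asarray(spec.voxel_size, float)),
        "s0": spec.s0,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "designed_alps": truth.designed_alps,
        "region_layout": {k: [list(map(int, s)), list(map(int, z))]
                          for k, (s, z) in spec.region_layout.items()},
        "compartment_tensors": {k: np.asarray(v, float).tolist()
                                for k, v in spec.compartment_tensors.items()},
    }
    (out / "phantom_truth.json").write_text(json.dumps(payload, indent=1))
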
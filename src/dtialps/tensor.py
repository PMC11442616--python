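"""Per-voxel diffusion-tensor estimation by log-linear least squares.

The model follows the mono-exponential signal equation

    S_i = S0 * exp(-b_i * g_i^T D g_i)

which is linear in (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) after taking logs.
:class:`DiffusionTensorModel` holds the data and scheme; :meth:`fit` solves
the ordinary least-squares problem for every masked voxel at once and
returns a :class:`DiffusionTensorField` results object from which FA, mean
diffusivity, and S0 maps are derived.

Choices that matter downstream:

* unweighted OLS in log-signal space — deterministic and exact on
  noiseless data;
* signals are clamped to a floor of ``1e-6 * max(signal)`` before the log
  so zero/negative magnitudes cannot produce -inf;
* no positivity constraint on the fitted tensor: the ALPS index uses the
  raw diagonal elements, and constraining them would silently change the
  statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DWIVolume, GradientTable, ScalarMap, _tensor_design

__all__ = [
    "DiffusionTensorModel",
    "DiffusionTensorField",
    "fit_log_linear",
    "trace_adc_map",
]

ELEMENT_NAMES = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class DiffusionTensorField:
    """Fitted (or ground-truth) symmetric tensor per voxel.

    Stores the six unique elements as 3D maps (mm^2/s) plus the fitted
    b=0 signal and the mask of voxels that were fitted.  Acts as the
    results object of :class:`DiffusionTensorModel`.
    """

    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    dxy: np.ndarray
    dxz: np.ndarray
    dyz: np.ndarray
    s0_map: np.ndarray
    mask: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self):
        shapes = {m.shape for m in (self.dxx, self.dyy, self.dzz, self.dxy,
                                    self.dxz, self.dyz, self.s0_map, self.mask)}
        if len(shapes) != 1:
            raise ValueError(f"element maps have inconsistent shapes: {shapes}")
        self.mask = np.asarray(self.mask, dtype=bool)
        for name in ("dxx", "dyy", "dzz"):
            vals = getattr(self, name)[self.mask]
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"{name} not finite on masked voxels")

    @property
    def grid_shape(self) -> tuple:
        return self.dxx.shape

    def element(self, name: str) -> np.ndarray:
        """Return one element map by its conventional name, e.g. ``"Dxx"``."""
        if name not in ELEMENT_NAMES:
            raise KeyError(f"unknown tensor element {name!r}")
        return getattr(self, name.lower())

    def tensors(self) -> np.ndarray:
        """Full symmetric 3x3 tensor per voxel, shape ``grid_shape + (3, 3)``."""
        t = np.empty(self.grid_shape + (3, 3))
        t[..., 0, 0] = self.dxx
        t[..., 1, 1] = self.dyy
        t[..., 2, 2] = self.dzz
        t[..., 0, 1] = t[..., 1, 0] = self.dxy
        t[..., 0, 2] = t[..., 2, 0] = self.dxz
        t[..., 1, 2] = t[..., 2, 1] = self.dyz
        return t

    def eigenvalues(self) -> np.ndarray:
        """Tensor eigenvalues per voxel, ascending, zeros outside the mask."""
        evals = np.zeros(self.grid_shape + (3,))
        if np.any(self.mask):
            evals[self.mask] = np.linalg.eigvalsh(self.tensors()[self.mask])
        return evals

    def principal_direction(self) -> np.ndarray:
        """Unit eigenvector of the largest eigenvalue per voxel."""
        vecs = np.zeros(self.grid_shape + (3,))
        if np.any(self.mask):
            w, v = np.linalg.eigh(self.tensors()[self.mask])
            vecs[self.mask] = v[..., -1]  # eigh returns ascending eigenvalues
        return vecs

    def fa_map(self) -> ScalarMap:
        """Fractional anisotropy from the eigenvalues.

        FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||, clipped to
        [0, 1]; voxels with non-positive trace (or outside the mask) map
        to 0.
        """
        evals = self.eigenvalues()
        mean = evals.mean(axis=-1, keepdims=True)
        num = np.sqrt((3.0 / 2.0) * np.sum((evals - mean) ** 2, axis=-1))
        den = np.sqrt(np.sum(evals**2, axis=-1))
        trace = evals.sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fa = np.where((trace > 0) & (den > 0), num / np.maximum(den, 1e-300), 0.0)
        fa = np.where(self.mask, fa, 0.0)
        return ScalarMap(data=np.clip(fa, 0.0, 1.0), kind="FA", voxel_size=self.voxel_size)

    def md_map(self) -> ScalarMap:
        """Mean diffusivity (Dxx + Dyy + Dzz) / 3."""
        md = np.where(self.mask, (self.dxx + self.dyy + self.dzz) / 3.0, 0.0)
        return ScalarMap(data=md, kind="MD", voxel_size=self.voxel_size)

    def s0_scalar_map(self) -> ScalarMap:
        return ScalarMap(data=np.where(self.mask, self.s0_map, 0.0), kind="S0",
                         voxel_size=self.voxel_size, units="signal")

    def summary(self) -> str:
        """Plain-text summary of the fitted field."""
        n = int(self.mask.sum())
        lines = [
            "Diffusion tensor field",
            f"  grid: {self.grid_shape}, fitted voxels: {n}",
        ]
        if n:
            md = (self.dxx + self.dyy + self.dzz)[self.mask] / 3.0
            fa = self.fa_map().data[self.mask]
            lines += [
                f"  mean diffusivity: median {np.median(md):.3e} mm^2/s",
                f"  FA: median {np.median(fa):.3f}",
            ]
        return "\n".join(lines)


class DiffusionTensorModel:
    """Log-linear least-squares diffusion tensor model for a DWI series.

    Parameters
    ----------
    dwi
        The 4D measurement series.
    gradients
        Diffusion-encoding scheme; must contain a b=0 entry and at least
        six non-collinear diffusion-weighted directions.
    mask
        Optional 3D boolean array of voxels to fit; default all.
    """

    def __init__(self, dwi: DWIVolume, gradients: GradientTable, mask: np.ndarray | None = None):
        dwi.check_scheme(gradients)
        gradients.validate_for_fit()
        if mask is None:
            mask = np.ones(dwi.grid_shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != dwi.grid_shape:
            raise ValueError("mask shape does not match the image grid")
        if not np.any(mask):
            raise ValueError("empty mask: nothing to fit")
        self.dwi = dwi
        self.gradients = gradients
        self.mask = mask

    def design_matrix(self) -> np.ndarray:
        """N x 7 design: column of ones for ln S0, then -b * tensor design."""
        b = self.gradients.bvals[:, None]
        return np.column_stack(
            [np.ones(len(self.gradients)), -b * _tensor_design(self.gradients.bvecs)]
        )

    def fit(self) -> DiffusionTensorField:
        """Solve the OLS problem per masked voxel; returns the tensor field."""
        signals = self.dwi.data[self.mask]  # (V, N)
        floor = 1e-6 * max(float(signals.max()), np.finfo(float).tiny)
        log_s = np.log(np.maximum(signals, floor))
        design = self.design_matrix()
        coef, *_ = np.linalg.lstsq(design, log_s.T, rcond=None)  # (7, V)

        shape = self.dwi.grid_shape
        maps = {}
        for i, name in enumerate(ELEMENT_NAMES):
            m = np.zeros(shape)
            m[self.mask] = coef[1 + i]
            maps[name.lower()] = m
        s0 = np.zeros(shape)
        s0[self.mask] = np.exp(coef[0])
        return DiffusionTensorField(
            **maps, s0_map=s0, mask=self.mask.copy(), voxel_size=self.dwi.voxel_size
        )


def fit_log_linear(dwi: DWIVolume, gradients: GradientTable,
                   mask: np.ndarray | None = None) -> DiffusionTensorField:
    """Functional shorthand for ``DiffusionTensorModel(dwi, gradients, mask).fit()``."""
    return DiffusionTensorModel(dwi, gradients, mask).fit()


def trace_adc_map(dwi: DWIVolume, gradients: GradientTable) -> ScalarMap:
    """ADC from the trace image and the b=0 image.

    The trace image is the geometric mean of all diffusion-weighted
    measurements of the (single) non-zero shell; with the mono-exponential
    model this makes ``ADC = ln(S_b0 / S_trace) / b`` equal the average of
    g^T D g over the directions, i.e. the mean diffusivity whenever the
    direction set is isotropic.  Reported in mm^2/s.
    """
    dwi.check_scheme(gradients)
    b0 = gradients.b0_mask
    dw = gradients.dwi_mask
    if not np.any(b0):
        raise ValueError("scheme has no b=0 volume; cannot form the ADC map")
    if not np.any(dw):
        raise ValueError("scheme has no diffusion-weighted volume")
    bvals = np.unique(gradients.bvals[dw])
    if len(bvals) != 1:
        raise ValueError(f"expected a single non-zero shell, got b = {bvals}")
    b = float(bvals[0])

    floor = 1e-6 * max(float(dwi.data.max()), np.finfo(float).tiny)
    s_b0 = np.maximum(dwi.data[..., b0].mean(axis=-1), floor)
    log_dw = np.log(np.maximum(dwi.data[..., dw], floor))
    s_trace = np.exp(log_dw.mean(axis=-1))  # geometric mean
    adc = np.log(s_b0 / s_trace) / b
    return ScalarMap(data=adc, kind="ADC", voxel_size=dwi.voxel_size)
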
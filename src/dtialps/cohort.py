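"""Synthetic cohort tables with the statistical structure of a tumor study.

Generates paired per-patient ALPS indices (tumor-ipsilateral vs
contralateral hemisphere) and healthy-control right/left indices, with the
group means and standard deviations a unilateral-brain-tumor cohort
exhibits.  Defaults mirror the study conditions: 24 patients with
ipsilateral 1.26 +/- 0.24 vs contralateral 1.43 +/- 0.28, 12 controls
around 1.28 +/- 0.22, ages uniform on [24, 73], 14/24 male.  Within-subject
hemisphere pairs are drawn from a bivariate normal with correlation 0.7 —
paired diffusivity measures in the same brain are strongly coupled, and a
positive correlation is what gives the paired test its power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CohortSimSpec", "generate_cohort_table"]


@dataclass(frozen=True)
class CohortSimSpec:
    """Parameters of a synthetic two-group cohort."""

    n_patients: int = 24
    n_controls: int = 12
    ipsi_mean: float = 1.26
    contra_mean: float = 1.43
    hc_mean: float = 1.28
    ipsi_sd: float = 0.24
    contra_sd: float = 0.28
    hc_sd: float = 0.22
    pair_correlation: float = 0.7
    age_range: tuple = (24, 73)
    male_fraction: float = 14 / 24
    primary_fraction: float = 17 / 24
    roi_in_ptbe_fraction: float = 5 / 24
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("n_patients and n_controls must be >= 1")
        if min(self.ipsi_sd, self.contra_sd, self.hc_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if not -1.0 <= self.pair_correlation <= 1.0:
            raise ValueError("pair_correlation must lie in [-1, 1]")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")


def _paired_normal(rng, n, mean_a, sd_a, mean_b, sd_b, rho):
    """n draws of a correlated pair; degenerates gracefully when an sd is 0."""
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    a = mean_a + sd_a * z1
    b = mean_b + sd_b * (rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * z2)
    return a, b


def generate_cohort_table(spec: CohortSimSpec) -> dict:
    """Draw a synthetic cohort; returns ``{"patients": df, "controls": df}``.

    The frames use the same schema as the packaged study tables (ids, age,
    sex, per-hemisphere index; patients additionally carry a tumor side and
    an inclusion flag, all included).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)

    def _one_group(n, mean_a, sd_a, mean_b, sd_b):
        a, b = _paired_normal(rng, n, mean_a, sd_a, mean_b, sd_b, spec.pair_correlation)
        lo, hi = spec.age_range
        ages = rng.integers(lo, hi + 1, size=n)
        sexes = np.where(rng.random(n) < spec.male_fraction, "male", "female")
        return a, b, ages, sexes

    ipsi, contra, p_ages, p_sexes = _one_group(
        spec.n_patients, spec.ipsi_mean, spec.ipsi_sd, spec.contra_mean, spec.contra_sd)
    patients = pd.DataFrame({
        "patient_id": np.arange(1, spec.n_patients + 1),
        "age": p_ages,
        "sex": p_sexes,
        "alps_ipsi": ipsi,
        "alps_contra": contra,
        "tumor_side": rng.choice(["left", "right"], size=spec.n_patients),
        "tumor_type": np.where(rng.random(spec.n_patients) < spec.primary_fraction,
                               "primary", "metastasis"),
        "roi_in_ptbe": rng.random(spec.n_patients) < spec.roi_in_ptbe_fraction,
        "included": True,
    })

    right, left, c_ages, c_sexes = _one_group(
        spec.n_controls, spec.hc_mean, spec.hc_sd, spec.hc_mean, spec.hc_sd)
    controls = pd.DataFrame({
        "control_id": np.arange(1, spec.n_controls + 1),
        "age": c_ages,
        "sex": c_sexes,
        "alps_right": right,
        "alps_left": left,
    })
    return {"patients": patients, "controls": controls}
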
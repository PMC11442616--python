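"""Cohort-level ALPS study driver.

:class:`AlpsStudy` is built from per-subject tables (the packaged
tumor-cohort tables, external CSVs with the same schema, or a synthetic
cohort) and its :meth:`~AlpsStudy.fit` runs the full analysis: hemisphere
descriptives and the paired signed-rank test, ipsilateral-index subgroup
comparisons (age, sex, tumor type, ROI-in-edema), simple regressions of
the index on age and tumor ADC, and the healthy-control summaries.  The
returned :class:`StudyResults` carries every number at full precision and
renders a rounded summary table; reports serialize deterministically to
JSON / Markdown / CSV.

Tumor ADC values are stored as printed in the source tables (magnitudes
~75-2930 under an mm^2/s header, consistent with units of 1e-6 mm^2/s).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortSimSpec, generate_cohort_table
from .stats import (Descriptives, describe, linear_regression, mann_whitney_u,
                    match_controls, wilcoxon_signed_rank)

__all__ = [
    "SubjectRecord",
    "AlpsStudy",
    "StudyResults",
    "load_subject_table",
    "load_patient_table",
    "load_control_table",
    "run_hemisphere_comparison",
    "run_group_comparisons",
    "run_regressions",
    "emit_report",
    "AGE_SPLIT_YEARS",
]

AGE_SPLIT_YEARS = 55  # subgroups are strictly < 55 vs strictly > 55
SEXES = ("male", "female")
TUMOR_TYPES = ("primary", "metastasis")
TUMOR_SIDES = ("left", "right", "intraventricular")
EVENTS = ("first_diagnosis", "local_recurrence", "distance_recurrence")


@dataclass(frozen=True)
class SubjectRecord:
    """One row of a study table: a patient or a healthy control."""

    id: int
    age: float
    sex: str
    group: str  # "patient" | "control"
    included: bool = True
    alps_ipsi: float | None = None
    alps_contra: float | None = None
    alps_right: float | None = None
    alps_left: float | None = None
    tumor_adc: float | None = None  # as printed; magnitudes ~1e-6 mm^2/s
    tumor_type: str | None = None
    tumor_side: str | None = None
    tumor_details: str | None = None
    tumor_location: str | None = None
    event: str | None = None
    ptbe: str | None = None
    roi_in_ptbe: bool = False
    matched_patient_ids: tuple = ()

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"subject {self.id}: invalid sex {self.sex!r}")
        if self.group not in ("patient", "control"):
            raise ValueError(f"subject {self.id}: invalid group {self.group!r}")
        if self.group == "patient":
            if self.age < 18:
                raise ValueError(f"patient {self.id}: age {self.age} below the adult cutoff")
            has_both = self.alps_ipsi is not None and self.alps_contra is not None
            if self.included and not has_both:
                raise ValueError(f"patient {self.id}: included but missing an ALPS value")
            if self.tumor_type is not None and self.tumor_type not in TUMOR_TYPES:
                raise ValueError(f"patient {self.id}: invalid tumor_type {self.tumor_type!r}")
            if self.tumor_side is not None and self.tumor_side not in TUMOR_SIDES:
                raise ValueError(f"patient {self.id}: invalid tumor_side {self.tumor_side!r}")
            if self.event is not None and self.event not in EVENTS:
                raise ValueError(f"patient {self.id}: invalid event {self.event!r}")
        else:
            if self.alps_right is None or self.alps_left is None:
                raise ValueError(f"control {self.id}: missing a hemisphere ALPS value")


def _opt_float(value):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in ("true", "1", "yes")


PATIENT_COLUMNS = ("patient_id", "age", "sex", "alps_ipsi", "alps_contra")
CONTROL_COLUMNS = ("control_id", "age", "sex", "alps_right", "alps_left")


def load_subject_table(source, group: str = "patient") -> list:
    """Read a patient or control CSV into validated :class:`SubjectRecord`s.

    The schema is documented in the packaged dataset README; empty ALPS
    cells mean the subject was excluded (patients) and are only legal with
    ``included`` false.
    """
    df = pd.read_csv(source)
    required = PATIENT_COLUMNS if group == "patient" else CONTROL_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"schema mismatch: missing column(s) {missing}")
    id_col = required[0]
    if df[id_col].duplicated().any():
        dupes = df.loc[df[id_col].duplicated(), id_col].tolist()
        raise ValueError(f"duplicate ids: {dupes}")

    records = []
    for row in df.to_dict("records"):
        if group == "patient":
            records.append(SubjectRecord(
                id=int(row["patient_id"]), age=float(row["age"]), sex=str(row["sex"]),
                group="patient",
                included=_opt_bool(row.get("included", True)),
                alps_ipsi=_opt_float(row.get("alps_ipsi")),
                alps_contra=_opt_float(row.get("alps_contra")),
                tumor_adc=_opt_float(row.get("tumor_adc")),
                tumor_type=row.get("tumor_type") or None,
                tumor_side=row.get("tumor_side") or None,
                tumor_details=row.get("tumor_details") or None,
                tumor_location=row.get("tumor_location") or None,
                event=row.get("event") or None,
                ptbe=row.get("ptbe") or None,
                roi_in_ptbe=_opt_bool(row.get("roi_in_ptbe", False)),
            ))
        else:
            raw = row.get("matched_patient_ids")
            matched = ()
            if raw is not None and not (isinstance(raw, float) and math.isnan(raw)):
                matched = tuple(int(t) for t in str(raw).split(";") if t.strip())
            records.append(SubjectRecord(
                id=int(row["control_id"]), age=float(row["age"]), sex=str(row["sex"]),
                group="control",
                alps_right=float(row["alps_right"]), alps_left=float(row["alps_left"]),
                matched_patient_ids=matched,
            ))
    return records


def _fixture_path(name: str):
    return resources.files("dtialps") / "datasets" / name


def load_patient_table() -> list:
    """The packaged tumor-cohort table (30 rows, 24 included)."""
    with resources.as_file(_fixture_path("table1_patients.csv")) as p:
        return load_subject_table(p, group="patient")


def load_control_table() -> list:
    """The packaged healthy-control table (12 subjects)."""
    with resources.as_file(_fixture_path("table2_controls.csv")) as p:
        return load_subject_table(p, group="control")


# ---------------------------------------------------------------------------
# report sections


def _descriptives_or_mean(values) -> dict:
    """Full descriptives, or mean-only for singleton groups (sd omitted)."""
    values = np.asarray(values, dtype=float)
    if len(values) >= 2:
        d = describe(values)
        return {"n": d.n, "mean": d.mean, "sd": d.sd, "median": d.median,
                "q1": d.q1, "q3": d.q3}
    return {"n": int(len(values)), "mean": float(values.mean()) if len(values) else None,
            "sd": None, "median": float(values[0]) if len(values) else None,
            "q1": None, "q3": None}


def _test_dict(result) -> dict:
    return {"method": result.method, "statistic": result.statistic,
            "p_two_sided": result.p_two_sided, "n_effective": result.n_effective}


def run_hemisphere_comparison(patients) -> dict:
    """Ipsi/contra descriptives plus the paired signed-rank test."""
    inc = [p for p in patients if p.included]
    if len(inc) < 2:
        raise ValueError("need at least two included patients")
    ipsi = np.array([p.alps_ipsi for p in inc])
    contra = np.array([p.alps_contra for p in inc])
    section = {
        "ipsilateral": _descriptives_or_mean(ipsi),
        "contralateral": _descriptives_or_mean(contra),
    }
    try:
        section["test"] = _test_dict(wilcoxon_signed_rank(ipsi, contra))
    except ValueError:
        section["test"] = None
        section["note"] = "no difference computable: all paired differences are zero"
    return section


def run_group_comparisons(patients) -> dict:
    """Ipsilateral-index subgroups: age, sex, tumor type, ROI-in-edema.

    Splits whose attribute is absent from every record (e.g. no tumor
    typing in a minimal synthetic cohort) are skipped; a split that is
    present but leaves one side empty is an error.
    """
    inc = [p for p in patients if p.included]

    def _ipsi(subset):
        return np.array([p.alps_ipsi for p in subset])

    splits = {
        "age": {f"<{AGE_SPLIT_YEARS}": [p for p in inc if p.age < AGE_SPLIT_YEARS],
                f">{AGE_SPLIT_YEARS}": [p for p in inc if p.age > AGE_SPLIT_YEARS]},
        "sex": {"male": [p for p in inc if p.sex == "male"],
                "female": [p for p in inc if p.sex == "female"]},
        "tumor_type": {"primary": [p for p in inc if p.tumor_type == "primary"],
                       "metastasis": [p for p in inc if p.tumor_type == "metastasis"]},
        "roi_in_ptbe": {"inside": [p for p in inc if p.roi_in_ptbe],
                        "outside": [p for p in inc if not p.roi_in_ptbe]},
    }
    if all(p.tumor_type is None for p in inc):
        del splits["tumor_type"]
    if not any(p.roi_in_ptbe for p in inc):  # flag unused in this cohort
        del splits["roi_in_ptbe"]
    section = {}
    for name, groups in splits.items():
        (label_a, ga), (label_b, gb) = groups.items()
        if not ga or not gb:
            raise ValueError(f"empty group in the {name} split "
                             f"({label_a}: {len(ga)}, {label_b}: {len(gb)})")
        section[name] = {
            label_a: _descriptives_or_mean(_ipsi(ga)),
            label_b: _descriptives_or_mean(_ipsi(gb)),
            "test": _test_dict(mann_whitney_u(_ipsi(ga), _ipsi(gb))),
        }
    return section


def run_regressions(patients) -> dict:
    """OLS of the index on age (both hemispheres) and on tumor ADC."""
    inc = [p for p in patients if p.included]
    if len(inc) < 3:
        raise ValueError("need at least three included patients for regression")
    age = np.array([p.age for p in inc])
    ipsi = np.array([p.alps_ipsi for p in inc])
    contra = np.array([p.alps_contra for p in inc])
    out = {}

    def _reg(x, y):
        r = linear_regression(x, y)
        return {"slope": r.slope, "intercept": r.intercept,
                "r_squared": r.r_squared, "p_slope": r.p_slope, "n": r.n}

    out["ipsi_vs_age"] = _reg(age, ipsi)
    out["contra_vs_age"] = _reg(age, contra)
    with_adc = [p for p in inc if p.tumor_adc is not None]
    if len(with_adc) >= 3:
        out["ipsi_vs_tumor_adc"] = _reg(
            np.array([p.tumor_adc for p in with_adc]),
            np.array([p.alps_ipsi for p in with_adc]))
    else:
        out["ipsi_vs_tumor_adc"] = None
    return out


def _run_controls(controls) -> dict:
    right = np.array([c.alps_right for c in controls])
    left = np.array([c.alps_left for c in controls])
    ages = np.array([c.age for c in controls])
    section = {
        "right": _descriptives_or_mean(right),
        "left": _descriptives_or_mean(left),
        "age": _descriptives_or_mean(ages),
    }
    try:
        section["right_vs_left_test"] = _test_dict(wilcoxon_signed_rank(right, left))
    except ValueError:
        section["right_vs_left_test"] = None
    return section


def _control_value(control: SubjectRecord, patient: SubjectRecord,
                   rule: str, matched_side: str) -> float:
    """Which control hemisphere stands in for the patient's `matched_side`.

    Under ``tumor_side`` the control hemisphere on the patient's tumor side
    plays the ipsilateral role (the opposite one the contralateral role);
    under a fixed rule one hemisphere is used for the ipsilateral role and
    the other for the contralateral role.  The convention is an analysis
    parameter, not a claim — source studies rarely state theirs.
    """
    if rule == "tumor_side":
        side = patient.tumor_side if patient.tumor_side in ("left", "right") else "left"
    elif rule == "fixed_left":
        side = "left"
    else:
        side = "right"
    if matched_side == "contralateral":
        side = "right" if side == "left" else "left"
    return control.alps_right if side == "right" else control.alps_left


def _run_matched_comparison(patients, controls, hemisphere_rule: str) -> dict:
    """Patient-vs-matched-control comparisons under the chosen hemisphere rule.

    Uses the explicit control -> patient mapping when the control table
    provides one, otherwise greedy age/sex matching (within 2 years).
    """
    inc = {p.id: p for p in patients if p.included}
    explicit = {}
    for c in controls:
        for pid in c.matched_patient_ids:
            if pid in inc:
                explicit[pid] = c
    if not explicit:
        assignment = match_controls(list(inc.values()), controls,
                                    hemisphere_rule=hemisphere_rule)
        ctrl_by_id = {c.id: c for c in controls}
        explicit = {pid: ctrl_by_id[cid] for pid, cid in assignment.pairs}

    section = {"hemisphere_rule": hemisphere_rule, "n_pairs": len(explicit)}
    for role, patient_attr in (("ipsilateral", "alps_ipsi"), ("contralateral", "alps_contra")):
        pv, cv = [], []
        for pid, control in sorted(explicit.items()):
            patient = inc[pid]
            pv.append(getattr(patient, patient_attr))
            cv.append(_control_value(control, patient, hemisphere_rule, role))
        entry = {"patient": _descriptives_or_mean(pv), "matched_hc": _descriptives_or_mean(cv)}
        try:
            entry["test"] = _test_dict(wilcoxon_signed_rank(np.array(pv), np.array(cv)))
        except ValueError:
            entry["test"] = None
        section[role] = entry
    return section


def _demographics(patients, controls) -> dict:
    inc = [p for p in patients if p.included]
    demo = {
        "n_total": len(patients),
        "n_included": len(inc),
        "n_excluded": len(patients) - len(inc),
        "n_male": sum(p.sex == "male" for p in inc),
        "n_female": sum(p.sex == "female" for p in inc),
        "n_primary": sum(p.tumor_type == "primary" for p in inc),
        "n_metastasis": sum(p.tumor_type == "metastasis" for p in inc),
        "n_roi_in_ptbe": sum(p.roi_in_ptbe for p in inc),
        "age": _descriptives_or_mean([p.age for p in inc]),
    }
    adcs = [p.tumor_adc for p in inc if p.tumor_adc is not None]
    demo["tumor_adc"] = _descriptives_or_mean(adcs) if adcs else None
    if controls:
        demo["n_controls"] = len(controls)
    return demo


# ---------------------------------------------------------------------------
# model / results


class AlpsStudy:
    """The cohort model: patients (and optionally controls) ready to analyse.

    Parameters
    ----------
    patients
        :class:`SubjectRecord` list, ``group="patient"``.
    controls
        Optional control records (``group="control"``).
    """

    def __init__(self, patients, controls=None):
        patients = list(patients)
        controls = list(controls) if controls is not None else []
        if any(p.group != "patient" for p in patients):
            raise ValueError("patients list contains non-patient records")
        if any(c.group != "control" for c in controls):
            raise ValueError("controls list contains non-control records")
        if not patients:
            raise ValueError("need at least one patient")
        self.patients = patients
        self.controls = controls

    @classmethod
    def from_csv(cls, patients_csv, controls_csv=None) -> "AlpsStudy":
        patients = load_subject_table(patients_csv, group="patient")
        controls = load_subject_table(controls_csv, group="control") if controls_csv else None
        return cls(patients, controls)

    @classmethod
    def from_packaged_tables(cls) -> "AlpsStudy":
        """The study cohort shipped with the package (30 + 12 subjects)."""
        return cls(load_patient_table(), load_control_table())

    @classmethod
    def from_simulation(cls, spec: CohortSimSpec | None = None) -> "AlpsStudy":
        """A synthetic cohort with the study's statistical structure."""
        spec = spec if spec is not None else CohortSimSpec()
        tables = generate_cohort_table(spec)
        patients = [
            SubjectRecord(id=int(r.patient_id), age=float(r.age), sex=str(r.sex),
                          group="patient", included=True,
                          alps_ipsi=float(r.alps_ipsi), alps_contra=float(r.alps_contra),
                          tumor_side=str(r.tumor_side), tumor_type=str(r.tumor_type),
                          roi_in_ptbe=bool(r.roi_in_ptbe))
            for r in tables["patients"].itertuples()
        ]
        controls = [
            SubjectRecord(id=int(r.control_id), age=float(r.age), sex=str(r.sex),
                          group="control",
                          alps_right=float(r.alps_right), alps_left=float(r.alps_left))
            for r in tables["controls"].itertuples()
        ]
        return cls(patients, controls)

    def fit(self, hemisphere_rule: str = "tumor_side") -> "StudyResults":
        """Run every comparison and return the results object."""
        sections = {
            "demographics": _demographics(self.patients, self.controls),
            "hemisphere": run_hemisphere_comparison(self.patients),
            "group_comparisons": run_group_comparisons(self.patients),
            "regressions": run_regressions(self.patients),
        }
        if self.controls:
            sections["controls"] = _run_controls(self.controls)
            try:
                sections["matched_comparison"] = _run_matched_comparison(
                    self.patients, self.controls, hemisphere_rule)
            except ValueError as exc:  # e.g. no eligible control within tolerance
                sections["matched_comparison"] = {"error": str(exc)}
        else:
            sections["controls"] = None
            sections["matched_comparison"] = None
        return StudyResults(model=self, sections=sections)


def _round_half_away(x: float, ndigits: int = 2) -> float:
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class StudyResults:
    """Results of :meth:`AlpsStudy.fit`: full-precision sections + renderers."""

    model: AlpsStudy
    sections: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.sections[key]

    # -- rendering ----------------------------------------------------------

    @staticmethod
    def _fmt_group(d: dict) -> str:
        if d["sd"] is None:
            return f"{d['n']:>3}  mean {d['mean']:.2f}" if d["mean"] is not None else "  0  -"
        return (f"{d['n']:>3}  {_round_half_away(d['mean']):.2f} +/- "
                f"{_round_half_away(d['sd']):.2f}  "
                f"{_round_half_away(d['median']):.2f} "
                f"({_round_half_away(d['q1']):.2f}, {_round_half_away(d['q3']):.2f})")

    def summary(self) -> str:
        """Human-readable report; rounding (2 decimals, half away from zero)
        happens only here, never in the stored numbers."""
        s = self.sections
        demo = s["demographics"]
        lines = [
            "ALPS study summary",
            "==================",
            f"patients: {demo['n_included']} included of {demo['n_total']} "
            f"({demo['n_male']} male, {demo['n_female']} female; "
            f"{demo['n_primary']} primary, {demo['n_metastasis']} metastasis)",
            f"patient age: mean {demo['age']['mean']:.2f} +/- {demo['age']['sd']:.2f}",
            "",
            "ALPS index by hemisphere         n  mean +/- sd   median (q1, q3)",
        ]
        hemi = s["hemisphere"]
        lines.append(f"  tumor ipsilateral            {self._fmt_group(hemi['ipsilateral'])}")
        lines.append(f"  tumor contralateral          {self._fmt_group(hemi['contralateral'])}")
        if hemi.get("test"):
            t = hemi["test"]
            lines.append(f"  {t['method']}: W = {t['statistic']:g}, p = {t['p_two_sided']:.2g}")
        else:
            lines.append(f"  {hemi.get('note', 'test unavailable')}")
        lines.append("")
        lines.append("Ipsilateral index by subgroup    n  mean +/- sd   median (q1, q3)")
        for split, entry in s["group_comparisons"].items():
            p = entry["test"]["p_two_sided"]
            lines.append(f"  {split} (p = {p:.2g})")
            for label, d in entry.items():
                if label == "test":
                    continue
                lines.append(f"    {label:<26} {self._fmt_group(d)}")
        lines.append("")
        lines.append("Regressions (OLS)")
        for name, reg in s["regressions"].items():
            if reg is None:
                lines.append(f"  {name}: not computable")
                continue
            lines.append(f"  {name}: slope = {reg['slope']:.3g}, "
                         f"R^2 = {reg['r_squared']:.2g}, p = {reg['p_slope']:.2g}")
        if s.get("controls"):
            c = s["controls"]
            lines += [
                "",
                "Healthy controls                 n  mean +/- sd   median (q1, q3)",
                f"  right hemisphere             {self._fmt_group(c['right'])}",
                f"  left hemisphere              {self._fmt_group(c['left'])}",
                f"  age: mean {c['age']['mean']:.2f} +/- {c['age']['sd']:.2f}",
            ]
            if c.get("right_vs_left_test"):
                lines.append(f"  right vs left: p = {c['right_vs_left_test']['p_two_sided']:.2g}")
        return "\n".join(lines)

    def to_json(self) -> str:
        """Deterministic JSON (sorted keys, fixed float formatting)."""
        return json.dumps(self.sections, sort_keys=True, indent=1, allow_nan=False)

    def to_markdown(self) -> str:
        """Summary-style Markdown table of the subgroup comparisons."""
        s = self.sections
        rows = ["| Parameter | Participants | Mean +/- sd | Median (Q1, Q3) | p |",
                "|---|---|---|---|---|"]

        def _row(param, d, p=""):
            if d["sd"] is None:
                rows.append(f"| {param} | {d['n']} | {d['mean']:.2f} | - | {p} |")
            else:
                rows.append(
                    f"| {param} | {d['n']} | {_round_half_away(d['mean']):.2f} +/- "
                    f"{_round_half_away(d['sd']):.2f} | {_round_half_away(d['median']):.2f} "
                    f"({_round_half_away(d['q1']):.2f}, {_round_half_away(d['q3']):.2f}) | {p} |")

        hemi = s["hemisphere"]
        p_h = f"{hemi['test']['p_two_sided']:.2g}" if hemi.get("test") else "-"
        _row("Tumor ipsilateral", hemi["ipsilateral"], p_h)
        _row("Tumor contralateral", hemi["contralateral"], "")
        for split, entry in s["group_comparisons"].items():
            p = f"{entry['test']['p_two_sided']:.2g}"
            first = True
            for label, d in entry.items():
                if label == "test":
                    continue
                _row(f"{split}: {label}", d, p if first else "")
                first = False
        return "\n".join(rows)

    def to_csv_frame(self) -> pd.DataFrame:
        """Flat one-row-per-group frame of the descriptive cells."""
        records = []
        s = self.sections
        hemi = s["hemisphere"]
        for label in ("ipsilateral", "contralateral"):
            records.append({"section": "hemisphere", "group": label, **hemi[label]})
        for split, entry in s["group_comparisons"].items():
            for label, d in entry.items():
                if label == "test":
                    continue
                records.append({"section": split, "group": label, **d})
        if s.get("controls"):
            for label in ("right", "left"):
                records.append({"section": "controls", "group": label, **s["controls"][label]})
        return pd.DataFrame.from_records(records)

    def plot_hemispheres(self, ax=None):
        """Boxplot of ipsi/contra (and control) index distributions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        inc = [p for p in self.model.patients if p.included]
        data = [[p.alps_ipsi for p in inc], [p.alps_contra for p in inc]]
        labels = ["ipsilateral", "contralateral"]
        if self.model.controls:
            data.append([c.alps_right for c in self.model.controls]
                        + [c.alps_left for c in self.model.controls])
            labels.append("HC (both)")
        ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel("ALPS index")
        return ax


def emit_report(results: StudyResults, destination) -> None:
    """Write report.json / report.md / report.csv into a directory.

    Output is deterministic: repeated runs on the same inputs produce
    byte-identical files.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    (dest / "report.json").write_text(results.to_json() + "\n")
    (dest / "report.md").write_text(results.to_markdown() + "\n")
    results.to_csv_frame().to_csv(dest / "report.csv", index=False)
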
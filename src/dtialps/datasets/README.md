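# Packaged datasets

## `table1_patients.csv` — tumor cohort (30 rows, 24 included)

Per-patient demographics and measurements of the brain-tumor cohort.
Columns:

| column | type | notes |
|---|---|---|
| `patient_id` | int | unique, 1-30 |
| `age` | int | years; all >= 18 |
| `sex` | `male` / `female` | |
| `alps_ipsi` | float or empty | ALPS index, tumor-side hemisphere; empty iff excluded |
| `alps_contra` | float or empty | ALPS index, opposite hemisphere; empty iff excluded |
| `tumor_adc` | float | tumor-center ADC as printed in the source table; header unit mm^2/s, magnitudes (~75-2930) consistent with 1e-6 mm^2/s |
| `event` | `first_diagnosis` / `local_recurrence` / `distance_recurrence` | |
| `tumor_type` | `primary` / `metastasis` | the one histologically unclear tumor (patient 5) is counted as primary, keeping the 17 + 7 split |
| `tumor_details` | text | histology |
| `tumor_location` | text | free-text location |
| `tumor_side` | `left` / `right` / `intraventricular` | derived from `tumor_location` |
| `ptbe` | `yes` / `no` | peritumoral brain edema present |
| `roi_in_ptbe` | bool | ALPS ROI lay inside the edema (5 included patients) |
| `included` | bool | False for the 6 subjects excluded from analysis |

## `table2_controls.csv` — healthy controls (12 rows)

| column | type | notes |
|---|---|---|
| `control_id` | int | unique, 1-12 |
| `sex`, `age` | | matched to patients within +/- 2 years, same sex |
| `alps_right`, `alps_left` | float | per-hemisphere ALPS index |
| `matched_patient_ids` | `;`-separated ints | one control may serve up to 4 patients |

## `scheme64.bval` / `scheme64.bvec`

The default diffusion-encoding scheme: one b = 0 entry plus 64 unit
directions at b = 1000 s/mm^2, produced once by a deterministic
electrostatic-repulsion layout (`dtialps.phantom.electrostatic_directions`,
seed 7) and frozen here. FSL dialect, image-frame direction cosines.

## Known source-table quirks

These are properties of the transcribed tables, kept verbatim rather than
reconciled:

* The source report prints a mean tumor ADC of 1618.42, but the mean of the
  24 included `tumor_adc` cells is 1618.94. The tables are authoritative
  here; the recomputed value is what the pipeline reports.
* The printed R^2 for the contralateral-index-vs-age regression (0.003)
  is inconsistent with its own p-value: OLS on these rows gives
  R^2 = 0.0295 with p = 0.4223, reproducing the printed p = 0.422 exactly,
  so the printed R^2 appears to be a typo for 0.03.
* Printed standard deviations match the population (ddof = 0) convention;
  `dtialps.stats.describe` defaults to the sample (n - 1) convention and
  takes `ddof=0` to match the printed values.
* The control table's printed matching stretches its own +/- 2-year rule
  twice: patient 7 (38) vs control 5 (41) and patient 16 (60) vs control 3
  (57) are 3-year gaps. Kept verbatim.
* Printed quartiles follow an unstated quantile convention and are not
  exactly reproduced by the midpoint-of-halves hinges used here; medians
  are convention-free and do reproduce.
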
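"""ROI extraction, the ALPS index, tumor ADC, and the ROI suggestion helper."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtialps.alps import (RoiSpec, alps_from_rois, compute_alps_index,
                          read_roi_sidecar, roi_mean_diffusivities, suggest_roi,
                          tumor_roi_adc, write_roi_sidecar)
from dtialps.io import ScalarMap
from dtialps.phantom import default_alps_rois
from dtialps.tensor import DiffusionTensorField


def uniform_field(shape=(6, 6, 4), dxx=1.2e-3, dyy=0.8e-3, dzz=1.6e-3, mask=None):
    if mask is None:
        mask = np.ones(shape, bool)
    z = np.zeros(shape)
    return DiffusionTensorField(
        dxx=np.full(shape, dxx), dyy=np.full(shape, dyy), dzz=np.full(shape, dzz),
        dxy=z.copy(), dxz=z.copy(), dyz=z.copy(),
        s0_map=np.ones(shape), mask=mask, voxel_size=np.array([2.0, 2.0, 2.0]))


class TestRoiSpec:
    def test_standard_size_enforced_for_fiber_rois(self):
        with pytest.raises(ValueError, match="2, 2, 1"):
            RoiSpec(kind="projection", start_voxel=(0, 0, 0), size_voxels=(3, 3, 1))
        RoiSpec(kind="projection", start_voxel=(0, 0, 0), size_voxels=(3, 3, 1),
                allow_nonstandard_size=True)  # explicit override allowed

    def test_tumor_roi_size_is_free(self):
        RoiSpec(kind="tumor", start_voxel=(0, 0, 0), size_voxels=(3, 3, 3))

    def test_invalid_kind_and_hemisphere_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            RoiSpec(kind="cerebellum", start_voxel=(0, 0, 0), size_voxels=(2, 2, 1))
        with pytest.raises(ValueError, match="hemisphere"):
            RoiSpec(kind="projection", start_voxel=(0, 0, 0), size_voxels=(2, 2, 1),
                    hemisphere="top")

    def test_sidecar_round_trip(self, tmp_path):
        rois = [RoiSpec(kind="projection", start_voxel=(12, 6, 3), size_voxels=(2, 2, 1),
                        hemisphere="left"),
                RoiSpec(kind="tumor", start_voxel=(2, 4, 1), size_voxels=(3, 3, 3))]
        write_roi_sidecar(rois, tmp_path / "rois.json")
        assert read_roi_sidecar(tmp_path / "rois.json") == rois


class TestRoiMeans:
    def test_uniform_field_mean_is_the_value(self):
        field = uniform_field(dxx=1.2e-3)
        roi = RoiSpec(kind="projection", start_voxel=(1, 1, 1), size_voxels=(2, 2, 1))
        assert roi_mean_diffusivities(field, roi)["Dxx"] == pytest.approx(1.2e-3)

    def test_two_by_two_mean_is_plain_average(self):
        field = uniform_field()
        field.dxx[1:3, 1:3, 1] = np.array([[1e-3, 2e-3], [3e-3, 4e-3]])
        roi = RoiSpec(kind="projection", start_voxel=(1, 1, 1), size_voxels=(2, 2, 1))
        assert roi_mean_diffusivities(field, roi)["Dxx"] == pytest.approx(2.5e-3)

    def test_roi_straddling_grid_edge_rejected(self):
        roi = RoiSpec(kind="projection", start_voxel=(5, 5, 3), size_voxels=(2, 2, 1))
        with pytest.raises(ValueError, match="out of bounds"):
            roi_mean_diffusivities(uniform_field(), roi)

    def test_roi_touching_unfitted_voxels_rejected(self):
        mask = np.ones((6, 6, 4), bool)
        mask[2, 2, 1] = False
        roi = RoiSpec(kind="projection", start_voxel=(1, 1, 1), size_voxels=(2, 2, 1))
        with pytest.raises(ValueError, match="mask"):
            roi_mean_diffusivities(uniform_field(mask=mask), roi)


class TestAlpsIndex:
    def test_equal_diffusivities_give_unit_index(self):
        m = compute_alps_index({"Dxx": 1e-3, "Dyy": 1e-3}, {"Dxx": 1e-3, "Dzz": 1e-3})
        assert m.index == pytest.approx(1.0)

    def test_stated_arithmetic_example(self):
        # (1.2 + 1.0)/2 over (0.8 + 0.7)/2 = 1.1/0.75
        m = compute_alps_index({"Dxx": 1.2e-3, "Dyy": 0.8e-3},
                               {"Dxx": 1.0e-3, "Dzz": 0.7e-3})
        assert m.index == pytest.approx(1.1 / 0.75, rel=1e-12)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            compute_alps_index({"Dxx": 1e-3, "Dyy": -1e-3}, {"Dxx": 1e-3, "Dzz": 1e-3})

    @settings(deadline=None, max_examples=50)
    @given(dxx_p=st.floats(1e-4, 3e-3), dxx_a=st.floats(1e-4, 3e-3),
           dyy_p=st.floats(1e-4, 3e-3), dzz_a=st.floats(1e-4, 3e-3),
           scale=st.floats(0.01, 100.0))
    def test_scale_invariance_and_reciprocal_swap(self, dxx_p, dxx_a, dyy_p, dzz_a, scale):
        proj = {"Dxx": dxx_p, "Dyy": dyy_p}
        assoc = {"Dxx": dxx_a, "Dzz": dzz_a}
        base = compute_alps_index(proj, assoc).index
        scaled = compute_alps_index({k: v * scale for k, v in proj.items()},
                                    {k: v * scale for k, v in assoc.items()}).index
        assert scaled == pytest.approx(base, rel=1e-9)
        # feeding the perpendicular diffusivities as the numerator inverts the ratio
        swapped = compute_alps_index({"Dxx": dyy_p, "Dyy": dxx_p},
                                     {"Dxx": dzz_a, "Dzz": dxx_a}).index
        assert swapped == pytest.approx(1.0 / base, rel=1e-9)


class TestTumorAdc:
    def adc_map(self, value=1.5e-3, shape=(10, 10, 4)):
        return ScalarMap(data=np.full(shape, value), kind="ADC", voxel_size=(2, 2, 2))

    def test_uniform_field_returns_the_value_for_any_area(self):
        adc = self.adc_map(1.5e-3)
        for area in (1.0, 5.3, 40.0):
            assert tumor_roi_adc(adc, (10.0, 10.0, 3.0), area) == pytest.approx(1.5e-3)

    def test_subvoxel_area_reads_exactly_the_center_voxel(self):
        adc = self.adc_map(1.0e-3)
        adc.data[5, 5, 1] = 9.9e-3
        # 5.3 mm^2 -> radius 1.30 mm: no neighbouring 2x2 mm voxel center reached
        value = tumor_roi_adc(adc, (11.0, 11.0, 3.0), area_mm2=5.3)
        assert value == pytest.approx(9.9e-3)

    def test_larger_area_averages_neighbours(self):
        adc = self.adc_map(1.0e-3)
        adc.data[:, :, 1] = 2.0e-3
        value = tumor_roi_adc(adc, (11.0, 11.0, 3.0), area_mm2=40.0)
        assert value == pytest.approx(2.0e-3)

    def test_center_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            tumor_roi_adc(self.adc_map(), (100.0, 10.0, 3.0))

    def test_phantom_tumor_diffusivity_recovered_noiseless(self, noiseless_dwi,
                                                           scheme64, phantom_truth):
        from dtialps.tensor import trace_adc_map

        adc = trace_adc_map(noiseless_dwi, scheme64)
        # center of the tumor box in mm
        (x0, y0, z0), (sx, sy, sz) = phantom_truth.spec.region_layout["tumor"]
        center = ((x0 + sx / 2) * 2.0, (y0 + sy / 2) * 2.0, (z0 + sz / 2) * 2.0)
        designed = phantom_truth.spec.compartment_tensors["tumor"][0, 0]
        assert tumor_roi_adc(adc, center) == pytest.approx(designed, rel=0.01)


class TestSuggestRoi:
    def test_suggestions_fall_inside_designed_boxes(self, fitted_field, phantom_truth):
        proj, assoc = suggest_roi(fitted_field.fa_map(), fitted_field,
                                  hemisphere="left", slice_index=3)
        layout = phantom_truth.spec.region_layout
        for roi, label in ((proj, "projection_area"), (assoc, "association_area")):
            (x0, y0, _), (sx, sy, _) = layout[label]
            assert x0 <= roi.start_voxel[0] and roi.start_voxel[0] + 2 <= x0 + sx
            assert y0 <= roi.start_voxel[1] and roi.start_voxel[1] + 2 <= y0 + sy

    def test_all_zero_fa_yields_no_candidate(self, fitted_field):
        flat_fa = ScalarMap(data=np.zeros(fitted_field.grid_shape), kind="FA",
                            voxel_size=fitted_field.voxel_size)
        with pytest.raises(ValueError, match="no candidate window"):
            suggest_roi(flat_fa, fitted_field, hemisphere="left", slice_index=3)

    def test_explicit_rois_bypass_the_heuristic(self, fitted_field, phantom_truth):
        # contract: when explicit ROIs are given, the pipeline uses them verbatim
        proj, assoc = default_alps_rois()
        measurement = alps_from_rois(fitted_field, proj, assoc)
        assert measurement.index == pytest.approx(phantom_truth.designed_alps, rel=1e-6)
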
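"""Edge detection, centerline extraction, distance and mean area."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

import angioflow as af
from angioflow import EdgeDetectionError, ImageSequence, Modality, ROI
from angioflow.geometry import (
    DistanceIntensityProfile,
    build_geometry,
    detect_edges,
    extract_profiles,
    max_opacification_image,
)


def _profile(values, row=0):
    values = np.asarray(values, dtype=float)
    return DistanceIntensityProfile(row, np.arange(values.size, dtype=float), values)


def _chord_image(radius_px, center_col=40.0, n_rows=60, n_cols=80):
    """Projected circular tube: chord length 2 sqrt(R^2 - x^2) per column."""
    x = np.arange(n_cols) - center_col
    chord = 2.0 * np.sqrt(np.maximum(radius_px**2 - x**2, 0.0))
    return np.tile(chord, (n_rows, 1))


def test_rectangular_profile_edges_interpolate_the_threshold_crossing():
    left, right = detect_edges(_profile([0, 0, 100, 100, 100, 0, 0]), threshold_frac=0.12)
    assert left == pytest.approx(1.12)
    assert right == pytest.approx(4.88)
    assert right - left == pytest.approx(3.76)


def test_symmetric_profile_midpoint_is_the_center_of_symmetry():
    values = [0, 2, 8, 20, 8, 2, 0]
    left, right = detect_edges(_profile(values), threshold_frac=0.12)
    assert (left + right) / 2 == pytest.approx(3.0)


def test_no_signal_above_threshold_is_an_error():
    with pytest.raises(EdgeDetectionError):
        detect_edges(_profile([0.0, 0.0, 0.0]))
    with pytest.raises(EdgeDetectionError):
        detect_edges(_profile([0, 0, 5, 0, 0]), threshold_frac=0.12, global_max=1000.0)


def test_nearest_to_previous_centerline_resolves_double_crossings():
    values = [0, 30, 30, 0, 0, 0, 0, 80, 80, 80, 0]
    widest = detect_edges(_profile(values), threshold_frac=0.12)
    assert 6.0 < (widest[0] + widest[1]) / 2 < 10.0
    near_left = detect_edges(_profile(values), threshold_frac=0.12, prev_center_px=1.5)
    assert (near_left[0] + near_left[1]) / 2 == pytest.approx(1.5, abs=1.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(scale=st.floats(0.01, 100.0))
def test_edges_invariant_to_positive_rescaling(scale):
    base = _profile([0, 1, 5, 9, 10, 9, 5, 1, 0])
    scaled = _profile(np.asarray([0, 1, 5, 9, 10, 9, 5, 1, 0], float) * scale)
    assert detect_edges(base) == pytest.approx(detect_edges(scaled))


@pytest.mark.parametrize("diameter_px", [8, 14, 20, 30])
def test_chord_profile_width_matches_analytic_threshold_crossing(diameter_px):
    radius = diameter_px / 2.0
    img = _chord_image(radius)
    left, right = detect_edges(
        _profile(img[0]), threshold_frac=0.12, global_max=float(img.max())
    )
    expected = 2.0 * radius * np.sqrt(1.0 - 0.12**2)
    assert right - left == pytest.approx(expected, abs=1.0)


def test_scan_rows_step_by_spacing_and_include_both_roi_rows():
    img = np.ones((128, 30))
    roi_a = ROI(9, 12, 5, 10)   # center row 10
    roi_b = ROI(109, 112, 5, 10)  # center row 110
    profiles = extract_profiles(img, roi_a, roi_b, spacing_px=25)
    assert [p.station_row for p in profiles] == [10, 35, 60, 85, 110]
    wide = extract_profiles(img, roi_a, roi_b, spacing_px=200)
    assert [p.station_row for p in wide] == [10, 110]


def test_same_row_rois_and_bad_spacing_are_errors():
    img = np.ones((64, 30))
    roi = ROI(9, 12, 5, 10)
    with pytest.raises(ValueError):
        extract_profiles(img, roi, roi, spacing_px=25)
    other = ROI(40, 43, 5, 10)
    with pytest.raises(ValueError):
        extract_profiles(img, roi, other, spacing_px=0)


def test_max_opacification_of_constant_sequence_is_zero():
    seq = ImageSequence(np.full((6, 5, 5), 4.2), 0.25, 0.05)
    assert np.allclose(max_opacification_image(seq, 2), 0.0)


def test_max_opacification_captures_single_frame_enhancement():
    frames = np.zeros((5, 6, 6))
    frames[3, 2, 4] = 9.0
    seq = ImageSequence(frames, 0.25, 0.05)
    img = max_opacification_image(seq, 1)
    assert img[2, 4] == 9.0
    assert img.sum() == 9.0


def test_max_opacification_rejects_exhausted_baseline():
    seq = ImageSequence(np.zeros((4, 5, 5)), 0.25, 0.05)
    with pytest.raises(ValueError):
        max_opacification_image(seq, 4)


def _straight_geometry(diameter_px=10.0, pixel_spacing=0.03, taper_to=None, n_rows=260):
    img = np.zeros((n_rows, 80))
    for row in range(n_rows):
        if taper_to is None:
            radius = diameter_px / 2.0
        else:
            radius = (diameter_px + (taper_to - diameter_px) * row / (n_rows - 1)) / 2.0
        img[row] = _chord_image(radius, n_rows=1)[0]
    roi_a = ROI(18, 23, 38, 43)   # center row 20
    roi_b = ROI(218, 223, 38, 43)  # center row 220
    return build_geometry(img, roi_a, roi_b, pixel_spacing_cm=pixel_spacing,
                          median_size_px=0)


def test_straight_tube_path_length_is_row_separation():
    geom = _straight_geometry()
    assert geom.path_length_cm == pytest.approx(200 * 0.03, rel=1e-6)
    assert np.all(geom.right_edge_px > geom.left_edge_px)


def test_constant_diameter_mean_area_matches_circle_arithmetic():
    # stations all at (approximately) the analytic 12% chord width
    geom = _straight_geometry(diameter_px=10.0)
    width_cm = geom.diameters_px.mean() * 0.03
    assert geom.mean_area_cm2 == pytest.approx(np.pi * (width_cm / 2) ** 2, rel=1e-3)
    assert geom.mean_area_cm2 == pytest.approx(np.pi * 0.15**2, rel=0.1)


def test_tapered_tube_mean_area_is_mean_of_station_areas():
    geom = _straight_geometry(diameter_px=12.0, taper_to=8.0)
    station_areas = np.pi * (geom.diameters_px * 0.03 / 2.0) ** 2
    assert geom.mean_area_cm2 == pytest.approx(station_areas.mean(), rel=1e-12)
    # Jensen: mean of areas exceeds area of the mean diameter
    mean_d = geom.diameters_px.mean() * 0.03
    assert geom.mean_area_cm2 > np.pi * (mean_d / 2.0) ** 2


def test_centerline_lies_strictly_between_edges():
    geom = _straight_geometry(diameter_px=12.0, taper_to=8.0)
    centers = geom.centerline_px[:, 1]
    assert np.all(centers > geom.left_edge_px)
    assert np.all(centers < geom.right_edge_px)


def test_geometry_export(tmp_path):
    geom = _straight_geometry()
    geom.to_csv(tmp_path / "geom.csv")
    geom.centerline_to_csv(tmp_path / "centerline.csv")
    frame = np.loadtxt(tmp_path / "centerline.csv", delimiter=",", skiprows=1)
    assert frame.shape == geom.centerline_px.shape


def test_noisy_rendered_tube_diameters_within_one_pixel():
    # straight phantoms across diameters at DSA noise: median error <= 1 px
    for diameter_px in (8, 16, 30):
        errors = []
        for seed in range(3):
            cfg = af.PhantomConfig(
                diameter_cm=diameter_px * 0.05, true_flow_ml_min=600.0, seed=seed
            )
            seq, truth = af.render_sequence(cfg)
            opac = max_opacification_image(seq, 6)
            geom = build_geometry(opac, truth.roi1, truth.roi2, pixel_spacing_cm=0.05)
            expected = diameter_px * np.sqrt(1 - 0.12**2)
            errors.append(abs(np.median(geom.diameters_px) - expected))
        assert np.median(errors) <= 1.0


def test_loop_centerline_arc_length_matches_generating_curve():
    cfg = af.PhantomConfig(tube_shape="LOOP", true_flow_ml_min=500.0,
                           noise_sigma_frac=0.0, seed=3)
    seq, truth = af.render_sequence(cfg)
    opac = max_opacification_image(seq, 6)
    geom = build_geometry(opac, truth.roi1, truth.roi2, pixel_spacing_cm=0.05)
    r1 = int(round(truth.roi1.center_row))
    r2 = int(round(truth.roi2.center_row))
    analytic = truth.path.s_at_row(r2) - truth.path.s_at_row(r1)
    assert geom.path_length_cm == pytest.approx(analytic, rel=0.02)


def test_loop_profile_midpoints_stay_inside_the_rendered_tube():
    cfg = af.PhantomConfig(tube_shape="LOOP", true_flow_ml_min=500.0,
                           noise_sigma_frac=0.0, seed=3)
    seq, truth = af.render_sequence(cfg)
    opac = max_opacification_image(seq, 6)
    geom = build_geometry(opac, truth.roi1, truth.roi2, pixel_spacing_cm=0.05)
    dilated = ndimage.binary_dilation(truth.tube_mask, iterations=1)
    for row, col in geom.centerline_px:
        assert dilated[int(round(row)), int(round(col))]
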
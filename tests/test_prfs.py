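"""PRFS reconstruction: differences, unwrapping, drift correction, corridors."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from littherm.dose import area_mm2
from littherm.prfs import (
    AcquisitionParams,
    ComplexImageSeries,
    DriftReferenceROI,
    MonitoringROI,
    TemperatureMap,
    b0_correct,
    corridor_map,
    lethal_zone_prfs,
    phase_difference,
    phase_to_temperature,
    select_peak_slice,
    unwrap_temporal,
    wrap_phase,
)


def _series_from_phases(*phases):
    arr = np.stack([np.broadcast_to(np.asarray(p, dtype=float), (1, 8, 8)) for p in phases])
    return ComplexImageSeries(magnitude=np.ones_like(arr), phase=wrap_phase(arr))


# ---------------------------------------------------------------------------
# phase differences and wrapping
# ---------------------------------------------------------------------------


def test_identical_phases_give_zero_difference():
    s = _series_from_phases(1.3, 1.3)
    assert np.all(phase_difference(s, 1) == 0.0)


def test_wrapped_difference_crosses_pi_boundary():
    # actual 3.0 rad vs reference −3.0 rad: 6.0 wraps to 6.0 − 2π ≈ −0.2832
    s = _series_from_phases(-3.0, 3.0)
    diff = phase_difference(s, 1)
    assert np.allclose(diff, 6.0 - 2 * np.pi, atol=1e-12)


def test_difference_antisymmetry_away_from_boundary():
    a, b = 0.7, -1.2
    sab = _series_from_phases(a, b)
    sba = _series_from_phases(b, a)
    assert np.allclose(phase_difference(sab, 1), -phase_difference(sba, 1))


def test_difference_before_reference_rejected():
    s = ComplexImageSeries(
        magnitude=np.ones((3, 1, 4, 4)), phase=np.zeros((3, 1, 4, 4)), reference_index=1
    )
    with pytest.raises(ValueError):
        phase_difference(s, 0)


@given(st.floats(min_value=-50.0, max_value=50.0))
def test_wrap_phase_lands_in_half_open_interval(x):
    w = wrap_phase(x)
    assert -np.pi < w <= np.pi
    # wrapping preserves the angle modulo 2π
    assert abs((x - w) / (2 * np.pi) - round((x - w) / (2 * np.pi))) < 1e-9


# ---------------------------------------------------------------------------
# temporal unwrapping
# ---------------------------------------------------------------------------


def test_unwrap_is_identity_for_small_heating():
    truth = np.linspace(0.0, 2.0, 12)[:, None, None] * np.ones((1, 3, 3))
    unwrapped, flags = unwrap_temporal(wrap_phase(truth))
    assert np.allclose(unwrapped, truth)
    assert not flags.any()


def test_unwrap_recovers_ramp_through_pi():
    truth = np.linspace(0.0, 3 * np.pi, 40)[:, None, None] * np.ones((1, 2, 2))
    unwrapped, flags = unwrap_temporal(wrap_phase(truth))
    assert np.max(np.abs(unwrapped - truth)) < 1e-9
    assert not flags.any()


def test_unwrap_cooling_ramp_is_symmetric():
    truth = np.linspace(0.0, 3 * np.pi, 40)[:, None, None] * np.ones((1, 2, 2))
    up, _ = unwrap_temporal(wrap_phase(truth))
    down, _ = unwrap_temporal(wrap_phase(-truth))
    assert np.allclose(down, -up)


def test_unwrap_flags_steps_near_pi():
    jumpy = np.array([0.0, 0.97 * np.pi])[:, None, None] * np.ones((1, 1, 1))
    _, flags = unwrap_temporal(wrap_phase(jumpy))
    assert flags.all()


# ---------------------------------------------------------------------------
# B0 drift correction
# ---------------------------------------------------------------------------


def test_uniform_drift_removed_exactly():
    rng = np.random.default_rng(0)
    clean = rng.normal(0, 0.05, size=(16, 16))
    roi = DriftReferenceROI(center=(8, 8))
    corrected = b0_correct(clean + 0.3, roi)
    expected = clean - clean[roi.slices()].mean()
    assert np.allclose(corrected, expected, atol=1e-15)
    assert abs(corrected[roi.slices()].mean()) < 1e-15


def test_drift_roi_out_of_bounds_rejected():
    with pytest.raises(ValueError):
        b0_correct(np.zeros((8, 8)), DriftReferenceROI(center=(0, 0)))


def test_drift_roi_overlapping_monitoring_roi_warns():
    roi = DriftReferenceROI(center=(10, 10))
    mon = MonitoringROI(center=(12, 12), side=8)
    with pytest.warns(UserWarning):
        b0_correct(np.zeros((24, 24)), roi, monitoring_roi=mon)


# ---------------------------------------------------------------------------
# temperature conversion
# ---------------------------------------------------------------------------


def test_zero_difference_maps_to_baseline():
    tm = phase_to_temperature(np.zeros((4, 4)), AcquisitionParams())
    assert np.all(tm.temp == 37.0)


def test_known_phase_shift_maps_to_ten_degrees():
    acq = AcquisitionParams()
    tm = phase_to_temperature(np.full((2, 2), -0.4815), acq)
    assert np.allclose(tm.temp - acq.baseline_temp, 10.0, atol=0.01)


def test_halving_te_doubles_reconstructed_delta():
    acq1 = AcquisitionParams()
    acq2 = AcquisitionParams(echo_time=acq1.echo_time / 2)
    diff = np.full((2, 2), -0.2)
    d1 = phase_to_temperature(diff, acq1).temp - 37.0
    d2 = phase_to_temperature(diff, acq2).temp - 37.0
    assert np.allclose(d2, 2 * d1)


def test_acquisition_rejects_zero_echo_time():
    with pytest.raises(ValueError):
        AcquisitionParams(echo_time=0.0)


# ---------------------------------------------------------------------------
# corridors
# ---------------------------------------------------------------------------


def _map_with(temp_value, shape=(1, 20, 20)):
    temp = np.full(shape, 37.0)
    temp[0, 10, 10] = temp_value
    return TemperatureMap(temp=temp, valid=np.ones(shape, dtype=bool))


@pytest.mark.parametrize(
    "temp, label",
    [(39.9, 0), (40.0, 1), (54.9, 1), (55.0, 2), (56.0, 2), (69.9, 2),
     (70.0, 3), (84.9, 3), (85.0, 4), (99.0, 4), (120.0, 4)],
)
def test_corridor_labels_partition_temperature_axis(temp, label):
    roi = MonitoringROI(center=(10, 10), side=10)
    labels = corridor_map(_map_with(temp), roi)
    assert labels[0, 10, 10] == label


def test_hot_voxel_outside_roi_stays_unlabeled():
    roi = MonitoringROI(center=(4, 4), side=4)  # far from the hot voxel
    labels = corridor_map(_map_with(90.0), roi)
    assert labels[0, 10, 10] == 0


@given(st.floats(min_value=40.0, max_value=99.9))
def test_each_in_range_temperature_gets_exactly_one_corridor(temp):
    roi = MonitoringROI(center=(10, 10), side=10)
    labels = corridor_map(_map_with(temp), roi)
    assert labels[0, 10, 10] in (1, 2, 3, 4)


# ---------------------------------------------------------------------------
# lethal zone and slice selection
# ---------------------------------------------------------------------------


def test_lethal_threshold_is_inclusive():
    roi = MonitoringROI(center=(10, 10), side=10)
    at = lethal_zone_prfs(_map_with(55.0), roi, voxel_spacing=2.5)
    below = lethal_zone_prfs(_map_with(54.9), roi, voxel_spacing=2.5)
    assert at.area_mm2 == pytest.approx(6.25)
    assert below.area_mm2 == 0.0


def test_all_baseline_map_has_zero_area():
    roi = MonitoringROI(center=(10, 10), side=10)
    zone = lethal_zone_prfs(_map_with(37.0), roi)
    assert zone.area_mm2 == 0.0


def test_lethal_area_monotone_in_threshold():
    rng = np.random.default_rng(5)
    temp = TemperatureMap(
        temp=rng.uniform(37, 90, size=(3, 20, 20)), valid=np.ones((3, 20, 20), dtype=bool)
    )
    roi = MonitoringROI(center=(10, 10), side=16)
    areas = [
        lethal_zone_prfs(temp, roi, threshold=th).area_mm2 for th in (45, 55, 65, 75)
    ]
    assert all(a >= b for a, b in zip(areas, areas[1:]))


def test_invalid_voxels_excluded_from_lethal_zone():
    shape = (1, 20, 20)
    temp = np.full(shape, 80.0)
    valid = np.zeros(shape, dtype=bool)
    roi = MonitoringROI(center=(10, 10), side=10)
    zone = lethal_zone_prfs(TemperatureMap(temp=temp, valid=valid), roi)
    assert zone.area_mm2 == 0.0


@pytest.mark.parametrize(
    "areas, expected",
    [((10.0, 40.0, 20.0), 1), ((5.0, 5.0, 5.0), 0), ((0.0, 0.0, 7.0), 2)],
)
def test_select_peak_slice_rules(areas, expected):
    assert select_peak_slice(np.asarray(areas)) == expected


def test_select_peak_slice_from_masks():
    masks = np.zeros((3, 6, 6), dtype=bool)
    masks[2, :4, :4] = True
    masks[0, 0, 0] = True
    assert select_peak_slice(masks) == 2
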
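"""Phantom physics: power regimen, bioheat solver, MR encodings, cohorts."""

import numpy as np
import pytest
from scipy.special import erfc

from littherm.dose import DamageModelParams, arrhenius_omega
from littherm.phantom import (
    Anatomy,
    ApplicatorGeometry,
    CohortConfig,
    DriftModel,
    LaserRegimen,
    SimulationGrid,
    T1SignalModel,
    TemperatureSeries,
    TissueParams,
    applicator_count,
    drop_isotherm_temperature,
    encode_prfs,
    encode_t1_magnitude,
    generate_case,
    generate_cohort,
    ground_truth_necrosis,
    make_anatomy,
    plan_applicators,
    power_schedule,
    solve_pennes,
    stability_limit,
    total_energy,
)
from littherm.prfs import AcquisitionParams


# ---------------------------------------------------------------------------
# power regimen
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "t, expected",
    [
        (0.0, 2.0),  # first ramp minute
        (30.0, 2.0),
        (90.0, 4.0),  # second minute
        (359.0, 12.0),  # last ramp minute
        (360.0, 14.0),  # hold starts after the 6 min ramp
        (600.0, 14.0),  # mid-hold
        (1379.0, 14.0),
        (1381.0, 0.0),  # regimen over after 23 min
    ],
)
def test_power_schedule_ramp_hold_off(t, expected):
    assert power_schedule(LaserRegimen(), t) == expected


def test_power_schedule_rejects_negative_time():
    with pytest.raises(ValueError):
        power_schedule(LaserRegimen(), -1.0)


def test_power_schedule_nondecreasing_during_activity():
    t = np.arange(0.0, 1380.0, 5.0)
    p = power_schedule(LaserRegimen(), t)
    assert np.all(np.diff(p) >= 0)
    assert p.max() == 14.0


def test_total_energy_hold_only():
    # 14 W for 17 min = 14.28 kJ
    r = LaserRegimen(ramp_increment=0.0, power_max=14.0, hold_duration=17.0)
    assert total_energy(r) == pytest.approx(14.28)


def test_total_energy_zero_regimen():
    assert total_energy(LaserRegimen(ramp_increment=0.0, hold_duration=0.0)) == 0.0


def test_total_energy_two_fiber_standard_within_clinical_range():
    e = total_energy(LaserRegimen(n_fibers=2))
    assert e == pytest.approx(33.6)
    assert 12.2 <= e <= 65.2


def test_total_energy_beam_split_divides_power():
    full = total_energy(LaserRegimen(n_fibers=2))
    split = total_energy(
        LaserRegimen(n_fibers=2, beam_split_equal=True, fibers_per_source=2)
    )
    assert split == pytest.approx(full / 2)


# ---------------------------------------------------------------------------
# bioheat solver
# ---------------------------------------------------------------------------


def test_zero_source_simulation_is_stationary():
    grid = SimulationGrid(nx=9, ny=9, nz=5, dz=3.0, slice_pitch=3.0)
    series = solve_pennes(
        TissueParams(), [], LaserRegimen(), duration=120.0, dt=2.0, grid=grid
    )
    assert np.all(series.frames == 37.0)


def test_perfusion_only_relaxation_matches_closed_form():
    # conductivity 0, uniform +10 °C elevation: pure exponential return to T_a
    tissue = TissueParams(conductivity=0.0)
    grid = SimulationGrid(nx=5, ny=5, nz=5, dz=3.0, slice_pitch=3.0)
    series = solve_pennes(
        tissue,
        [],
        LaserRegimen(),
        duration=300.0,
        dt=0.05,
        grid=grid,
        store_interval=30.0,
        initial_temp=np.full((5, 5, 5), 47.0),
    )
    rate = tissue.perfusion_rate
    center = series.frames[:, 1, 2, 2]
    expected = 37.0 + 10.0 * np.exp(-rate * series.times)
    assert np.max(np.abs(center - expected) / 10.0) < 0.01


def test_point_source_matches_conduction_greens_function():
    # constant point source, no perfusion: T(r) = P/(4πkr)·erfc(r/(2√(αt)))
    tissue = TissueParams(perfusion_heat_sink=0.0)
    grid = SimulationGrid(nx=41, ny=41, nz=41, dx=2.0, dy=2.0, dz=2.0, slice_pitch=2.0)
    power = 4.0
    regimen = LaserRegimen(ramp_increment=0.0, power_max=power, hold_duration=30.0)
    series = solve_pennes(
        tissue,
        [ApplicatorGeometry(tip_length=1e-3)],
        regimen,
        duration=400.0,
        dt=1.0,
        grid=grid,
        attenuation_length_mm=0.8,
        absorbed_fraction=1.0,
        store_full_volume=True,
    )
    T = series.frames[-1]
    t = series.times[-1]
    alpha = tissue.diffusivity
    k = tissue.conductivity
    c = 20  # center index
    for r_vox in (4, 5, 6, 7):  # mid radii 8-14 mm
        r_m = r_vox * 2.0e-3
        analytic = power / (4 * np.pi * k * r_m) * erfc(r_m / (2 * np.sqrt(alpha * t)))
        profiles = [
            T[c, c, c + r_vox],
            T[c, c, c - r_vox],
            T[c, c + r_vox, c],
            T[c + r_vox, c, c],
        ]
        for val in profiles:
            assert abs((val - 37.0) - analytic) / analytic < 0.05


def test_unstable_dt_raises_with_bound():
    tissue = TissueParams()
    grid = SimulationGrid()
    limit = stability_limit(tissue, grid)
    with pytest.raises(ValueError, match="stability bound"):
        solve_pennes(tissue, [], LaserRegimen(), duration=60.0, dt=2 * limit, grid=grid)


def test_applicator_outside_grid_raises():
    grid = SimulationGrid(nx=9, ny=9, nz=5, dz=3.0, slice_pitch=3.0)
    bad = ApplicatorGeometry(tip_center=(500.0, 0.0, 0.0))
    with pytest.raises(ValueError, match="outside"):
        solve_pennes(TissueParams(), [bad], LaserRegimen(), duration=60.0, dt=1.0, grid=grid)


# ---------------------------------------------------------------------------
# ground-truth necrosis
# ---------------------------------------------------------------------------


def _constant_series(temp_c, duration_s, n=11):
    times = np.linspace(0.0, duration_s, n)
    frames = np.full((n, 1, 1, 1), float(temp_c))
    return TemperatureSeries(frames=frames, times=times, voxel_spacing=(2.5, 2.5))


def test_all_baseline_series_has_empty_necrosis():
    truth = ground_truth_necrosis(_constant_series(37.0, 1380.0))
    assert truth.necrosis_area.sum() == 0.0
    assert not truth.necrosis_mask.any()


def test_hot_voxel_with_closed_form_omega_above_one_is_necrotic():
    params = DamageModelParams()
    duration = 600.0
    omega_closed = duration * params.rate(70.0)
    assert omega_closed > 1  # premise of the scenario
    truth = ground_truth_necrosis(_constant_series(70.0, duration), params)
    assert truth.necrosis_mask.all()
    assert truth.omega_map.flat[0] == pytest.approx(omega_closed, rel=1e-12)


def test_extending_hold_never_shrinks_necrosis(standard_series):
    params = DamageModelParams()
    omega_short = arrhenius_omega(
        standard_series.frames[:40], standard_series.times[:40], params
    )
    omega_full = arrhenius_omega(standard_series.frames, standard_series.times, params)
    short_mask = omega_short >= 1.0
    full_mask = omega_full >= 1.0
    assert np.all(full_mask[short_mask])


# ---------------------------------------------------------------------------
# PRFS encoding
# ---------------------------------------------------------------------------


def _uniform_delta_series(delta_t, n=3, grid=None):
    grid = grid or SimulationGrid(nx=32, ny=32, nz=9)
    frames = np.full((n, 3, grid.ny, grid.nx), 37.0)
    frames[1:] += delta_t
    times = np.arange(n) * 15.0
    return TemperatureSeries(frames=frames, times=times, voxel_spacing=(grid.dy, grid.dx))


def test_prfs_phase_shift_of_ten_degrees():
    # 2π·γ·B0·α·TE·ΔT at TE 12 ms, 1.5 T, -0.01 ppm/°C, ΔT=10 → |Δφ| ≈ 0.4815
    series = _uniform_delta_series(10.0)
    anatomy = make_anatomy(SimulationGrid(nx=32, ny=32, nz=9))
    enc = encode_prfs(series, AcquisitionParams(), noise_sd=0.0, anatomy=anatomy)
    dphi = enc.phase[1] - enc.phase[0]
    assert np.allclose(np.abs(dphi), 0.4815, atol=5e-4)
    assert np.all(dphi < 0)  # heating shifts phase negative for water


def test_prfs_encoding_baseline_gives_zero_phase_difference():
    series = _uniform_delta_series(0.0)
    enc = encode_prfs(series, noise_sd=0.0)
    assert np.allclose(enc.phase[2] - enc.phase[0], 0.0, atol=1e-12)


def test_prfs_encoding_deterministic_per_seed():
    series = _uniform_delta_series(5.0)
    a = encode_prfs(series, noise_sd=0.1, seed=123)
    b = encode_prfs(series, noise_sd=0.1, seed=123)
    c = encode_prfs(series, noise_sd=0.1, seed=124)
    assert np.array_equal(a.magnitude, b.magnitude)
    assert np.array_equal(a.phase, b.phase)
    assert not np.array_equal(a.phase, c.phase)


# ---------------------------------------------------------------------------
# T1-magnitude encoding
# ---------------------------------------------------------------------------


def test_t1_signal_strictly_decreasing_in_temperature():
    sig = []
    for temp in (37.0, 60.0, 80.0):
        series = _uniform_delta_series(temp - 37.0)
        enc = encode_t1_magnitude(series, noise_sd=0.0)
        sig.append(enc.signal[-1, 1, 16, 16])
    assert sig[0] > sig[1] > sig[2]


def test_t1_baseline_signal_unchanged_noise_free():
    series = _uniform_delta_series(0.0)
    enc = encode_t1_magnitude(series, noise_sd=0.0)
    assert np.allclose(enc.signal[-1], enc.signal[0])


def test_drop_isotherm_is_above_50c_at_defaults():
    iso = drop_isotherm_temperature()
    assert iso > 50.0
    # steeper T1 dependence moves the isotherm cooler
    steep = drop_isotherm_temperature(T1SignalModel(temp_coefficient=0.02))
    assert steep < iso


def test_t1_drop_zone_contained_in_52c_zone(standard_series):
    enc = encode_t1_magnitude(standard_series, noise_sd=0.0)
    drop = 1.0 - enc.signal[-1] / enc.signal[0]
    zone25 = drop >= 0.25
    hot52 = standard_series.frames.max(axis=0) >= 52.0
    assert zone25.any()
    assert np.all(hot52[zone25])


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "diameter, n_min", [(0.5, 1), (2.0, 1), (2.1, 2), (3.0, 2), (5.5, 4)]
)
def test_applicator_count_rule(diameter, n_min):
    n = applicator_count(diameter)
    assert n >= n_min
    if diameter <= 2.0:
        assert n == 1


def test_planned_applicators_keep_overlap():
    for d in (2.5, 4.0, 6.0):
        apps = plan_applicators(d)
        ys = sorted(a.tip_center[1] for a in apps)
        spacings = np.diff(ys)
        # zones are <= 25 mm wide; >= 5 mm overlap needs spacing <= 20 mm
        assert np.all(spacings <= 20.0 + 1e-9)


def test_generate_case_deterministic(small_config):
    a = generate_case(small_config, "c", seed=11)
    b = generate_case(small_config, "c", seed=11)
    assert np.array_equal(a.prfs_series.magnitude, b.prfs_series.magnitude)
    assert np.array_equal(a.prfs_series.phase, b.prfs_series.phase)
    assert np.array_equal(a.t1_series.signal, b.t1_series.signal)
    assert np.array_equal(a.truth.omega_map, b.truth.omega_map)
    assert a.tumor_diameter_cm == b.tumor_diameter_cm


def test_cohort_pairs_share_one_temperature_series(small_config):
    case = generate_cohort(small_config, n_cases=1, seed=3)[0]
    # both encodings must be sampled on the same stored times
    assert np.array_equal(case.prfs_series.times, case.t1_series.times)
    assert case.prfs_series.magnitude.shape == case.t1_series.signal.shape
    if case.tumor_diameter_cm > 2.0:
        assert case.applicator_count >= 2
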
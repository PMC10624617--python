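import numpy as np
import pandas as pd
import pytest

from pdpxtal.xtal import (
    InconclusiveScanError,
    ReflectionSet,
    UnitCellSymmetry,
    compute_difference_map,
    derivative_threshold_elbow,
    extrapolate_structure_factors,
    fit_two_segment_elbow,
    integrate_negative_density,
    q_weight_differences,
    scan_n_ext,
    structure_factors_from_model,
    synthesize_map,
)


def test_friedel_reality(mini_toy_crystal):
    # the synthesis of a Friedel-complete amplitude set is real by
    # construction; verify values are finite real and reproduce the model
    rs_map = synthesize_map(mini_toy_crystal.dark_calc)
    assert np.isrealobj(rs_map.values)
    assert np.isfinite(rs_map.values).all()
    # density is concentrated at atoms: map max far above rms
    assert rs_map.values.max() > 10 * rs_map.rms


def test_peak_positions_recover_atoms(mini_toy_crystal):
    # Fourier round trip: map peaks sit within one grid step of atoms
    rs_map = synthesize_map(mini_toy_crystal.dark_calc)
    cell = mini_toy_crystal.spec.cell
    frac_mat = np.array(cell.gemmi_cell().frac.mat)
    shape = np.array(rs_map.values.shape)
    step = max(cell.a / shape[0], cell.b / shape[1], cell.c / shape[2])
    for pos in mini_toy_crystal.dark_model.atom_positions():
        fpos = (frac_mat @ pos) % 1.0
        idx = np.round(fpos * shape).astype(int) % shape
        box = rs_map.values[
            np.ix_(*((idx[i] + np.arange(-2, 3)) % shape[i] for i in range(3)))]
        # the atom's voxel is a local maximum within the box center
        assert rs_map.values[tuple(idx)] > 0.5 * box.max()
        assert box.max() > 5 * rs_map.rms


def test_difference_map_antisymmetry(mini_toy_crystal):
    data = mini_toy_crystal
    qw_lr = q_weight_differences(data.light_reflections, data.dark_reflections)
    qw_rl = q_weight_differences(data.dark_reflections, data.light_reflections)
    m1 = compute_difference_map(qw_lr.reflections, data.dark_calc)
    m2 = compute_difference_map(qw_rl.reflections, data.dark_calc)
    np.testing.assert_allclose(m1.values, -m2.values, atol=1e-10)


def test_difference_map_zero_mean(mini_toy_crystal):
    data = mini_toy_crystal
    qw = q_weight_differences(data.light_reflections, data.dark_reflections)
    m = compute_difference_map(qw.reflections, data.dark_calc)
    # zero up to single-precision accumulation of the grid FFT
    assert abs(m.mean) < 1e-8 * m.rms


def test_integrate_negative_density_threshold():
    # synthetic map with one negative voxel block inside the region
    cell = UnitCellSymmetry(10.0, 10.0, 10.0, space_group="P 1")
    values = np.zeros((10, 10, 10))
    values[5, 5, 5] = -4.0
    values[0, 0, 0] = -4.0  # outside the region
    from pdpxtal.xtal.types import RealSpaceMap
    rs_map = RealSpaceMap(cell, values)
    centers = np.array([[5.0, 5.0, 5.0]])
    voxvol = rs_map.voxel_volume
    total = integrate_negative_density(rs_map, centers, radius=1.5,
                                       threshold=-1.0)
    assert total == pytest.approx(4.0 * voxvol, rel=1e-12)
    # threshold below the feature -> nothing integrated
    assert integrate_negative_density(rs_map, centers, 1.5,
                                      threshold=-5.0) == 0.0
    with pytest.raises(ValueError):
        integrate_negative_density(rs_map, centers, 1.5, threshold=0.5)


def test_extrapolation_zero_identity(mini_toy_crystal):
    data = mini_toy_crystal
    qw = q_weight_differences(data.light_reflections, data.dark_reflections)
    ext = extrapolate_structure_factors(qw.reflections, data.dark_calc, 0.0)
    merged = ext.join_common(data.dark_calc)
    np.testing.assert_allclose(merged["F_a"], merged["F_b"], atol=1e-10)


def test_extrapolation_linear_in_n(mini_toy_crystal):
    data = mini_toy_crystal
    qw = q_weight_differences(data.light_reflections, data.dark_reflections)
    maps = {}
    for n in (0.0, 1.0, 4.0):
        ext = extrapolate_structure_factors(qw.reflections, data.dark_calc, n)
        maps[n] = synthesize_map(ext).values
    predicted = maps[0.0] + 4.0 * (maps[1.0] - maps[0.0])
    # map synthesis runs on a single-precision grid
    np.testing.assert_allclose(maps[4.0], predicted, atol=1e-5)


def test_extrapolation_rejects_negative_n(mini_toy_crystal):
    data = mini_toy_crystal
    qw = q_weight_differences(data.light_reflections, data.dark_reflections)
    with pytest.raises(ValueError):
        extrapolate_structure_factors(qw.reflections, data.dark_calc, -1.0)


def test_two_segment_elbow_on_hockey_stick():
    x = np.linspace(0, 20, 41)
    y = np.maximum(x - 12.5, 0.0) * 3.0
    b, report = fit_two_segment_elbow(x, y)
    assert b == pytest.approx(12.5, abs=0.15)
    assert report["slope_right"] == pytest.approx(3.0, rel=1e-3)


def test_derivative_threshold_elbow():
    x = np.linspace(0, 20, 81)
    y = np.maximum(x - 10.0, 0.0) * 2.0
    b = derivative_threshold_elbow(x, y)
    assert b == pytest.approx(10.0, abs=0.5)


def test_scan_flat_curve_inconclusive(mini_toy_crystal):
    data = mini_toy_crystal
    # a null difference set: no negative density ever builds up
    null = data.dark_calc.copy_with(F=np.zeros(len(data.dark_calc)),
                                    sigF=np.zeros(len(data.dark_calc)))
    null.data.drop(columns=["phase"], inplace=True)
    with pytest.raises(InconclusiveScanError):
        scan_n_ext(null, data.dark_calc, data.dark_model,
                   data.dark_model.atom_positions(), radius=1.2,
                   n_ext_grid=np.linspace(0.5, 20, 20))
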
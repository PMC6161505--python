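"""Large-deflection plate mechanics: solves, modulus fit, elongation."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hexpore import (
    LoadDeflectionSeries,
    PlateSystem,
    concentrated_load_for_deflection,
    deflection_under_concentrated_load,
    deflection_under_uniform_load,
    elongation,
    fit_equivalent_modulus,
    pore_size_change,
    predict_filtration_deformation,
    pressure_to_load,
)
from hexpore.mechanics import DegenerateFitError, uniform_load_for_deflection
from hexpore.synthetic import gen_load_deflection

from .conftest import oracle_deflection_concentrated, oracle_deflection_uniform


def test_zero_deflection_needs_zero_load(plate):
    assert concentrated_load_for_deflection(plate, 0.0) == 0.0
    assert deflection_under_concentrated_load(plate, 0.0) == 0.0
    assert deflection_under_uniform_load(plate, 0.0) == 0.0


def test_concentrated_load_reference_value(plate):
    """Direct evaluation at d_v = 100 μm, with symbolically re-derived
    coefficients 257.5/324 and 8/3 at μ = 0.5 as the independent check."""
    q = concentrated_load_for_deflection(plate, 100e-6)
    assert q == pytest.approx(1.84e-3, rel=5e-3)
    E, h, dv, a = plate.E, plate.h, 100e-6, plate.a
    expected = (math.pi / a**2) * (
        (257.5 / 324.0) * E * h * dv**3 + (8.0 / 3.0) * E * h**3 * dv
    )
    assert q == pytest.approx(expected, rel=1e-14)


def test_load_linear_in_modulus(plate):
    doubled = PlateSystem(E=2 * plate.E, mu=plate.mu, h=plate.h, a=plate.a)
    q1 = concentrated_load_for_deflection(plate, 50e-6)
    assert concentrated_load_for_deflection(doubled, 50e-6) == pytest.approx(2 * q1)


@pytest.mark.parametrize("factor", [0.1, 1.0, 10.0])
def test_concentrated_roundtrip_to_ten_digits(plate, factor):
    dv = factor * plate.h
    q = concentrated_load_for_deflection(plate, dv)
    assert deflection_under_concentrated_load(plate, q) == pytest.approx(
        dv, rel=1e-10
    )


def test_uniform_roundtrip(plate):
    dv = 200e-6
    q = uniform_load_for_deflection(plate, dv)
    assert deflection_under_uniform_load(plate, q) == pytest.approx(dv, rel=1e-10)


def test_solver_matches_bisection_oracle(plate):
    for q in np.logspace(-7, 0, 15):
        assert deflection_under_concentrated_load(plate, q) == pytest.approx(
            oracle_deflection_concentrated(plate, q), rel=1e-10
        )
        assert deflection_under_uniform_load(plate, q) == pytest.approx(
            oracle_deflection_uniform(plate, q), rel=1e-10
        )


def test_small_load_limit_is_linear_plate_bending(plate):
    """d_v → 3(1−μ)·q·a²/(4π·E·h³) as q → 0 (linearised concentrated law)."""
    q = 1e-12
    linear = 3 * (1 - plate.mu) * q * plate.a**2 / (4 * math.pi * plate.E * plate.h**3)
    assert deflection_under_concentrated_load(plate, q) == pytest.approx(
        linear, rel=1e-6
    )


def test_uniform_deflection_strictly_monotone_in_load(plate):
    loads = np.logspace(-8, 0, 30)
    defl = [deflection_under_uniform_load(plate, q) for q in loads]
    assert np.all(np.diff(defl) > 0)


def test_negative_inputs_rejected(plate):
    with pytest.raises(ValueError):
        concentrated_load_for_deflection(plate, -1e-6)
    with pytest.raises(ValueError):
        deflection_under_concentrated_load(plate, -1e-3)
    with pytest.raises(ValueError):
        deflection_under_uniform_load(plate, -1e-3)


@given(k=st.floats(0.1, 100.0), q=st.floats(1e-8, 1e-1))
@settings(deadline=None, max_examples=30)
def test_deflection_invariant_under_joint_load_modulus_scaling(k, q):
    base = PlateSystem(E=3.01e9)
    scaled = PlateSystem(E=k * 3.01e9)
    assert deflection_under_concentrated_load(
        scaled, k * q
    ) == pytest.approx(deflection_under_concentrated_load(base, q), rel=1e-12)


# --- modulus fitting ------------------------------------------------------


def test_fit_recovers_modulus_from_noiseless_series():
    series = gen_load_deflection(E_true=2.76e9, noise_sd_rel=0.0, seed=3)
    e_hat, _ = fit_equivalent_modulus(series)
    assert e_hat == pytest.approx(2.76e9, rel=1e-12)


def test_fit_noisy_series_within_three_stderr():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        series = gen_load_deflection(E_true=3.01e9, noise_sd_rel=0.05, seed=11)
    e_hat, stderr = fit_equivalent_modulus(series)
    assert abs(e_hat - 3.01e9) <= 3 * stderr


def test_fit_scales_linearly_with_loads():
    series = gen_load_deflection(E_true=3.01e9, noise_sd_rel=0.0, seed=5)
    scaled = LoadDeflectionSeries(4.0 * series.loads, series.deflections)
    assert fit_equivalent_modulus(scaled)[0] == pytest.approx(
        4.0 * fit_equivalent_modulus(series)[0]
    )


def test_fit_degenerate_on_all_zero_deflections():
    series = LoadDeflectionSeries([0.0, 1e-3, 2e-3], [0.0, 0.0, 0.0])
    with pytest.raises(DegenerateFitError):
        fit_equivalent_modulus(series)


def test_series_warns_when_not_monotone_consistent():
    with pytest.warns(UserWarning, match="monotone"):
        LoadDeflectionSeries([1e-3, 2e-3, 3e-3], [1e-6, 3e-6, 2e-6])


def test_series_validation():
    with pytest.raises(ValueError):
        LoadDeflectionSeries([1e-3], [1e-6])
    with pytest.raises(ValueError):
        LoadDeflectionSeries([1e-3, -1e-3], [1e-6, 1e-6])


# --- elongation and pore-size change -------------------------------------


def test_elongation_limits():
    assert elongation(6.5e-3, 0.0) == 0.0
    assert elongation(1.0, 1.0) == pytest.approx(math.sqrt(2.0) - 1.0, rel=1e-14)


def test_elongation_small_deflection_taylor():
    a = 6.5e-3
    for ratio in [1e-3, 5e-3, 1e-2]:
        dv = ratio * a
        assert elongation(a, dv) == pytest.approx(ratio**2 / 2.0, rel=1e-4)


def test_elongation_rejects_bad_inputs():
    with pytest.raises(ValueError):
        elongation(0.0, 1e-6)
    with pytest.raises(ValueError):
        elongation(1.0, -1e-6)


def test_pore_size_change_consistent_with_reported_bounds():
    """δ = 0.28 % on the largest-pore design gives a change of about 40 nm."""
    assert pore_size_change(0.0, 14.52) == 0.0
    change_d = pore_size_change(0.0028, 14.52)
    assert change_d == pytest.approx(40.7, abs=0.1)
    assert abs(change_d - 40.0) / 40.0 < 0.10
    assert pore_size_change(0.0028, 12.57) == pytest.approx(35.2, abs=0.1)
    assert pore_size_change(0.0028, 12.57) <= 40.0


def test_predict_deformation_chains_components(plate):
    zero = predict_filtration_deformation(plate, 14.52, 0.0)
    assert (zero.d_v, zero.delta, zero.pore_change_nm, zero.load) == (0, 0, 0, 0)
    res = predict_filtration_deformation(plate, 14.52, 0.05)
    assert res.pore_change_nm / 14.52 == pytest.approx(res.delta * 1e3, rel=1e-12)
    assert res.d_v == pytest.approx(
        deflection_under_uniform_load(plate, 0.05), rel=1e-12
    )


def test_deflection_of_half_millimetre_gives_quarter_percent_elongation():
    """The load regime with d_v ≈ 0.49 mm on a 6.5 mm half-span sits at the
    reported sub-0.28 % elongation level."""
    assert elongation(6.5e-3, 0.4866e-3) == pytest.approx(0.0028, rel=1e-2)


def test_pressure_to_load():
    assert pressure_to_load(100.0, 13e-3) == pytest.approx(100.0 * 13e-3**2)
    with pytest.raises(ValueError):
        pressure_to_load(-1.0, 13e-3)


def test_plate_system_validation():
    with pytest.raises(ValueError):
        PlateSystem(E=-1.0)
    with pytest.raises(ValueError):
        PlateSystem(E=1e9, mu=1.2)
    with pytest.raises(ValueError):
        PlateSystem(E=1e9, h=1e-2, a=1e-3)
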
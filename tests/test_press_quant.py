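"""PRESS / absolute-quantification tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gshmrs.core import AcquisitionParams, ParameterError, StructuralError
from gshmrs.press import (VoxelComposition, absolute_gsh, csf_correct,
                          estimate_water_t2, fit_press, make_basis,
                          preprocess_press, water_peak_area, water_reference)
from gshmrs.simulate import (WATER_AMPLITUDE_PER_UNIT_GAIN, NoiseModel,
                             simulate_press, simulate_water_pair)


@pytest.fixture(scope="module")
def basis():
    return make_basis()


def test_press_fit_recovers_concentrations(basis):
    truth = {"Cr": 6.1, "NAA": 8.0, "Cho": 1.5, "Glx": 9.0}
    fid = simulate_press(truth, noise=NoiseModel(noise_sd=0.4, seed=5))
    spec = preprocess_press(fid)
    fit = fit_press(spec, basis)
    assert fit.qc_pass
    for name, conc in truth.items():
        assert fit.concentrations[name] == pytest.approx(conc, rel=0.05)


def test_water_t2_estimate_matches_closed_form():
    t2 = 82.0
    w_short, w_long = simulate_water_pair(t2, te_pair_ms=(68.0, 122.0))
    assert estimate_water_t2(w_short, w_long) == pytest.approx(t2, rel=1e-9)
    # argument order must not matter
    assert estimate_water_t2(w_long, w_short) == pytest.approx(t2, rel=1e-9)
    with pytest.raises(ParameterError):
        estimate_water_t2(w_short, w_short)


def test_water_reference_round_trips_simulated_cr(basis):
    """Noise-free forward + inverse chain recovers the Cr concentration."""
    cr_true = 6.09
    fid = simulate_press({"Cr": cr_true, "NAA": 1.3 * cr_true,
                          "Cho": 0.25 * cr_true, "Glx": 1.5 * cr_true})
    fit = fit_press(preprocess_press(fid), basis)
    t2 = 80.0
    w_short, w_long = simulate_water_pair(t2)
    t2_est = estimate_water_t2(w_short, w_long)
    cr_iu = water_reference(fit, w_short, t2_est)
    assert cr_iu == pytest.approx(cr_true, rel=0.05)
    # invariance under receiver gain: scale every acquisition by the same g
    g = 3.7
    fid_g = simulate_press({"Cr": cr_true, "NAA": 1.3 * cr_true,
                            "Cho": 0.25 * cr_true, "Glx": 1.5 * cr_true},
                           gain=g)
    fit_g = fit_press(preprocess_press(fid_g), basis)
    w_short_g, w_long_g = simulate_water_pair(t2, gain=g)
    cr_g = water_reference(fit_g, w_short_g,
                           estimate_water_t2(w_short_g, w_long_g))
    assert cr_g == pytest.approx(cr_iu, rel=1e-6)


def test_water_reference_refuses_failed_qc(basis):
    fid = simulate_press({"Cr": 6.0, "NAA": 8.0, "Cho": 1.5, "Glx": 9.0})
    fit = fit_press(preprocess_press(fid), basis)
    fit.qc_pass = False
    w_short, _ = simulate_water_pair(80.0)
    with pytest.raises(StructuralError):
        water_reference(fit, w_short, 80.0)


def test_water_peak_area_is_first_sample_magnitude():
    w, _ = simulate_water_pair(80.0)
    assert water_peak_area(w) == pytest.approx(
        WATER_AMPLITUDE_PER_UNIT_GAIN * np.exp(-68.0 / 80.0), rel=1e-12)


@given(st.floats(0.01, 100.0), st.floats(0.0, 0.9))
def test_csf_correct_closed_form(c, f):
    assert csf_correct(c, f) == pytest.approx(c / (1 - f), rel=1e-12)


def test_csf_correct_accepts_voxel_composition_and_validates():
    voxel = VoxelComposition(f_gm=0.5, f_wm=0.3, f_csf=0.2)
    assert csf_correct(4.0, voxel) == pytest.approx(5.0)
    with pytest.raises(ParameterError):
        VoxelComposition(f_gm=0.5, f_wm=0.5, f_csf=0.2)
    with pytest.raises(ParameterError):
        csf_correct(4.0, 1.0)


def test_absolute_gsh_is_product_and_validates():
    assert absolute_gsh(0.03, 6.0) == pytest.approx(0.18)
    with pytest.raises(ParameterError):
        absolute_gsh(np.nan, 6.0)
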
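"""Forward-model tests: editing bookkeeping, determinism, water decay."""

import numpy as np
import pytest

from gshmrs.core import AcquisitionParams, ParameterError, to_spectrum
from gshmrs.edited import difference_edit
from gshmrs.press import water_peak_area
from gshmrs.simulate import (GSH_PPM, MetabolitePeak, NoiseModel,
                             simulate_fid, simulate_megapress_pair,
                             simulate_water_pair)


def test_simulation_is_deterministic_under_fixed_seed():
    noise = NoiseModel(noise_sd=0.05, freq_jitter_sd=1.0,
                       phase_jitter_sd=0.05, seed=42)
    a_on, a_off = simulate_megapress_pair(0.03, noise=noise)
    b_on, b_off = simulate_megapress_pair(0.03, noise=noise)
    assert np.array_equal(a_on.samples, b_on.samples)
    assert np.array_equal(a_off.samples, b_off.samples)


def test_suppressed_resonances_cancel_and_edited_survive_at_efficiency():
    """Zero noise: the OFF-ON difference carries efficiency x amplitude of
    the edited resonance only; everything suppressed cancels exactly."""
    eff = 0.74
    gsh_cr = 0.05
    on, off = simulate_megapress_pair(gsh_cr, editing_efficiency=eff)
    diff = off.samples - on.samples
    acq = on.acq
    t = acq.time_axis()
    f = acq.offset_hz(GSH_PPM)
    expected = -eff * gsh_cr * np.exp((2j * np.pi * f - 12.0) * t)
    assert np.allclose(diff, expected, atol=1e-12)


def test_difference_edit_sign_normalises_the_gsh_extremum():
    on, off = simulate_megapress_pair(0.05, editing_efficiency=0.74)
    d = difference_edit(to_spectrum(on), to_spectrum(off))
    m = d.window(GSH_PPM - 0.05, GSH_PPM + 0.05)
    assert d.values.real[m].max() > 0


def test_lorentzian_linewidth_matches_damping():
    """FWHM of a simulated line is damping / pi Hz."""
    from gshmrs.preprocess import zero_fill

    acq = AcquisitionParams()
    damping = 12.0
    peak = MetabolitePeak("x", 3.0, 1.0, damping)
    # zero-fill for a grid fine enough to resolve the half-maximum crossings
    spec = to_spectrum(zero_fill(simulate_fid([peak], acq), 16 * acq.n_points))
    y = spec.values.real
    top = y.max()
    above = spec.ppm[y >= top / 2]
    fwhm_hz = (above.max() - above.min()) * acq.hz_per_ppm
    assert fwhm_hz == pytest.approx(damping / np.pi, rel=0.15)


def test_peak_validation():
    with pytest.raises(ParameterError):
        MetabolitePeak("bad", 3.0, -1.0, 12.0)
    with pytest.raises(ParameterError):
        MetabolitePeak("bad", 3.0, 1.0, 0.0)
    with pytest.raises(ParameterError):
        MetabolitePeak("bad", 3.0, 1.0, 12.0, edit_behavior="mystery")


def test_out_of_window_peak_is_rejected():
    acq = AcquisitionParams()
    with pytest.raises(ParameterError):
        simulate_fid([MetabolitePeak("far", 25.0, 1.0, 12.0)], acq)


def test_water_pair_areas_follow_t2_decay():
    t2 = 80.0
    w_short, w_long = simulate_water_pair(t2, te_pair_ms=(68.0, 122.0))
    ratio = water_peak_area(w_short) / water_peak_area(w_long)
    assert ratio == pytest.approx(np.exp((122.0 - 68.0) / t2), rel=1e-9)
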
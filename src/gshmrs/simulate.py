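"""Forward simulation of single-voxel MRS acquisitions.

The signal model is a sum of damped complex exponentials (Lorentzian lines):
a resonance of amplitude ``a``, chemical shift ``delta`` and damping ``d`` (Hz)
contributes ``a * exp((2j*pi*f - d) * t + 1j*phase)`` with
``f = (delta - ref) * f0``.  The frequency-domain full width at half maximum of
such a line is ``d / pi`` Hz.  Peak areas are proportional to amplitude.

The simulated lineshape is deliberately Lorentzian even though the
quantification stage fits Gaussians: the mismatch keeps fit-error statistics
nonzero and realistic.  Spectral editing is modelled by amplitude bookkeeping:
an *edited* resonance appears at full amplitude in the editing-ON acquisition
and at ``(1 - efficiency)`` of it in OFF, so the OFF-ON difference carries
``efficiency * amplitude``; *suppressed* resonances are identical in ON and
OFF and cancel; *unedited* resonances occur only in non-edited (PRESS/water)
acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import FID, AcquisitionParams, ParameterError

#: in vivo water concentration scale (IU-equivalent) times tissue visibility
WATER_CONCENTRATION_IU = 55510.0
TISSUE_WATER_FRACTION = 0.7
WATER_AMPLITUDE_PER_UNIT_GAIN = WATER_CONCENTRATION_IU * TISSUE_WATER_FRACTION

GSH_PPM = 2.95
CR_PPM = 3.03

EDIT_BEHAVIORS = ("edited", "suppressed", "unedited")


@dataclass(frozen=True)
class MetabolitePeak:
    """One Lorentzian resonance with its editing behaviour."""

    name: str
    center_ppm: float
    amplitude: float
    damping_hz: float
    phase_rad: float = 0.0
    edit_behavior: str = "suppressed"
    edit_efficiency: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ParameterError(f"peak {self.name}: amplitude must be >= 0")
        if self.damping_hz <= 0:
            raise ParameterError(f"peak {self.name}: damping must be > 0")
        if self.edit_behavior not in EDIT_BEHAVIORS:
            raise ParameterError(f"peak {self.name}: unknown edit behaviour")
        if not 0.0 <= self.edit_efficiency <= 1.0:
            raise ParameterError(f"peak {self.name}: efficiency outside [0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """Additive complex Gaussian noise plus per-transient instability.

    ``noise_sd`` is the standard deviation per point of the independent real
    and imaginary noise; ``freq_jitter_sd`` (Hz) and ``phase_jitter_sd``
    (radians) draw one frequency / zero-order phase offset per transient.
    Identical seed and parameters give bit-identical output.
    """

    noise_sd: float = 0.0
    freq_jitter_sd: float = 0.0
    phase_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_sd", "freq_jitter_sd", "phase_jitter_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def scaled(self, factor: float) -> "NoiseModel":
        return replace(self, noise_sd=self.noise_sd * factor)


def _check_in_window(peaks: list[MetabolitePeak], acq: AcquisitionParams) -> None:
    lo, hi = acq.ppm_window
    for p in peaks:
        if not lo <= p.center_ppm <= hi:
            raise ParameterError(
                f"peak {p.name} at {p.center_ppm} ppm outside window {lo:.2f}-{hi:.2f}")


def simulate_fid(peaks: list[MetabolitePeak], acq: AcquisitionParams,
                 noise: NoiseModel | None = None,
                 rng: np.random.Generator | None = None,
                 provenance: str = "SIM") -> FID:
    """Sample the sum-of-Lorentzians model at the dwell time.

    ``rng`` overrides the generator derived from ``noise.seed``; passing the
    same generator across calls advances it (independent noise per transient).
    """
    _check_in_window(peaks, acq)
    t = acq.time_axis()
    sig = np.zeros(acq.n_points, dtype=complex)
    for p in peaks:
        f = acq.offset_hz(p.center_ppm)
        sig += p.amplitude * np.exp((2j * np.pi * f - p.damping_hz) * t
                                    + 1j * p.phase_rad)
    if noise is not None and (noise.noise_sd > 0 or noise.freq_jitter_sd > 0
                              or noise.phase_jitter_sd > 0):
        if rng is None:
            rng = noise.rng()
        df = rng.normal(0.0, noise.freq_jitter_sd) if noise.freq_jitter_sd else 0.0
        dphi = (rng.normal(0.0, noise.phase_jitter_sd)
                if noise.phase_jitter_sd else 0.0)
        if df or dphi:
            sig = sig * np.exp(1j * (2 * np.pi * df * t + dphi))
        if noise.noise_sd:
            sig = sig + noise.noise_sd * (rng.standard_normal(acq.n_points)
                                          + 1j * rng.standard_normal(acq.n_points))
    return FID(samples=sig, acq=acq, provenance=provenance, history=["simulate_fid"])


def default_background_peaks(cr_amplitude: float = 1.0) -> list[MetabolitePeak]:
    """Resonances identical in ON and OFF (cancel in the difference).

    Cr 3.03 is the reference singlet; choline, NAA, aspartate and a residual
    water line complete a realistic edited-voxel background.
    """
    a = cr_amplitude
    return [
        MetabolitePeak("Cr", CR_PPM, a, 12.0),
        MetabolitePeak("Cho", 3.19, 0.25 * a, 13.0),
        MetabolitePeak("NAA", 2.01, 1.2 * a, 12.0),
        MetabolitePeak("Asp", 2.82, 0.05 * a, 14.0),
        MetabolitePeak("water_residual", 4.70, 2.0 * a, 30.0),
    ]


def default_coedited_peaks(cr_amplitude: float = 1.0) -> list[MetabolitePeak]:
    """Co-edited contaminants that survive the difference with GSH."""
    a = cr_amplitude
    return [
        MetabolitePeak("coedit_2.82", 2.82, 0.012 * a, 14.0,
                       edit_behavior="edited", edit_efficiency=0.50),
        MetabolitePeak("coedit_3.01", 3.01, 0.010 * a, 14.0,
                       edit_behavior="edited", edit_efficiency=0.45),
        MetabolitePeak("coedit_3.10", 3.10, 0.008 * a, 14.0,
                       edit_behavior="edited", edit_efficiency=0.50),
        MetabolitePeak("coedit_3.26", 3.26, 0.014 * a, 13.0,
                       edit_behavior="edited", edit_efficiency=0.60),
    ]


#: fixed macromolecular comb: (center ppm, weight, sign).  Teeth carrying a
#: positive (absorptive) sign are kept outside 2.86-3.04 p.p.m. so that the
#: non-negative GSH component cannot absorb them; negative teeth near the
#: edges of the analyte region drive the fit residual without overlapping the
#: GSH template.
_MM_COMB = ((2.710, 0.8, +1), (2.740, 0.9, -1), (2.770, 1.0, +1),
            (2.800, 0.8, -1),
            # zero-net-area dipoles at the analyte-region edges; the tooth
            # facing the GSH template is negative, so the non-negative GSH
            # component cannot slide onto them
            (2.862, 1.0, +1), (2.878, 1.0, -1),
            (3.022, 1.0, -1), (3.038, 1.0, +1),
            (3.095, 0.9, +1), (3.130, 0.8, -1),
            (3.165, 0.9, +1), (3.200, 0.7, -1))
MM_RIPPLE_SCALE = 0.05


def coedited_macromolecule_background(cr_amplitude: float = 1.0,
                                      scale: float = MM_RIPPLE_SCALE
                                      ) -> list[MetabolitePeak]:
    """Co-edited macromolecular background underlying the GSH region.

    A fixed comb of narrow resonances of alternating sign spanning 2.71-3.20
    p.p.m.  The comb is partially co-edited, so a signal-proportional ripple
    survives the ON/OFF subtraction; smooth non-negative Gaussian components
    cannot absorb it, which makes it the dominant contribution to the
    analyte-region fit residual (as unmodelled macromolecules and subtraction
    artifacts are in vivo).  Near-zero net area keeps peak-area
    quantification essentially unbiased.  Deterministic by construction.
    """
    return [MetabolitePeak(f"mm_{c:.2f}", c, scale * cr_amplitude * w, 4.0,
                           phase_rad=0.0 if s > 0 else np.pi,
                           edit_behavior="edited", edit_efficiency=0.5)
            for c, w, s in _MM_COMB]


def _split_on_off(peaks: list[MetabolitePeak]):
    on, off = [], []
    for p in peaks:
        if p.edit_behavior == "unedited":
            continue
        if p.edit_behavior == "suppressed":
            on.append(p)
            off.append(p)
        else:  # edited: full in ON, attenuated in OFF
            on.append(p)
            off_amp = p.amplitude * (1.0 - p.edit_efficiency)
            off.append(replace(p, amplitude=off_amp))
    return on, off


def megapress_peaks(gsh_cr_true: float, editing_efficiency: float = 0.74,
                    coedited: list[MetabolitePeak] | None = None,
                    cr_amplitude: float = 1.0,
                    gsh_damping_hz: float = 12.0) -> list[MetabolitePeak]:
    """Full peak list for one edited acquisition pair.

    The GSH amplitude is ``gsh_cr_true * cr_amplitude`` so that areas keep the
    requested concentration ratio.
    """
    if not 0.0 <= editing_efficiency <= 1.0:
        raise ParameterError("editing_efficiency must be in [0, 1]")
    if gsh_cr_true < 0:
        raise ParameterError("gsh_cr_true must be >= 0")
    peaks = list(default_background_peaks(cr_amplitude))
    peaks.append(MetabolitePeak("GSH", GSH_PPM, gsh_cr_true * cr_amplitude,
                                gsh_damping_hz, edit_behavior="edited",
                                edit_efficiency=editing_efficiency))
    peaks.extend(coedited or [])
    return peaks


def simulate_megapress_pair(gsh_cr_true: float, editing_efficiency: float = 0.74,
                            coedited: list[MetabolitePeak] | None = None,
                            acq: AcquisitionParams | None = None,
                            noise: NoiseModel | None = None,
                            rng: np.random.Generator | None = None,
                            cr_amplitude: float = 1.0) -> tuple[FID, FID]:
    """One editing-ON / editing-OFF transient pair."""
    acq = acq or AcquisitionParams()
    peaks = megapress_peaks(gsh_cr_true, editing_efficiency, coedited,
                            cr_amplitude)
    on_peaks, off_peaks = _split_on_off(peaks)
    if rng is None and noise is not None:
        rng = noise.rng()
    on = simulate_fid(on_peaks, acq, noise, rng, provenance="ON")
    off = simulate_fid(off_peaks, acq, noise, rng, provenance="OFF")
    return on, off


def simulate_megapress_blocks(n_blocks: int, gsh_cr_true: float,
                              editing_efficiency: float = 0.74,
                              coedited: list[MetabolitePeak] | None = None,
                              acq: AcquisitionParams | None = None,
                              noise: NoiseModel | None = None,
                              rng: np.random.Generator | None = None,
                              cr_amplitude: float = 1.0
                              ) -> tuple[list[FID], list[FID]]:
    """``n_blocks`` stored ON/OFF averages with independent noise draws."""
    if n_blocks <= 0:
        raise ParameterError("n_blocks must be positive")
    if rng is None and noise is not None:
        rng = noise.rng()
    ons, offs = [], []
    for _ in range(n_blocks):
        on, off = simulate_megapress_pair(gsh_cr_true, editing_efficiency,
                                          coedited, acq, noise, rng,
                                          cr_amplitude)
        ons.append(on)
        offs.append(off)
    return ons, offs


#: PRESS resonance library: name -> [(ppm, relative amplitude, damping Hz)]
PRESS_LIBRARY: dict[str, list[tuple[float, float, float]]] = {
    "Cr": [(3.03, 1.0, 12.0)],
    "NAA": [(2.01, 1.0, 12.0)],
    "Cho": [(3.19, 1.0, 13.0)],
    "Glx": [(2.30, 0.45, 16.0), (3.72, 0.45, 16.0)],
}


def simulate_press(concentrations: dict[str, float],
                   acq: AcquisitionParams | None = None,
                   noise: NoiseModel | None = None,
                   rng: np.random.Generator | None = None,
                   water_residual_amplitude: float = 0.5,
                   gain: float = 1.0) -> FID:
    """Short-echo PRESS acquisition: one amplitude unit per IU at unit gain."""
    acq = acq or AcquisitionParams(echo_time_ms=36.0, n_averages=64)
    peaks: list[MetabolitePeak] = []
    for name, conc in concentrations.items():
        if name not in PRESS_LIBRARY:
            raise ParameterError(f"unknown metabolite {name!r}; "
                                 f"known: {sorted(PRESS_LIBRARY)}")
        if conc < 0:
            raise ParameterError(f"concentration of {name} must be >= 0")
        for ppm, rel, damp in PRESS_LIBRARY[name]:
            if conc * rel > 0:
                peaks.append(MetabolitePeak(name, ppm, gain * conc * rel, damp,
                                            edit_behavior="unedited"))
    if water_residual_amplitude > 0:
        peaks.append(MetabolitePeak("water_residual", 4.70,
                                    gain * water_residual_amplitude, 30.0,
                                    edit_behavior="unedited"))
    fid = simulate_fid(peaks, acq, noise, rng, provenance="PRESS")
    return fid


def simulate_water_pair(water_t2_ms: float,
                        acq: AcquisitionParams | None = None,
                        te_pair_ms: tuple[float, float] = (68.0, 122.0),
                        noise: NoiseModel | None = None,
                        rng: np.random.Generator | None = None,
                        gain: float = 1.0) -> tuple[FID, FID]:
    """Unsuppressed water scans at two echo times.

    Peak areas obey ``S_a / S_b = exp((TE_b - TE_a) / T2)``; the amplitude at
    zero echo time is the tissue-water reference used for absolute scaling.
    """
    if water_t2_ms <= 0:
        raise ParameterError("water_t2_ms must be positive")
    te_a, te_b = te_pair_ms
    if te_a == te_b:
        raise ParameterError("echo times must differ (T2 unidentifiable)")
    base = acq or AcquisitionParams(n_averages=8)
    fids = []
    if rng is None and noise is not None:
        rng = noise.rng()
    for te in (te_a, te_b):
        amp = gain * WATER_AMPLITUDE_PER_UNIT_GAIN * np.exp(-te / water_t2_ms)
        peak = MetabolitePeak("water", 4.70, amp, 30.0, edit_behavior="unedited")
        acq_te = replace(base, echo_time_ms=te)
        fids.append(simulate_fid([peak], acq_te, noise, rng, provenance="WATER"))
    return fids[0], fids[1]
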
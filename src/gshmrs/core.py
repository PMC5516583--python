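"""Core containers for single-voxel MRS data.

An acquisition is described by :class:`AcquisitionParams`; the raw signal is a
complex free induction decay (:class:`FID`); its discrete Fourier transform on
a chemical-shift (p.p.m.) axis is a :class:`Spectrum`.  The p.p.m. axis follows
the NMR convention: water is assigned 4.70 p.p.m. at the carrier frequency and
the axis is printed high-to-low.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class ParameterError(ValueError):
    """Invalid acquisition or processing parameter."""


class StructuralError(ValueError):
    """Inputs that cannot be combined (axis mismatch, rank deficiency...)."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Pulse-sequence timing and digitization settings.

    Defaults are the GSH-edited MEGA-PRESS protocol: TR 2000 ms, TE 122 ms,
    2048 complex points over a 2000 Hz spectral width at 3 T (127.7 MHz),
    with the spectrum centre referenced to water at 4.70 p.p.m.
    """

    repetition_time_ms: float = 2000.0
    echo_time_ms: float = 122.0
    n_points: int = 2048
    spectral_width_hz: float = 2000.0
    n_averages: int = 8
    transmitter_frequency_mhz: float = 127.7
    reference_ppm: float = 4.70

    def __post_init__(self) -> None:
        if self.n_points <= 0:
            raise ParameterError("n_points must be positive")
        if self.spectral_width_hz <= 0:
            raise ParameterError("spectral_width_hz must be positive")
        if self.transmitter_frequency_mhz <= 0:
            raise ParameterError("transmitter_frequency_mhz must be positive")
        if self.repetition_time_ms <= 0 or self.echo_time_ms <= 0:
            raise ParameterError("timings must be positive")

    @property
    def dwell_time_s(self) -> float:
        return 1.0 / self.spectral_width_hz

    @property
    def hz_per_ppm(self) -> float:
        return self.transmitter_frequency_mhz  # 1 ppm of f0 in MHz is f0 Hz

    def time_axis(self, n: int | None = None) -> np.ndarray:
        n = self.n_points if n is None else n
        return np.arange(n) * self.dwell_time_s

    def ppm_axis(self, n: int | None = None) -> np.ndarray:
        """Strictly decreasing chemical-shift axis for an n-point spectrum."""
        n = self.n_points if n is None else n
        freq = np.fft.fftshift(np.fft.fftfreq(n, d=self.dwell_time_s))
        ppm = self.reference_ppm + freq / self.hz_per_ppm
        return ppm[::-1].copy()

    def offset_hz(self, ppm: float) -> float:
        """Frequency offset from the carrier of a resonance at ``ppm``."""
        return (ppm - self.reference_ppm) * self.hz_per_ppm

    @property
    def ppm_window(self) -> tuple[float, float]:
        """(low, high) chemical-shift bounds of the spectral window."""
        half = 0.5 * self.spectral_width_hz / self.hz_per_ppm
        return (self.reference_ppm - half, self.reference_ppm + half)


@dataclass
class FID:
    """Complex time-domain transient with its acquisition metadata.

    ``acq.n_points`` records the acquired length; ``samples`` may be longer
    after zero-filling.  ``provenance`` labels the pathway (ON, OFF, PRESS,
    WATER) and ``history`` accumulates processing steps.
    """

    samples: np.ndarray
    acq: AcquisitionParams
    provenance: str = ""
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1:
            raise StructuralError("FID samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples.view(float))):
            raise StructuralError("FID contains non-finite samples")

    def copy_with(self, samples: np.ndarray, step: str) -> "FID":
        return FID(samples=samples, acq=self.acq, provenance=self.provenance,
                   history=[*self.history, step])


@dataclass
class Spectrum:
    """Complex frequency-domain data on a strictly decreasing p.p.m. axis."""

    values: np.ndarray
    ppm: np.ndarray
    acq: AcquisitionParams
    provenance: str = ""
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.values.shape != self.ppm.shape:
            raise StructuralError("values and ppm axis differ in length")
        if self.ppm.size > 1 and not np.all(np.diff(self.ppm) < 0):
            raise StructuralError("ppm axis must be strictly decreasing")

    def window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of bins with ``lo <= ppm <= hi``."""
        return (self.ppm >= lo) & (self.ppm <= hi)

    def copy_with(self, values: np.ndarray, step: str) -> "Spectrum":
        return Spectrum(values=values, ppm=self.ppm, acq=self.acq,
                        provenance=self.provenance,
                        history=[*self.history, step])


def to_spectrum(fid: FID) -> Spectrum:
    """Discrete Fourier transform of a FID onto the p.p.m. axis.

    Exactly invertible by :func:`to_fid`; satisfies the Parseval identity
    ``sum |S|^2 = N sum |s|^2``.
    """
    n = fid.samples.size
    vals = np.fft.fftshift(np.fft.fft(fid.samples))[::-1].copy()
    ppm = fid.acq.ppm_axis(n)
    return Spectrum(values=vals, ppm=ppm, acq=fid.acq,
                    provenance=fid.provenance,
                    history=[*fid.history, "to_spectrum"])


def to_fid(spec: Spectrum) -> FID:
    """Inverse transform of :func:`to_spectrum`."""
    vals = np.fft.ifft(np.fft.ifftshift(spec.values[::-1]))
    return FID(samples=vals, acq=spec.acq, provenance=spec.provenance,
               history=[*spec.history, "to_fid"])


def mean_spectrum(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise complex mean of spectra sharing one axis."""
    if not spectra:
        raise StructuralError("cannot average an empty list of spectra")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.values.size != ref.values.size or not np.allclose(s.ppm, ref.ppm):
            raise StructuralError("spectra do not share a common axis")
    vals = np.mean([s.values for s in spectra], axis=0)
    return Spectrum(values=vals, ppm=ref.ppm, acq=ref.acq,
                    provenance=ref.provenance,
                    history=[*ref.history, f"mean_of_{len(spectra)}"])
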
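"""Spectral exchange container and delimited tables.

The container is a self-describing JSON file: a version-tagged header with
acquisition metadata, provenance and processing history, plus a body of
interleaved real/imaginary samples per transient.  Two body encodings are
supported: ``ascii`` (decimal floats that round-trip binary64 exactly) and
``base64-le`` / ``base64-be`` (raw IEEE-754 doubles, either byte order).
Read(write(x)) is bit-exact for every encoding.
"""

from __future__ import annotations

import base64
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FID, AcquisitionParams

FORMAT_NAME = "gshmrs-spectra"
FORMAT_VERSION = 1
ENCODINGS = ("ascii", "base64-le", "base64-be")


class SpectraParseError(ValueError):
    """Malformed spectral exchange file; names the offending field."""


def _acq_to_dict(acq: AcquisitionParams) -> dict:
    return dict(repetition_time_ms=acq.repetition_time_ms,
                echo_time_ms=acq.echo_time_ms, n_points=acq.n_points,
                spectral_width_hz=acq.spectral_width_hz,
                n_averages=acq.n_averages,
                transmitter_frequency_mhz=acq.transmitter_frequency_mhz,
                reference_ppm=acq.reference_ppm)


def write_spectra(fids: list[FID], path: str | Path,
                  encoding: str = "ascii") -> None:
    """Write transients sharing one acquisition to a container file."""
    if encoding not in ENCODINGS:
        raise SpectraParseError(f"unknown encoding {encoding!r}")
    if not fids:
        raise SpectraParseError("no transients to write")
    acq = fids[0].acq
    doc = dict(format=FORMAT_NAME, version=FORMAT_VERSION, encoding=encoding,
               acquisition=_acq_to_dict(acq),
               transients=[])
    for f in fids:
        inter = np.empty(2 * f.samples.size)
        inter[0::2] = f.samples.real
        inter[1::2] = f.samples.imag
        if encoding == "ascii":
            body = [float(v) for v in inter]
        else:
            order = "<" if encoding == "base64-le" else ">"
            body = base64.b64encode(
                inter.astype(f"{order}f8").tobytes()).decode("ascii")
        doc["transients"].append(dict(provenance=f.provenance,
                                      history=list(f.history),
                                      n_samples=int(f.samples.size),
                                      samples=body))
    Path(path).write_text(json.dumps(doc))


def read_spectra(path: str | Path) -> list[FID]:
    """Read a container file back to FIDs (bit-exact round trip)."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise SpectraParseError(f"not valid JSON: {e}") from e
    for key in ("format", "version", "encoding", "acquisition", "transients"):
        if key not in doc:
            raise SpectraParseError(f"missing header field {key!r}")
    if doc["format"] != FORMAT_NAME:
        raise SpectraParseError(f"unknown format {doc['format']!r}")
    if doc["version"] != FORMAT_VERSION:
        raise SpectraParseError(f"unsupported version {doc['version']!r}")
    enc = doc["encoding"]
    if enc not in ENCODINGS:
        raise SpectraParseError(f"unknown encoding {enc!r}")
    try:
        acq = AcquisitionParams(**doc["acquisition"])
    except TypeError as e:
        raise SpectraParseError(f"bad acquisition header: {e}") from e
    fids = []
    for i, tr in enumerate(doc["transients"]):
        for key in ("n_samples", "samples"):
            if key not in tr:
                raise SpectraParseError(
                    f"transient {i}: missing field {key!r}")
        n = tr["n_samples"]
        if enc == "ascii":
            inter = np.asarray(tr["samples"], dtype=float)
        else:
            order = "<" if enc == "base64-le" else ">"
            raw = base64.b64decode(tr["samples"])
            inter = np.frombuffer(raw, dtype=f"{order}f8").astype(float)
        if inter.size != 2 * n:
            raise SpectraParseError(
                f"transient {i}: body has {inter.size} values, "
                f"expected {2 * n} (field 'samples' truncated?)")
        samples = inter[0::2] + 1j * inter[1::2]
        fids.append(FID(samples=samples, acq=acq,
                        provenance=tr.get("provenance", ""),
                        history=list(tr.get("history", []))))
    return fids


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Delimited text with header; floats at 6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
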
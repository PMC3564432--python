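"""Serialization: model documents, signal text files, TFR text triples.

Formats (all plain text):

* **Signal** — one float per line; the sampling rate travels out-of-band
  (CLI flag / function argument).
* **TFR** — three delimited files sharing a path prefix: ``<prefix>.t.txt``
  (time axis, s), ``<prefix>.f.txt`` (frequency axis, Hz) and
  ``<prefix>.P.txt`` (power matrix, one row per frequency bin).
* **Model** — a versioned JSON document::

      {"format_version": 1, "n": 2, "K": 3, "C": ..., "sigma_diag": [...],
       "peak_points": [[t, f, A], ...], "axis_units": {...}}

  Floats survive the round trip bit-exactly (JSON uses ``repr`` precision).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np

from .exceptions import ModelFormatError
from .model import SnaGeParams
from .tfr import Signal, TFRGrid

__all__ = [
    "save_model",
    "load_model",
    "save_signal",
    "load_signal",
    "save_tfr",
    "load_tfr",
]

FORMAT_VERSION = 1
DEFAULT_UNITS = {"t": "s", "f": "Hz", "A": "power"}


def _atomic_write(path, text: str):
    """Write via a temp file + rename so readers never see partial output."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def save_model(m: SnaGeParams, path, axis_units: dict | None = None):
    doc = {
        "format_version": FORMAT_VERSION,
        "n": int(m.n),
        "K": int(m.K),
        "C": float(m.C),
        "sigma_diag": [float(s) for s in m.sigma_diag],
        "peak_points": [[float(v) for v in row] for row in m.peak_points],
        "axis_units": dict(axis_units or DEFAULT_UNITS),
    }
    _atomic_write(path, json.dumps(doc, indent=1) + "\n")


def load_model(path) -> SnaGeParams:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"malformed model document {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ModelFormatError("model document must be a JSON object")
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported format_version {version!r} (expected {FORMAT_VERSION})"
        )
    for key in ("n", "K", "C", "sigma_diag", "peak_points"):
        if key not in doc:
            raise ModelFormatError(f"model document missing field {key!r}")
    pts = np.asarray(doc["peak_points"], dtype=float)
    if pts.ndim != 2 or pts.shape != (doc["K"], doc["n"] + 1):
        raise ModelFormatError(
            f"field 'peak_points' must be a {doc['K']}x{doc['n'] + 1} array"
        )
    sigma = np.asarray(doc["sigma_diag"], dtype=float)
    if sigma.shape != (doc["n"],):
        raise ModelFormatError(f"field 'sigma_diag' must have length {doc['n']}")
    return SnaGeParams(C=float(doc["C"]), sigma_diag=sigma, peak_points=pts)


def save_signal(sig: Signal, path):
    _atomic_write(path, "\n".join(repr(float(v)) for v in sig.samples) + "\n")


def load_signal(path, fs: float) -> Signal:
    return Signal(samples=np.loadtxt(path, ndmin=1), fs=fs)


def _tfr_paths(prefix):
    prefix = str(prefix)
    return (prefix + ".t.txt", prefix + ".f.txt", prefix + ".P.txt")


def save_tfr(tfr: TFRGrid, prefix):
    pt, pf, pp = _tfr_paths(prefix)
    _atomic_write(pt, "\n".join(repr(float(v)) for v in tfr.t) + "\n")
    _atomic_write(pf, "\n".join(repr(float(v)) for v in tfr.f) + "\n")
    _atomic_write(
        pp,
        "\n".join(" ".join(repr(float(v)) for v in row) for row in tfr.P) + "\n",
    )


def load_tfr(prefix) -> TFRGrid:
    pt, pf, pp = _tfr_paths(prefix)
    return TFRGrid(
        t=np.loadtxt(pt, ndmin=1),
        f=np.loadtxt(pf, ndmin=1),
        P=np.loadtxt(pp, ndmin=2),
    )
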
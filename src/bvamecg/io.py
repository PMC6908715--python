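"""Serialization: CSV interchange, WFDB-style records, run manifests.

CSV is the primary interchange format (all signals are single-lead time
series); numbers are written with 17 significant digits so that re-reading
reproduces values bit-exactly.  A minimal plain-text WFDB-style record
(a ``.hea`` header plus an ASCII sample file) is offered for ECG-tool
interoperability.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np

from .ecg import ECGSignal
from .errors import ParseError
from .model import Trajectory

__all__ = [
    "write_trajectory_csv", "write_ecg_csv", "read_ecg_csv",
    "write_spectrum_csv", "write_scan_csv", "write_wfdb", "write_manifest",
]

_FMT = "%.17g"


def write_trajectory_csv(traj: Trajectory, path) -> Path:
    path = Path(path)
    n = traj.n_components
    header = "t," + ",".join(f"x{i+1}" for i in range(n))
    data = np.column_stack([traj.times, traj.states])
    np.savetxt(path, data, fmt=_FMT, delimiter=",", header=header,
               comments="")
    return path


def write_ecg_csv(signal: ECGSignal, path) -> Path:
    path = Path(path)
    data = np.column_stack([signal.times, signal.values])
    np.savetxt(path, data, fmt=_FMT, delimiter=",",
               header="time_s,amplitude", comments="")
    return path


def read_ecg_csv(path) -> ECGSignal:
    """Read a two-column (time_s, amplitude) CSV written by write_ecg_csv."""
    path = Path(path)
    times, values = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().startswith("time"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(
                    f"expected 2 comma-separated fields, got {len(parts)}",
                    line=lineno)
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError:
                raise ParseError(f"non-numeric field in {line!r}",
                                 line=lineno) from None
    if len(times) < 2:
        raise ParseError("fewer than 2 samples in file")
    return ECGSignal(times=np.asarray(times), values=np.asarray(values))


def write_spectrum_csv(spectrum, path) -> Path:
    path = Path(path)
    data = np.column_stack([spectrum.frequencies, spectrum.power])
    np.savetxt(path, data, fmt=_FMT, delimiter=",",
               header="frequency,power", comments="")
    return path


def write_scan_csv(scan, path) -> Path:
    path = Path(path)
    data = np.column_stack([scan.H_values, scan.lambda_max])
    np.savetxt(path, data, fmt=_FMT, delimiter=",",
               header="H,lambda_max", comments="")
    return path


def write_wfdb(signal: ECGSignal, path_base, record_name: str | None = None,
               gain: float = 1000.0) -> tuple[Path, Path]:
    """Write a minimal plain-text WFDB-style record (header + samples).

    The ``.hea`` header follows the WFDB header-line layout (record name,
    signal count, sampling frequency, sample count); samples are stored in
    a text file as scaled integers (amplitude * gain, one per line), a
    plain-text stand-in for the binary WFDB signal formats.
    """
    path_base = Path(path_base)
    record_name = record_name or path_base.stem
    fs = signal.sample_rate
    n = len(signal.values)
    hea = path_base.with_suffix(".hea")
    dat = path_base.with_suffix(".txt")
    with open(hea, "w") as fh:
        fh.write(f"{record_name} 1 {fs:.6f} {n}\n")
        fh.write(f"{dat.name} ascii {gain:g}(0)/mV 16 0 0 0 0 II\n")
        fh.write("# single synthetic lead II, amplitude*gain as integers\n")
    samples = np.round(signal.values * gain).astype(int)
    np.savetxt(dat, samples, fmt="%d")
    return hea, dat


def write_manifest(path, command: str, config: dict, seed=None) -> Path:
    """Record everything needed to reproduce a run byte-for-byte."""
    from . import __version__
    path = Path(path)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "versions": {
            "bvamecg": __version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
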
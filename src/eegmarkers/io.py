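"""Reading and writing recordings, masks and ground-truth tables.

Two on-disk recording formats are supported:

* **EDF** (European Data Format).  Reading goes through
  :func:`mne.io.read_raw_edf`; writing uses a small self-contained 16-bit
  EDF writer (one data record per second), since no EDF export library is
  bundled.  Round-trip error is bounded by EDF's 16-bit quantization of the
  per-channel physical range.
* **matrix**: a delimited numeric text file (channels as columns, header row
  of labels) plus a sidecar ``<stem>.meta`` key-value file carrying ``fs``
  and ``id``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .errors import FormatError
from .recording import ChannelMask, EEGRecording

__all__ = [
    "write_psd",
    "read_psd",
    "read_recording",
    "write_recording",
    "write_edf",
    "read_edf",
    "write_matrix",
    "read_matrix",
    "write_channel_mask",
    "write_ground_truth",
    "write_cohort",
]

_MATRIX_SUFFIXES = {".tsv", ".txt", ".csv", ".mat.txt"}


def _sidecar_path(matrix_path: Path) -> Path:
    return matrix_path.with_suffix(".meta")


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        b = b[:width]
    return b.ljust(width)


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write ``rec`` as a 16-bit EDF file with 1-second data records.

    The recording duration must be a whole number of seconds and ``fs`` an
    integer, so that each data record holds exactly ``fs`` samples.
    """
    path = Path(path)
    fs = rec.fs
    if fs != int(fs):
        raise FormatError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(fs)
    n_records, rem = divmod(rec.n_samples, fs)
    if rem:
        raise FormatError(
            "EDF writer requires a whole number of seconds "
            f"({rec.n_samples} samples at {fs} Hz)"
        )
    n_sig = rec.n_channels

    # physical range per channel, symmetric and never degenerate
    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-6)
    dig_max = 32767.0
    scaled = np.round(rec.data / phys_max[:, None] * dig_max).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),  # local patient identification (anonymous)
            _pad(f"Startdate 01-JAN-2000 {rec.id or 'X'}", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (n_sig + 1)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),  # record duration, seconds
            _pad(str(n_sig), 4),
        ]
    )
    fields: list[bytes] = []
    for spec_width, values in [
        (16, rec.channel_labels),
        (80, [""] * n_sig),  # transducer type
        (8, ["uV"] * n_sig),
        (8, [f"{-m:.6g}"[:8] for m in phys_max]),
        (8, [f"{m:.6g}"[:8] for m in phys_max]),
        (8, ["-32767"] * n_sig),
        (8, ["32767"] * n_sig),
        (80, [""] * n_sig),  # prefiltering
        (8, [str(fs)] * n_sig),
        (32, [""] * n_sig),
    ]:
        fields.extend(_pad(str(v), spec_width) for v in values)
    signal_header = b"".join(fields)

    # data records: record-major, signal-blocked int16 little-endian
    records = scaled.reshape(n_sig, n_records, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        fh.write(np.ascontiguousarray(records).tobytes())
    return path


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (microvolts)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types for malformed files
        raise FormatError(f"cannot parse {path} as EDF: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # MNE returns Volts
    labels = list(raw.ch_names)
    if len(set(labels)) != len(labels):
        raise FormatError(f"duplicate channel labels in {path}")
    rec_id = path.stem
    return EEGRecording(data=data_uv, fs=float(raw.info["sfreq"]),
                        channel_labels=labels, id=rec_id)


def write_matrix(rec: EEGRecording, path: str | Path) -> Path:
    """Write the matrix+sidecar text format (channels as columns)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.6f", delimiter="\t")
    with open(_sidecar_path(path), "w") as fh:
        fh.write(f"fs = {rec.fs:g}\n")
        fh.write(f"id = {rec.id}\n")
    return path


def read_matrix(path: str | Path) -> EEGRecording:
    """Read the matrix+sidecar text format."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata file {sidecar}")
    meta: dict[str, str] = {}
    for line in sidecar.read_text().splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            meta[key.strip()] = value.strip()
    if "fs" not in meta:
        raise FormatError(f"sidecar {sidecar} lacks an 'fs' entry")
    with open(path) as fh:
        labels = fh.readline().rstrip("\n").split("\t")
        try:
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise FormatError(f"cannot parse numeric matrix in {path}: {exc}") from exc
    if len(set(labels)) != len(labels):
        raise FormatError(f"duplicate channel labels in {path}")
    return EEGRecording(data=data.T, fs=float(meta["fs"]),
                        channel_labels=labels, id=meta.get("id", path.stem))


def write_recording(rec: EEGRecording, path: str | Path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "matrix")
    if fmt == "edf":
        return write_edf(rec, path)
    if fmt == "matrix":
        return write_matrix(rec, path)
    raise FormatError(f"unknown recording format {fmt!r}")


def read_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read a recording, dispatching on ``format`` or the file extension."""
    path = Path(path)
    fmt = format
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix == ".edf":
            fmt = "edf"
        elif suffix in _MATRIX_SUFFIXES:
            fmt = "matrix"
        else:
            raise FormatError(f"cannot infer recording format from extension {suffix!r}")
    if fmt == "edf":
        return read_edf(path)
    if fmt == "matrix":
        return read_matrix(path)
    raise FormatError(f"unknown recording format {fmt!r}")


def write_psd(psd, path: str | Path) -> Path:
    """Export a PSD estimate as CSV (frequency, power, log_power)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frequency_hz", "power", "log_power"])
        for f, p, lp in zip(psd.freqs, psd.power, psd.log_power):
            writer.writerow([f"{f:.17g}", f"{p:.17g}", f"{lp:.17g}"])
    return path


def read_psd(path: str | Path):
    """Read a PSD CSV written by :func:`write_psd`."""
    import numpy as np

    from .spectral import PSDEstimate

    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    if data.ndim != 2 or data.shape[1] != 3:
        raise FormatError(f"{path} is not a 3-column PSD CSV")
    return PSDEstimate(freqs=data[:, 0], power=data[:, 1], log_power=data[:, 2])


def write_channel_mask(mask: ChannelMask, labels: list[str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["channel", "bad", "reasons"])
        for lab, bad, reasons in zip(labels, mask.bad, mask.reasons):
            writer.writerow([lab, int(bad), ";".join(sorted(reasons))])
    return path


def write_ground_truth(truths, path: str | Path) -> Path:
    """Export generator ground truth as a CSV keyed by recording id."""
    import pandas as pd

    rows = []
    for gt in truths:
        ph = gt.phenotype
        rows.append(
            {
                "recording_id": gt.recording_id,
                "group": gt.group,
                "phenotype": ph.label,
                "crs_r": "" if gt.crs_r_score is None else gt.crs_r_score,
                "aperiodic_exponent": ph.aperiodic_exponent,
                "oscillation_center_hz": ph.oscillation_center_hz,
                "oscillation_bandwidth_hz": ph.oscillation_bandwidth_hz,
                "oscillation_amplitude": ph.oscillation_amplitude,
                "ar_timescale_s": ph.ar_timescale_s,
                "delta_amplitude": ph.delta_amplitude,
                "path_a": gt.mediation_paths[0],
                "path_b": gt.mediation_paths[1],
                "latent_power": gt.latent_power,
                "latent_acw": gt.latent_acw,
                "latent_score": gt.latent_score,
                "seed": gt.seed,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def write_cohort(recordings, truths, out_dir: str | Path, format: str = "edf") -> Path:
    """Write a simulated cohort (recordings + ground-truth CSV) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".edf" if format == "edf" else ".tsv"
    for rec in recordings:
        write_recording(rec, out_dir / f"{rec.id}{suffix}", format=format)
    write_ground_truth(truths, out_dir / "ground_truth.csv")
    return out_dir
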
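"""File I/O: recordings (TSV and HDF5), ground truth, events and results
tables.

Recordings round-trip losslessly at double precision.  The TSV layout is a
``time_s`` column followed by one column per channel; the HDF5 container
stores ``/recording/data`` (channels x samples), ``/recording/fs`` and
``/recording/labels``.
"""
from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import SamplingError, SchemaError, ValidationError
from .geometry import ProbeGeometry
from .preprocess import MatchedTransit, SpikeEvent
from .recording import MultichannelRecording

__all__ = [
    "read_recording",
    "write_recording",
    "write_events_tsv",
    "read_events_tsv",
    "write_results_tsv",
    "read_results_tsv",
    "write_ground_truth_tsv",
    "read_ground_truth_tsv",
]

_TSV_SUFFIXES = {".tsv", ".txt"}
_H5_SUFFIXES = {".h5", ".hdf5"}

#: maximum relative jitter of the time column before the file is rejected
TIME_JITTER_REL_TOL = 1.0e-6


def write_recording(rec: MultichannelRecording, path: str | Path) -> None:
    """Write a recording as TSV (.tsv/.txt) or the HDF5 container (.h5/.hdf5)."""
    path = Path(path)
    if path.suffix in _H5_SUFFIXES:
        with h5py.File(path, "w") as f:
            g = f.create_group("recording")
            g.create_dataset("data", data=rec.samples)
            g.create_dataset("fs", data=float(rec.sampling_rate_hz))
            g.create_dataset("labels", data=[lab.encode() for lab in rec.labels])
    elif path.suffix in _TSV_SUFFIXES:
        df = pd.DataFrame({"time_s": rec.times})
        for lab in rec.labels:
            df[lab] = rec.channel(lab)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    else:
        raise ValidationError(f"unsupported recording format: {path.suffix!r}")


def _fs_from_time_column(time_s: np.ndarray) -> float:
    if time_s.size < 2:
        raise SamplingError("need at least 2 samples to recover a sampling rate")
    dt = np.diff(time_s)
    period = float(np.median(dt))
    if period <= 0.0:
        raise SamplingError("time column is not strictly increasing")
    if np.max(np.abs(dt - period)) > TIME_JITTER_REL_TOL * period:
        raise SamplingError("time column is irregular beyond tolerance")
    return 1.0 / period


def read_recording(
    path: str | Path, probe: ProbeGeometry | None = None
) -> MultichannelRecording:
    """Read a TSV or HDF5 recording.

    If ``probe`` is given, the channels are validated against and reordered
    to the probe labels; a missing channel raises :class:`SchemaError`.
    """
    path = Path(path)
    if path.suffix in _H5_SUFFIXES:
        with h5py.File(path, "r") as f:
            try:
                g = f["recording"]
                data = np.asarray(g["data"], dtype=float)
                fs = float(np.asarray(g["fs"]))
                labels = tuple(
                    lab.decode() if isinstance(lab, bytes) else str(lab)
                    for lab in g["labels"][()]
                )
            except KeyError as exc:
                raise SchemaError(f"missing HDF5 dataset: {exc}") from exc
        rec = MultichannelRecording(data, fs, labels)
    elif path.suffix in _TSV_SUFFIXES:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        if "time_s" not in df.columns:
            raise SchemaError("TSV recording must have a 'time_s' column")
        fs = _fs_from_time_column(df["time_s"].to_numpy(dtype=float))
        labels = tuple(c for c in df.columns if c != "time_s")
        if not labels:
            raise SchemaError("TSV recording has no channel columns")
        rec = MultichannelRecording(
            df[list(labels)].to_numpy(dtype=float).T, fs, labels
        )
    else:
        raise ValidationError(f"unsupported recording format: {path.suffix!r}")
    if probe is not None:
        missing = [lab for lab in probe.labels if lab not in rec.labels]
        if missing:
            raise SchemaError(f"recording lacks probe channels: {missing}")
        order = [rec.labels.index(lab) for lab in probe.labels]
        rec = MultichannelRecording(rec.samples[order], rec.sampling_rate_hz, probe.labels)
    return rec


# ---------------------------------------------------------------------------
# Tables


def write_events_tsv(
    path: str | Path,
    matched: list[MatchedTransit],
    unmatched: list[SpikeEvent] | None = None,
) -> None:
    """Serialise detected events; unmatched events carry transit_id = -1."""
    rows = []
    for tr in matched:
        for e in tr.events:
            rows.append(
                dict(
                    transit_id=tr.transit_id,
                    channel=e.channel,
                    t_peak_s=e.peak_time_s,
                    amplitude=e.peak_amplitude,
                    duration_s=e.duration_s,
                )
            )
    for e in unmatched or []:
        rows.append(
            dict(
                transit_id=-1,
                channel=e.channel,
                t_peak_s=e.peak_time_s,
                amplitude=e.peak_amplitude,
                duration_s=e.duration_s,
            )
        )
    cols = ["transit_id", "channel", "t_peak_s", "amplitude", "duration_s"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_results_tsv(path: str | Path, results: pd.DataFrame) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "flags" in df.columns:
        df["flags"] = df["flags"].fillna("")
    return df


def write_ground_truth_tsv(path: str | Path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ground_truth_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
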
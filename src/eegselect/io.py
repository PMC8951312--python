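"""Reading and writing cohorts.

A cohort on disk is one delimited-text matrix (channels x samples) per
recording plus a tab-separated manifest listing subject id, record id,
file name, sampling rate and channel names.  EDF files can optionally be
imported through :mod:`mne` when it is installed.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .synthetic import EEGRecording

__all__ = ["save_cohort", "load_cohort", "read_edf"]

_MANIFEST = "manifest.tsv"


def save_cohort(recordings: list[EEGRecording], directory: str | Path) -> Path:
    """Write one ``.tsv`` matrix per recording and a manifest; returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / _MANIFEST
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["subject_id", "record_id", "file", "sampling_rate_hz", "channels"])
        for rec in recordings:
            fname = f"{rec.subject_id}_r{rec.record_id}.tsv"
            np.savetxt(directory / fname, rec.data, delimiter="\t")
            w.writerow(
                [
                    rec.subject_id,
                    rec.record_id,
                    fname,
                    rec.sampling_rate_hz,
                    ",".join(rec.channel_names),
                ]
            )
    return manifest


def load_cohort(directory: str | Path) -> list[EEGRecording]:
    """Read a cohort written by :func:`save_cohort`."""
    directory = Path(directory)
    recs: list[EEGRecording] = []
    with open(directory / _MANIFEST, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            data = np.loadtxt(directory / row["file"], delimiter="\t", ndmin=2)
            recs.append(
                EEGRecording(
                    subject_id=row["subject_id"],
                    data=data,
                    sampling_rate_hz=float(row["sampling_rate_hz"]),
                    channel_names=row["channels"].split(","),
                    record_id=int(row["record_id"]),
                )
            )
    return recs


def read_edf(path: str | Path, subject_id: str, record_id: int = 0) -> EEGRecording:
    """Import one EDF file as an :class:`EEGRecording` (requires ``mne``)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF import requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(
        subject_id=subject_id,
        data=raw.get_data(),
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        record_id=record_id,
    )
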
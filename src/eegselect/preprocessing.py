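"""Segmentation and denoising of EEG recordings.

A record is cut into fixed-length non-overlapping windows (by default six
10-second sub-signals), then each window is cleaned with a notch filter at
the mains frequency and a band-pass filter, both applied forward-backward
for zero phase distortion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt, iirnotch

from .synthetic import EEGRecording

__all__ = ["PreprocessConfig", "segment", "notch", "bandpass", "preprocess"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Segmentation and filter parameters.

    The filters default to a 60 Hz mains notch (Q = 30) and a 0.5-50 Hz
    4th-order Butterworth band-pass; both are implementation choices the
    user can override — see docs/methods.md.
    """

    segment_length_s: float = 10.0
    n_segments: int = 6
    notch_freq_hz: float = 60.0
    notch_q: float = 30.0
    bandpass_low_hz: float = 0.5
    bandpass_high_hz: float = 50.0
    filter_order: int = 4

    def validate(self, sampling_rate_hz: float) -> None:
        nyq = sampling_rate_hz / 2.0
        if not (0 < self.bandpass_low_hz < self.bandpass_high_hz < nyq):
            raise ValueError(
                f"band-pass edges ({self.bandpass_low_hz}, {self.bandpass_high_hz}) "
                f"must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
            )
        if not (0 < self.notch_freq_hz < nyq):
            raise ValueError(
                f"notch frequency {self.notch_freq_hz} Hz outside (0, {nyq}) Hz"
            )
        if self.segment_length_s <= 0:
            raise ValueError("segment_length_s must be positive")


def segment(rec: EEGRecording, cfg: PreprocessConfig) -> list[EEGRecording]:
    """Cut a recording into consecutive non-overlapping windows.

    Returns at most ``cfg.n_segments`` windows of
    ``segment_length_s * fs`` samples each; a trailing partial window is
    discarded (padding would bias AR estimation at the boundary).
    """
    win = int(round(cfg.segment_length_s * rec.sampling_rate_hz))
    n_fit = rec.n_samples // win
    if n_fit < 1:
        raise ValueError(
            f"record {rec.subject_id}/{rec.record_id} has {rec.n_samples} samples, "
            f"shorter than one {win}-sample segment"
        )
    n_out = min(n_fit, cfg.n_segments)
    return [
        replace(rec, data=rec.data[:, i * win : (i + 1) * win].copy())
        for i in range(n_out)
    ]


def notch(seg: EEGRecording, cfg: PreprocessConfig) -> EEGRecording:
    """Suppress the mains frequency with an IIR notch, zero-phase."""
    cfg.validate(seg.sampling_rate_hz)
    b, a = iirnotch(cfg.notch_freq_hz, cfg.notch_q, fs=seg.sampling_rate_hz)
    return replace(seg, data=filtfilt(b, a, seg.data, axis=1))


def bandpass(seg: EEGRecording, cfg: PreprocessConfig) -> EEGRecording:
    """Butterworth band-pass, applied forward-backward (zero phase)."""
    cfg.validate(seg.sampling_rate_hz)
    b, a = butter(
        cfg.filter_order,
        [cfg.bandpass_low_hz, cfg.bandpass_high_hz],
        btype="bandpass",
        fs=seg.sampling_rate_hz,
    )
    return replace(seg, data=filtfilt(b, a, seg.data, axis=1))


def preprocess(rec: EEGRecording, cfg: PreprocessConfig) -> list[EEGRecording]:
    """Full pipeline: segment, then notch and band-pass each window."""
    return [bandpass(notch(s, cfg), cfg) for s in segment(rec, cfg)]
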
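"""Synthetic multi-subject EEG cohorts with planted discriminative channels.

The generator emulates the structure of a multi-subject motor/imagery EEG
corpus at desk scale: a cohort of subjects, each contributing several
multi-channel records at a fixed sampling rate.  A chosen subset of
*informative* channels carries a subject-specific stationary autoregressive
(AR) signature — the AR coefficients are drawn once per (subject, channel)
and reused for every record of that subject — while all remaining channels
carry one cohort-shared AR process plus white noise, so they contain no
information about subject identity.  Because the informative set is known,
channel-recovery by the selection algorithms is directly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = ["CohortSpec", "EEGRecording", "generate_cohort", "planted_truth"]

#: samples discarded at the start of every simulated AR series so the
#: process reaches its stationary distribution before recording begins
_BURN_IN = 500

#: attempts to redraw an AR coefficient set whose companion polynomial is
#: numerically unstable before giving up
_MAX_REDRAWS = 16


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults describe the desk-scale study cohort: 8 subjects, 16 channels
    of which 3 are informative, 6 records per subject, 10 s records sampled
    at 160 Hz (the sampling-rate convention of the reference corpus).
    """

    n_subjects: int = 8
    n_channels: int = 16
    informative_channels: frozenset[int] = field(
        default_factory=lambda: frozenset({2, 7, 11})
    )
    ar_order_gen: int = 5
    records_per_subject: int = 6
    record_duration_s: float = 10.0
    sampling_rate_hz: float = 160.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        info = frozenset(int(c) for c in self.informative_channels)
        if not info <= set(range(self.n_channels)):
            raise ValueError(
                f"informative_channels {sorted(info)} outside 0..{self.n_channels - 1}"
            )
        object.__setattr__(self, "informative_channels", info)

    @property
    def n_samples(self) -> int:
        return int(round(self.record_duration_s * self.sampling_rate_hz))


@dataclass
class EEGRecording:
    """One subject's multi-channel signal (channels x samples)."""

    subject_id: str
    data: np.ndarray
    sampling_rate_hz: float
    channel_names: list[str]
    record_id: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names must match the number of rows")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _rc_to_ar(reflection: np.ndarray) -> np.ndarray:
    """Map reflection coefficients to AR polynomial via Levinson recursion.

    Returns the monic polynomial ``[1, a1, ..., ap]`` of the AR process
    ``x_t = -a1 x_{t-1} - ... - ap x_{t-p} + e_t``.  Reflection coefficients
    with magnitude < 1 guarantee a stationary (minimum-phase) polynomial.
    """
    a = np.array([1.0])
    for k in reflection:
        a = np.concatenate([a, [0.0]]) + k * np.concatenate([[0.0], a[::-1]])
    return a


def _draw_stationary_ar(order: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a stationary AR polynomial by sampling reflection coefficients.

    Coefficients are sampled uniformly in (-0.95, 0.95); stationarity is
    then guaranteed by construction, but the polynomial roots are still
    checked to guard against numerical edge cases.
    """
    for _ in range(_MAX_REDRAWS):
        refl = rng.uniform(-0.95, 0.95, size=order)
        poly = _rc_to_ar(refl)
        roots = np.roots(poly[::-1])  # roots of a(z) in z; need |z| > 1
        if np.all(np.abs(roots) > 1.0 + 1e-9):
            return poly
    raise RuntimeError("could not draw a stationary AR polynomial")


def _ar_series(poly: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    e = rng.standard_normal(n + _BURN_IN)
    x = lfilter([1.0], poly, e)
    return x[_BURN_IN:]


def _substream(spec: CohortSpec, *key: int) -> np.random.Generator:
    """Independent RNG substream for one (subject, channel, record) slot.

    Fanning a single cohort seed out through ``spawn_key`` keeps every
    slot's stream fixed when the cohort grows along another axis.
    """
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=key))


def generate_cohort(spec: CohortSpec) -> list[EEGRecording]:
    """Generate ``n_subjects * records_per_subject`` recordings.

    Informative channels follow a subject-specific AR(``ar_order_gen``)
    process fixed per (subject, channel); the rest follow one cohort-shared
    AR process.  White observation noise of standard deviation ``noise_sd``
    is added to every channel.  Deterministic given ``spec.seed``.
    """
    n = spec.n_samples
    channel_names = [f"Ch{c}" for c in range(spec.n_channels)]

    shared_poly = _draw_stationary_ar(spec.ar_order_gen, _substream(spec, 0))
    subject_polys: dict[tuple[int, int], np.ndarray] = {}
    for s in range(spec.n_subjects):
        for c in sorted(spec.informative_channels):
            subject_polys[(s, c)] = _draw_stationary_ar(
                spec.ar_order_gen, _substream(spec, 1, s, c)
            )

    recordings: list[EEGRecording] = []
    for s in range(spec.n_subjects):
        for r in range(spec.records_per_subject):
            data = np.empty((spec.n_channels, n))
            for c in range(spec.n_channels):
                rng = _substream(spec, 2, s, r, c)
                poly = subject_polys.get((s, c), shared_poly)
                x = _ar_series(poly, n, rng)
                if spec.noise_sd > 0:
                    x = x + spec.noise_sd * rng.standard_normal(n)
                data[c] = x
            recordings.append(
                EEGRecording(
                    subject_id=f"S{s:03d}",
                    data=data,
                    sampling_rate_hz=spec.sampling_rate_hz,
                    channel_names=channel_names,
                    record_id=r,
                )
            )
    return recordings


def planted_truth(spec: CohortSpec) -> np.ndarray:
    """Binary channel mask with 1 exactly at the informative channels."""
    mask = np.zeros(spec.n_channels, dtype=np.int8)
    for c in spec.informative_channels:
        mask[c] = 1
    return mask
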
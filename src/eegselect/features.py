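"""Per-channel autoregressive and wavelet features.

Every channel of a segmented recording is summarized either by the
coefficients of a Yule-Walker-fitted autoregressive model (orders 5, 10 or
20) or by statistics of a multi-level discrete wavelet decomposition.  The
per-channel vectors are laid out as contiguous column blocks of a single
feature matrix with one row per record (segment features averaged) or per
segment, labelled by subject — the representation the channel-selection
search operates on: masking a channel removes its whole column block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pywt
from statsmodels.regression.linear_model import yule_walker

from .synthetic import EEGRecording

__all__ = [
    "FeatureConfig",
    "FeatureTable",
    "ar_features",
    "wavelet_features",
    "build_feature_table",
    "apply_mask",
]

_AR_METHODS = {"AR5": 5, "AR10": 10, "AR20": 20}


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction settings.

    ``method`` is one of ``AR5``/``AR10``/``AR20`` (autoregressive
    coefficients of that order) or ``WT`` (wavelet sub-band statistics).
    Wavelet defaults — Daubechies-4, 4 decomposition levels, per-band
    {energy, mean absolute value, standard deviation} — are implementation
    choices; see docs/methods.md.
    """

    method: str = "AR5"
    wavelet_name: str = "db4"
    wavelet_levels: int = 4
    wavelet_stats: tuple[str, ...] = ("energy", "mean_abs", "sd")
    aggregate_segments: bool = True

    def __post_init__(self) -> None:
        if self.method not in (*_AR_METHODS, "WT"):
            raise ValueError(f"unknown feature method {self.method!r}")
        if self.method == "WT" and self.wavelet_levels < 1:
            raise ValueError("wavelet_levels must be >= 1")
        unknown = set(self.wavelet_stats) - {"energy", "mean_abs", "sd"}
        if unknown:
            raise ValueError(f"unknown wavelet statistics {sorted(unknown)}")

    @property
    def ar_order(self) -> int:
        if self.method not in _AR_METHODS:
            raise ValueError(f"{self.method} has no AR order")
        return _AR_METHODS[self.method]

    @property
    def n_features_per_channel(self) -> int:
        if self.method in _AR_METHODS:
            return _AR_METHODS[self.method]
        return (self.wavelet_levels + 1) * len(self.wavelet_stats)


@dataclass
class FeatureTable:
    """Samples x features matrix with per-channel column blocks."""

    X: np.ndarray
    y: np.ndarray
    channel_of_column: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.channel_of_column = np.asarray(self.channel_of_column, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X.shape[1] != self.channel_of_column.shape[0]:
            raise ValueError("channel_of_column must map every column")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def channels(self) -> np.ndarray:
        """Distinct channel indices present, sorted."""
        return np.unique(self.channel_of_column)

    @property
    def n_channels(self) -> int:
        return self.channels.size

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def subset_rows(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            self.X[idx], self.y[idx], self.channel_of_column, self.feature_names
        )


def ar_features(channel_signal: np.ndarray, order: int) -> np.ndarray:
    """Autoregressive coefficients fitted by the Yule-Walker equations.

    Returns the ``order`` coefficients ``rho`` of
    ``x_t = rho_1 x_{t-1} + ... + rho_p x_{t-p} + e_t`` obtained by solving
    the autocovariance normal equations (least-squares / "mle" variant).

    Raises
    ------
    ValueError
        If the signal is shorter than ``10 * order`` or has zero variance
        (the autocovariance system is singular).
    """
    x = np.asarray(channel_signal, dtype=float).ravel()
    if x.size <= 10 * order:
        raise ValueError(
            f"signal length {x.size} too short for AR({order}) estimation"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant signal: autocovariance matrix is singular")
    rho, _sigma = yule_walker(x, order=order, method="mle")
    return np.asarray(rho, dtype=float)


def _band_stats(coeffs: np.ndarray, stats: Sequence[str]) -> list[float]:
    out = []
    for s in stats:
        if s == "energy":
            out.append(float(np.sum(coeffs**2)))
        elif s == "mean_abs":
            out.append(float(np.mean(np.abs(coeffs))))
        else:  # sd
            out.append(float(np.std(coeffs)))
    return out


def wavelet_features(channel_signal: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """Statistics of a multi-level discrete wavelet decomposition.

    The signal is decomposed to ``wavelet_levels`` levels; for each of the
    ``wavelet_levels + 1`` sub-bands (approximation first, then details
    from coarsest to finest) the configured statistics are concatenated in
    fixed (band, statistic) order.
    """
    x = np.asarray(channel_signal, dtype=float).ravel()
    if x.size < 2**cfg.wavelet_levels:
        raise ValueError(
            f"signal length {x.size} too short for {cfg.wavelet_levels} wavelet levels"
        )
    bands = pywt.wavedec(x, cfg.wavelet_name, level=cfg.wavelet_levels)
    feats: list[float] = []
    for band in bands:
        feats.extend(_band_stats(np.asarray(band), cfg.wavelet_stats))
    return np.array(feats)


def _channel_features(seg: EEGRecording, cfg: FeatureConfig) -> np.ndarray:
    """Feature vector of one segment: channel blocks concatenated."""
    if cfg.method == "WT":
        per_ch = [wavelet_features(seg.data[c], cfg) for c in range(seg.n_channels)]
    else:
        per_ch = [
            ar_features(seg.data[c], cfg.ar_order) for c in range(seg.n_channels)
        ]
    return np.concatenate(per_ch)


def build_feature_table(
    segments: Iterable[EEGRecording], cfg: FeatureConfig
) -> FeatureTable:
    """Assemble the channel-blocked feature matrix.

    Each channel contributes a contiguous block of
    ``cfg.n_features_per_channel`` columns.  With ``aggregate_segments``
    (default) the per-segment vectors of each (subject, record) pair are
    averaged element-wise into a single row — the "mean value of each
    electrode" convention that reduces dispersion across sub-signals;
    otherwise every segment becomes its own row.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("no segments supplied")
    n_ch = segments[0].n_channels
    for s in segments:
        if s.n_channels != n_ch:
            raise ValueError(
                f"inconsistent channel counts: {s.n_channels} != {n_ch}"
            )

    rows: list[np.ndarray] = []
    labels: list[str] = []
    if cfg.aggregate_segments:
        groups: dict[tuple[str, int], list[np.ndarray]] = {}
        order: list[tuple[str, int]] = []
        for s in segments:
            key = (s.subject_id, s.record_id)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(_channel_features(s, cfg))
        for key in order:
            rows.append(np.mean(groups[key], axis=0))
            labels.append(key[0])
    else:
        for s in segments:
            rows.append(_channel_features(s, cfg))
            labels.append(s.subject_id)

    k = cfg.n_features_per_channel
    channel_of_column = np.repeat(np.arange(n_ch), k)
    names = [f"ch{c}_{cfg.method.lower()}_{j}" for c in range(n_ch) for j in range(k)]
    return FeatureTable(np.vstack(rows), np.array(labels), channel_of_column, names)


def apply_mask(table: FeatureTable, mask: np.ndarray) -> FeatureTable:
    """Restrict a table to the column blocks of the selected channels.

    ``mask`` is indexed over the distinct channels present in the table
    (in sorted order), so masks can be chained on already-restricted
    tables.  The original channel indices are preserved in
    ``channel_of_column``.
    """
    mask = np.asarray(mask).astype(int).ravel()
    if mask.size != table.n_channels:
        raise ValueError(
            f"mask length {mask.size} != channel count {table.n_channels}"
        )
    if mask.sum() == 0:
        raise ValueError("all-zero channel mask selects no features")
    selected = set(table.channels[mask.astype(bool)])
    keep = np.array([c in selected for c in table.channel_of_column])
    return FeatureTable(
        table.X[:, keep],
        table.y,
        table.channel_of_column[keep],
        [n for n, k in zip(table.feature_names, keep) if k],
    )
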
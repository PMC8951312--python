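"""Experimental protocol: repeated independent selection runs and
optimizer/classifier comparisons with significance tests.

One *experiment* is ``n_runs`` independent repetitions (default 25) of the
full pipeline on one cohort: split the feature table, search for the best
channel mask on validation fitness, retrain the classifier on the training
rows with that mask, and score it once on the held-out test rows.  Run
``r`` uses seed ``base_seed + r`` for both the split and the optimizer, so
splits resample across runs unless ``fixed_split`` is set.  Summaries
collect mean/sd of accuracy, sensitivity, specificity, F-score and the
number of selected channels, plus per-run masks, convergence curves and
per-channel selection frequencies.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureConfig, FeatureTable, build_feature_table
from .fitness import ClassifierConfig, MaskFitness, SplitConfig, evaluate_mask, split
from .optimizers import (
    OptimizerConfig,
    RunHistory,
    bhc_optimize,
    fpa_bhc_optimize,
    fpa_optimize,
)
from .preprocessing import PreprocessConfig, preprocess, segment
from .synthetic import CohortSpec, EEGRecording, generate_cohort

__all__ = [
    "ExperimentConfig",
    "ExperimentSummary",
    "cohort_feature_table",
    "run_experiment",
    "compare_optimizers",
    "channel_frequency",
    "config_to_json",
    "config_from_json",
]

_OPTIMIZERS = {
    "fpa": fpa_optimize,
    "bhc": bhc_optimize,
    "fpa_bhc": fpa_bhc_optimize,
}

_METRICS = ("acc", "sen", "spe", "f_score", "n_selected")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment end to end."""

    feature: FeatureConfig = field(default_factory=FeatureConfig)
    optimizer: str = "fpa_bhc"
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    optimizer_cfg: OptimizerConfig = field(default_factory=OptimizerConfig)
    split_cfg: SplitConfig = field(default_factory=SplitConfig)
    preprocess_cfg: PreprocessConfig | None = None
    n_runs: int = 25
    base_seed: int = 0
    fixed_split: bool = False
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.optimizer not in _OPTIMIZERS:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class ExperimentSummary:
    """Aggregate of one experiment's runs."""

    metrics: pd.DataFrame          # n_runs rows x metric columns
    best_masks: list[np.ndarray]
    histories: list[RunHistory]
    selection_frequency: np.ndarray
    config: ExperimentConfig

    @property
    def mean(self) -> pd.Series:
        return self.metrics.mean()

    @property
    def sd(self) -> pd.Series:
        return self.metrics.std(ddof=1) if len(self.metrics) > 1 else self.metrics.std(ddof=0)


def cohort_feature_table(
    recordings: list[EEGRecording],
    feature: FeatureConfig,
    preprocess_cfg: PreprocessConfig | None = None,
) -> FeatureTable:
    """Segment (and optionally filter) recordings, then extract features.

    Without a ``preprocess_cfg`` the records are only windowed into
    10-second segments; notch/band-pass filtering targets recording
    artifacts and is applied when a config is given.
    """
    segs: list[EEGRecording] = []
    seg_cfg = preprocess_cfg or PreprocessConfig()
    for rec in recordings:
        if preprocess_cfg is not None:
            segs.extend(preprocess(rec, preprocess_cfg))
        else:
            segs.extend(segment(rec, seg_cfg))
    return build_feature_table(segs, feature)


def _one_run(
    table: FeatureTable, cfg: ExperimentConfig, run_seed: int, split_seed: int
) -> tuple[RunHistory, dict[str, float]]:
    sp = replace(cfg.split_cfg, seed=split_seed)
    train, val, test = split(table, sp)
    fitness = MaskFitness(train, val, cfg.classifier)
    ocfg = replace(
        cfg.optimizer_cfg, D=table.n_channels, seed=run_seed
    )
    history = _OPTIMIZERS[cfg.optimizer](fitness, ocfg)
    # final score: retrain on training rows with the best mask, one shot
    # on the test rows the optimizer never saw
    report = evaluate_mask(history.best_mask, train, test, cfg.classifier)
    row = {m: float(getattr(report, m)) for m in _METRICS}
    return history, row


def run_experiment(cfg: ExperimentConfig) -> ExperimentSummary:
    """Run ``cfg.n_runs`` independent selection runs and aggregate."""
    recordings = generate_cohort(cfg.cohort)
    table = cohort_feature_table(recordings, cfg.feature, cfg.preprocess_cfg)

    rows, masks, histories = [], [], []
    for r in range(cfg.n_runs):
        run_seed = cfg.base_seed + r
        split_seed = cfg.base_seed if cfg.fixed_split else cfg.base_seed + r
        try:
            history, row = _one_run(table, cfg, run_seed, split_seed)
        except Exception as exc:
            raise RuntimeError(
                f"run {r} (seed {run_seed}) failed: {exc}"
            ) from exc
        histories.append(history)
        masks.append(history.best_mask)
        rows.append(row)

    metrics = pd.DataFrame(rows)
    summary = ExperimentSummary(
        metrics=metrics,
        best_masks=masks,
        histories=histories,
        selection_frequency=channel_frequency([masks]),
        config=cfg,
    )
    if cfg.output_dir is not None:
        _write_artifacts(summary, Path(cfg.output_dir))
    return summary


def channel_frequency(mask_lists: list[list[np.ndarray]]) -> np.ndarray:
    """Per-channel count of runs whose best mask selects it.

    Accepts one or more experiments' mask lists; counts are summed, so
    the total over channels equals the sum of selected-channel counts
    over all runs.
    """
    all_masks = [np.asarray(m, dtype=int) for ml in mask_lists for m in ml]
    if not all_masks:
        raise ValueError("no masks supplied")
    return np.sum(all_masks, axis=0)


def compare_optimizers(
    summaries: list[ExperimentSummary], paired: bool = True
) -> pd.DataFrame:
    """Pairwise significance tests on per-run test accuracies.

    For every pair of experiment arms, reports a t-test (paired when the
    arms share run seeds, else Welch's two-sample) and — for paired arms —
    the Wilcoxon signed-rank test, flagged significant at alpha = 0.05.
    Arms must have equal ``n_runs``.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two experiment arms to compare")
    n = {len(s.metrics) for s in summaries}
    if len(n) != 1:
        raise ValueError("mismatched n_runs across arms")

    rows = []
    for a, b in combinations(range(len(summaries)), 2):
        sa, sb = summaries[a], summaries[b]
        xa = sa.metrics["acc"].to_numpy()
        xb = sb.metrics["acc"].to_numpy()
        if paired:
            t_stat, t_p = stats.ttest_rel(xa, xb)
            diff = xa - xb
            if np.allclose(diff, 0.0):
                w_stat, w_p = 0.0, 1.0
            else:
                w_stat, w_p = stats.wilcoxon(xa, xb)
            if np.all(np.isnan([t_stat])):
                t_stat, t_p = 0.0, 1.0
        else:
            t_stat, t_p = stats.ttest_ind(xa, xb, equal_var=False)
            w_stat, w_p = np.nan, np.nan
        rows.append(
            {
                "arm_a": sa.config.optimizer,
                "arm_b": sb.config.optimizer,
                "mean_a": xa.mean(),
                "mean_b": xb.mean(),
                "t_stat": float(t_stat),
                "t_p": float(t_p),
                "wilcoxon_w": float(w_stat),
                "wilcoxon_p": float(w_p),
                "significant_0.05": bool(min(t_p, w_p if paired else t_p) < 0.05),
            }
        )
    return pd.DataFrame(rows)


def config_to_json(cfg: ExperimentConfig, path: str | Path) -> None:
    """Serialize an experiment config (including the cohort spec) to JSON."""
    d = asdict(cfg)
    d["cohort"]["informative_channels"] = sorted(
        cfg.cohort.informative_channels
    )
    d["feature"]["wavelet_stats"] = list(cfg.feature.wavelet_stats)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, sort_keys=True)
        fh.write("\n")


def config_from_json(path: str | Path) -> ExperimentConfig:
    """Load an experiment config written by :func:`config_to_json`."""
    with open(path) as fh:
        d = json.load(fh)
    d["cohort"]["informative_channels"] = frozenset(
        d["cohort"]["informative_channels"]
    )
    d["feature"]["wavelet_stats"] = tuple(d["feature"]["wavelet_stats"])
    pp = d.pop("preprocess_cfg", None)
    return ExperimentConfig(
        feature=FeatureConfig(**d.pop("feature")),
        classifier=ClassifierConfig(**d.pop("classifier")),
        cohort=CohortSpec(**d.pop("cohort")),
        optimizer_cfg=OptimizerConfig(**d.pop("optimizer_cfg")),
        split_cfg=SplitConfig(**d.pop("split_cfg")),
        preprocess_cfg=PreprocessConfig(**pp) if pp else None,
        **d,
    )


def _write_artifacts(summary: ExperimentSummary, out: Path) -> None:
    """Delimited-text artifacts; content is fully determined by the config."""
    out.mkdir(parents=True, exist_ok=True)
    summary.metrics.to_csv(out / "runs.tsv", sep="\t", index_label="run")
    agg = pd.DataFrame({"mean": summary.mean, "sd": summary.sd})
    agg.to_csv(out / "summary.tsv", sep="\t", index_label="metric")
    with open(out / "best_masks.txt", "w") as fh:
        for m in summary.best_masks:
            fh.write("".join(str(int(b)) for b in m) + "\n")
    freq = pd.DataFrame(
        {
            "channel": np.arange(summary.selection_frequency.size),
            "count": summary.selection_frequency,
        }
    )
    freq.to_csv(out / "channel_frequency.tsv", sep="\t", index=False)
    conv = pd.DataFrame(
        {f"run{r}": h.best_fitness_per_iter for r, h in enumerate(summary.histories)}
    )
    conv.to_csv(out / "convergence.tsv", sep="\t", index_label="iteration")
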
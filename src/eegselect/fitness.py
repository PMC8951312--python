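"""Classifier-wrapped fitness for channel masks.

A candidate channel mask is scored by training a classifier on the masked
training features and measuring identification performance on a held-out
set.  Performance is summarized by true-accept / true-reject /
false-accept / false-reject counts aggregated one-vs-rest over the subject
classes (micro-averaging), from which the accuracy-rate objective

    Acc = 100 * (TA + TR) / (TA + TR + FA + FR)

and sensitivity, specificity and F-score are derived.  For two classes the
counts reduce to the ordinary binary confusion matrix; for K > 2 classes
the micro-aggregated Acc is a strictly increasing affine function of plain
sample accuracy ``a``:  Acc = 100 * ((K - 2) + 2 a) / K, so maximizing it
ranks channel subsets identically to maximizing sample accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable, apply_mask

__all__ = [
    "SplitConfig",
    "ClassifierConfig",
    "FitnessReport",
    "identification_counts",
    "identification_accuracy",
    "split",
    "evaluate_mask",
    "MaskFitness",
]


@dataclass(frozen=True)
class SplitConfig:
    """Train/validation/test partition: 50% / 30% / 20% by default."""

    train_frac: float = 0.5
    test_frac: float = 0.2
    val_frac: float = 0.3
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        fracs = (self.train_frac, self.test_frac, self.val_frac)
        if min(fracs) <= 0 or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")


@dataclass(frozen=True)
class ClassifierConfig:
    """Wrapped classifier and its hyper-parameters.

    ``kind`` is one of svm_rbf, svm_linear, lda, knn, ann, naive_bayes,
    tree; only the fields relevant to that kind are read.  The SVM default
    (C = 1e11, gamma = 0.01, RBF kernel) is the wrapper's reference
    setting; features are standardized with training-set statistics for
    every classifier.
    """

    kind: str = "svm_rbf"
    C: float = 1.0e11
    gamma: float = 0.01
    k: int = 1
    hidden: int = 32
    learning_rate: float = 0.3
    confidence_factor: float = 0.25
    seed: int = 0

    def build(self) -> Pipeline:
        if self.kind == "svm_rbf":
            clf = SVC(kernel="rbf", C=self.C, gamma=self.gamma)
        elif self.kind == "svm_linear":
            clf = SVC(kernel="linear", C=self.C)
        elif self.kind == "lda":
            clf = LinearDiscriminantAnalysis()
        elif self.kind == "knn":
            clf = KNeighborsClassifier(n_neighbors=self.k)
        elif self.kind == "ann":
            clf = MLPClassifier(
                hidden_layer_sizes=(self.hidden,),
                learning_rate_init=self.learning_rate,
                max_iter=500,
                random_state=self.seed,
            )
        elif self.kind == "naive_bayes":
            clf = GaussianNB()
        elif self.kind == "tree":
            clf = DecisionTreeClassifier(random_state=self.seed)
        else:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class FitnessReport:
    """Confusion counts and derived identification metrics for one mask."""

    TA: int
    TR: int
    FA: int
    FR: int
    acc: float
    sen: float
    spe: float
    f_score: float
    n_selected: int
    mask: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int8))


def identification_counts(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[int, int, int, int]:
    """One-vs-rest TA/TR/FA/FR summed over classes (micro-aggregation).

    Each sample contributes one accept/reject decision per enrolled
    identity: its true class (genuine trial) and every other class
    (impostor trials).
    """
    labels = np.unique(np.concatenate([y_true, y_pred]))
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    n = cm.sum()
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = n - tp - fp - fn
    return int(tp.sum()), int(tn.sum()), int(fp.sum()), int(fn.sum())


def identification_accuracy(TA: int, TR: int, FA: int, FR: int) -> float:
    """Accuracy rate: 100 * (TA + TR) / (TA + TR + FA + FR)."""
    total = TA + TR + FA + FR
    if total == 0:
        raise ValueError("empty confusion counts")
    return 100.0 * (TA + TR) / total


def _report_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, mask: np.ndarray
) -> FitnessReport:
    ta, tr, fa, fr = identification_counts(y_true, y_pred)
    return FitnessReport(
        TA=ta,
        TR=tr,
        FA=fa,
        FR=fr,
        acc=identification_accuracy(ta, tr, fa, fr),
        sen=ta / (ta + fr) if ta + fr else 0.0,
        spe=tr / (tr + fa) if tr + fa else 0.0,
        f_score=2 * ta / (2 * ta + fa + fr) if 2 * ta + fa + fr else 0.0,
        n_selected=int(np.asarray(mask).sum()),
        mask=np.asarray(mask, dtype=np.int8).copy(),
    )


def split(
    table: FeatureTable, cfg: SplitConfig
) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """Partition rows into (train, validation, test), stratified by subject.

    Per-class row counts are allocated by largest remainder so the global
    proportions are honoured as closely as integer counts allow.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = table.n_samples
    idx_parts: dict[str, list[np.ndarray]] = {"train": [], "val": [], "test": []}
    fracs = {"train": cfg.train_frac, "val": cfg.val_frac, "test": cfg.test_frac}

    if cfg.stratified:
        groups = [np.flatnonzero(table.y == lab) for lab in np.unique(table.y)]
        for g in groups:
            if g.size < 2:
                raise ValueError(
                    f"subject {table.y[g[0]]!r} has a single sample; "
                    "stratified splitting is impossible"
                )
    else:
        groups = [np.arange(n)]

    for g in groups:
        perm = rng.permutation(g)
        counts = _largest_remainder(g.size, fracs)
        a, b = counts["train"], counts["train"] + counts["val"]
        idx_parts["train"].append(perm[:a])
        idx_parts["val"].append(perm[a:b])
        idx_parts["test"].append(perm[b:])

    out = {k: np.sort(np.concatenate(v)) for k, v in idx_parts.items()}
    return (
        table.subset_rows(out["train"]),
        table.subset_rows(out["val"]),
        table.subset_rows(out["test"]),
    )


def _largest_remainder(n: int, fracs: dict[str, float]) -> dict[str, int]:
    exact = {k: n * f for k, f in fracs.items()}
    counts = {k: int(np.floor(v)) for k, v in exact.items()}
    short = n - sum(counts.values())
    # hand leftovers to the largest fractional parts, ties by key order
    by_rem = sorted(fracs, key=lambda k: exact[k] - counts[k], reverse=True)
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def evaluate_mask(
    mask: np.ndarray,
    train: FeatureTable,
    eval_set: FeatureTable,
    clf: ClassifierConfig,
) -> FitnessReport:
    """Train the classifier on masked features and score the held-out set."""
    mask = np.asarray(mask).astype(int).ravel()
    if mask.sum() == 0:
        raise ValueError("cannot evaluate an all-zero channel mask")
    model = clf.build()
    tr = apply_mask(train, mask)
    ev = apply_mask(eval_set, mask)
    try:
        model.fit(tr.X, tr.y)
    except Exception as exc:  # pragma: no cover - classifier-dependent
        raise RuntimeError(f"classifier {clf.kind} failed to train: {exc}") from exc
    y_pred = model.predict(ev.X)
    return _report_from_predictions(ev.y, y_pred, mask)


class MaskFitness:
    """Memoized validation-accuracy objective over channel masks.

    Holds a fixed (train, validation, classifier) context; repeated
    queries for the same mask hit a cache keyed on the bit-string, and
    ``evaluations`` counts cache misses — the currency for matched-budget
    optimizer comparisons.
    """

    def __init__(
        self,
        train: FeatureTable,
        validation: FeatureTable,
        clf: ClassifierConfig | None = None,
    ) -> None:
        self.train = train
        self.validation = validation
        self.clf = clf or ClassifierConfig()
        self.n_channels = train.n_channels
        self._cache: dict[bytes, float] = {}
        self.evaluations = 0

    def __call__(self, mask: np.ndarray) -> float:
        key = np.asarray(mask, dtype=np.int8).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        report = evaluate_mask(mask, self.train, self.validation, self.clf)
        self.evaluations += 1
        self._cache[key] = report.acc
        return report.acc
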
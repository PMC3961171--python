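"""Verification statistics for substrate-specificity predictions.

Covers overall and per-class accuracy with confusion counts, micro- and
macro-averaged F-measure, an exact binomial significance test against a
random-prediction null with Bonferroni correction over the number of
candidate models examined, the prior-only baseline, and a t-test comparing
the confidence (top-class posterior) of correct versus incorrect
predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import DEFAULT_CLASSES


@dataclass
class EvaluationReport:
    """Confusion counts and derived summary statistics.

    ``confusion[i, j]`` counts records with true class i predicted as class
    j (fixed class order).  ``f_measure`` is micro-averaged — identical to
    accuracy in single-label multi-class classification — with the
    macro-average reported alongside.
    """

    classes: tuple[str, ...]
    confusion: np.ndarray
    p_random: float | None = None
    p_confidence: float | None = None

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, float)
        n = len(self.classes)
        if self.confusion.shape != (n, n):
            raise ValueError("confusion matrix must be n_classes x n_classes")

    @property
    def n_total(self) -> int:
        return int(self.confusion.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.confusion))

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total

    @property
    def per_class_accuracy(self) -> dict[str, float]:
        """Recall per true class."""
        row_tot = self.confusion.sum(axis=1)
        return {
            c: (float(self.confusion[i, i] / row_tot[i]) if row_tot[i] else float("nan"))
            for i, c in enumerate(self.classes)
        }

    @property
    def f_measure(self) -> float:
        """Micro-averaged F1: aggregate TP / FP / FN over classes.  For
        single-label multi-class data this equals accuracy."""
        tp = np.trace(self.confusion)
        fp = self.confusion.sum() - tp  # every error is one FP and one FN
        fn = fp
        return float(2 * tp / (2 * tp + fp + fn))

    @property
    def macro_f_measure(self) -> float:
        f1s = []
        for i in range(len(self.classes)):
            tp = self.confusion[i, i]
            fp = self.confusion[:, i].sum() - tp
            fn = self.confusion[i, :].sum() - tp
            denom = 2 * tp + fp + fn
            f1s.append(2 * tp / denom if denom else 0.0)
        return float(np.mean(f1s))

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.astype(int).tolist(),
            "n_total": self.n_total,
            "n_correct": self.n_correct,
            "accuracy": self.accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "f_measure": self.f_measure,
            "macro_f_measure": self.macro_f_measure,
            "p_random": self.p_random,
            "p_confidence": self.p_confidence,
        }


def evaluate(
    predictions: Mapping[str, str],
    truths: Mapping[str, str],
    classes: tuple[str, ...] = DEFAULT_CLASSES,
) -> EvaluationReport:
    """Confusion counts and accuracies for id-aligned prediction/truth maps."""
    if set(predictions) != set(truths):
        only_p = sorted(set(predictions) - set(truths))
        only_t = sorted(set(truths) - set(predictions))
        raise ValueError(
            f"prediction/truth id mismatch: only-predicted {only_p[:5]}, "
            f"only-truth {only_t[:5]}"
        )
    n = len(classes)
    confusion = np.zeros((n, n))
    for rid, truth in truths.items():
        confusion[classes.index(truth), classes.index(predictions[rid])] += 1
    return EvaluationReport(tuple(classes), confusion)


def prior_only_accuracy(class_counts: Sequence[int]) -> float:
    """Accuracy of always predicting the modal class: max(counts)/sum(counts)."""
    counts = np.asarray(class_counts, float)
    if counts.size == 0 or counts.sum() <= 0:
        raise ValueError("class counts must be nonempty with positive total")
    if np.any(counts < 0):
        raise ValueError("class counts must be nonnegative")
    return float(counts.max() / counts.sum())


def significance_vs_random(
    n_correct: int,
    n_total: int,
    class_counts: Sequence[int],
    n_models: int = 1,
    null: str = "priors",
) -> float:
    """Bonferroni-corrected exact binomial p-value against random prediction.

    Under the default null both the prediction and the truth of each record
    are drawn independently from the class priors, so a single record
    matches with probability q = sum_i p_i^2; the p-value is the exact upper
    binomial tail P(X >= n_correct), X ~ Binomial(n_total, q), multiplied by
    the number of candidate models considered and capped at 1.

    Alternative nulls: ``uniform`` (q = 1/n, prediction uniformly random)
    and ``modal`` (q = max_i p_i, always predicting the modal class).
    """
    if not (0 <= n_correct <= n_total) or n_total <= 0:
        raise ValueError("need 0 <= n_correct <= n_total with n_total > 0")
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    counts = np.asarray(class_counts, float)
    if counts.sum() <= 0 or np.any(counts < 0):
        raise ValueError("degenerate class counts")
    p = counts / counts.sum()
    if null == "priors":
        q = float((p**2).sum())
    elif null == "uniform":
        q = 1.0 / len(p)
    elif null == "modal":
        q = float(p.max())
    else:
        raise ValueError(f"unknown null {null!r}")
    tail = float(stats.binom.sf(n_correct - 1, n_total, q))
    return min(1.0, n_models * tail)


def confidence_t_test(
    posteriors_correct: Sequence[float],
    posteriors_incorrect: Sequence[float],
    equal_var: bool = False,
) -> float:
    """One-sided two-sample t-test (Welch by default) that the top-class
    posterior is higher for correct than for incorrect predictions."""
    a = np.asarray(posteriors_correct, float)
    b = np.asarray(posteriors_incorrect, float)
    for name, g in (("correct", a), ("incorrect", b)):
        if g.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 values")
        if np.any((g <= 0) | (g > 1)):
            raise ValueError(f"group {name!r} has values outside (0, 1]")
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative="greater")
    return float(res.pvalue)
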
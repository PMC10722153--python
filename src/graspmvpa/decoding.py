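"""Linear binary orientation decoding.

Three analyses share one linear soft-margin support-vector classifier:

* *same-type*: train and test within one action condition, leave-one-run-out;
* *transfer-type* (cross-decoding): train on one condition, test on another,
  averaged over both directions -- above-chance accuracy implies a pattern
  shared between the conditions;
* *cross-phase*: train on instruction-phase samples, test on action-phase
  samples and vice versa -- below-chance accuracy implies anti-correlated
  phase coding.

Features are z-scored per fold with training-set statistics (see
:func:`graspmvpa.preprocess.zscore_fold`).  Chance level is 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .preprocess import PatternSample, zscore_fold

DEFAULT_MARGIN_PENALTY = 1.0


class DecodingError(ValueError):
    """Raised for ill-posed decoding requests."""


@dataclass
class LinearModel:
    """A fitted linear decision rule: sign(w . x + b).

    An exactly-zero decision value predicts the first label seen in the
    training set, which makes repeated runs bit-reproducible.
    """

    weights: np.ndarray
    bias: float
    pos_label: int
    neg_label: int
    first_label: int

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features, dtype=float) @ self.weights + self.bias

    def predict(self, features: np.ndarray) -> np.ndarray:
        d = self.decision_values(features)
        out = np.where(d > 0, self.pos_label,
                       np.where(d < 0, self.neg_label, self.first_label))
        return out.astype(int)


def fit_linear_classifier(train: Sequence[PatternSample] | np.ndarray,
                          margin_penalty: float = DEFAULT_MARGIN_PENALTY,
                          labels: np.ndarray | None = None) -> LinearModel:
    """Fit a linear soft-margin SVM on orientation-labelled samples.

    Accepts either a sequence of :class:`PatternSample` or an (X, labels)
    pair.  Deterministic for a fixed input order and penalty.
    """
    if labels is None:
        X, y = as_xy(train)
    else:
        X, y = np.asarray(train, dtype=float), np.asarray(labels)
    if margin_penalty <= 0:
        raise DecodingError("margin_penalty must be positive")
    classes = np.unique(y)
    if classes.size != 2:
        raise DecodingError(f"training set must contain both orientation labels, "
                            f"got {classes.tolist()}")
    svm = SVC(kernel="linear", C=margin_penalty)
    svm.fit(X, y)
    return LinearModel(weights=svm.coef_[0].copy(), bias=float(svm.intercept_[0]),
                       neg_label=int(svm.classes_[0]), pos_label=int(svm.classes_[1]),
                       first_label=int(y[0]))


def as_xy(samples: Sequence[PatternSample]) -> tuple[np.ndarray, np.ndarray]:
    if len(samples) == 0:
        raise DecodingError("empty sample set")
    X = np.vstack([s.features for s in samples])
    y = np.array([s.orientation for s in samples], dtype=int)
    if not np.all(np.isfinite(X)):
        raise DecodingError("pattern features must be finite")
    return X, y


@dataclass
class DecodingResult:
    """Accuracy of one analysis for one participant/ROI."""

    participant_id: int
    roi_name: str
    kind: str                      # "same" | "transfer" | "cross_phase"
    phase: str | tuple[str, str]
    condition: str | tuple[str, str]
    accuracy: float
    fold_accuracies: list[float] = field(default_factory=list)
    directions: dict[str, float] = field(default_factory=dict)


def _train_test_accuracy(train: Sequence[PatternSample],
                         test: Sequence[PatternSample],
                         margin_penalty: float) -> float:
    Xtr, ytr = as_xy(train)
    Xte, yte = as_xy(test)
    if Xtr.shape[1] != Xte.shape[1]:
        raise DecodingError(f"feature-length mismatch: train {Xtr.shape[1]}, "
                            f"test {Xte.shape[1]}")
    ztr, zte = zscore_fold(Xtr, Xte)
    model = fit_linear_classifier(ztr, margin_penalty, labels=ytr)
    return float(np.mean(model.predict(zte) == yte))


def loro_accuracy(samples: Sequence[PatternSample],
                  margin_penalty: float = DEFAULT_MARGIN_PENALTY) -> DecodingResult:
    """Leave-one-run-out accuracy for one condition/phase/ROI/participant.

    Each retained run serves once as the test set; features are z-scored
    inside each fold with training statistics; fold accuracies are averaged.
    """
    samples = list(samples)
    if not samples:
        raise DecodingError("no samples")
    runs = sorted({s.run_index for s in samples})
    if len(runs) < 2:
        raise DecodingError("leave-one-run-out needs samples from at least 2 runs")
    fold_acc = []
    for run in runs:
        train = [s for s in samples if s.run_index != run]
        test = [s for s in samples if s.run_index == run]
        labels = {s.orientation for s in train}
        if len(labels) < 2:
            raise DecodingError(f"training fold for held-out run {run} lacks a class")
        fold_acc.append(_train_test_accuracy(train, test, margin_penalty))
    first = samples[0]
    return DecodingResult(first.participant_id, first.roi_name, "same",
                          first.phase, first.condition,
                          float(np.mean(fold_acc)), fold_acc)


def transfer_accuracy(samples_a: Sequence[PatternSample],
                      samples_b: Sequence[PatternSample],
                      margin_penalty: float = DEFAULT_MARGIN_PENALTY) -> DecodingResult:
    """Cross-condition accuracy: mean of train-on-A/test-on-B and the
    reverse direction, each z-scored with its own training statistics."""
    a, b = list(samples_a), list(samples_b)
    acc_ab = _train_test_accuracy(a, b, margin_penalty)
    acc_ba = _train_test_accuracy(b, a, margin_penalty)
    first = a[0]
    cond = (a[0].condition, b[0].condition)
    return DecodingResult(first.participant_id, first.roi_name, "transfer",
                          first.phase, cond, float((acc_ab + acc_ba) / 2.0),
                          [acc_ab, acc_ba],
                          {f"{cond[0]}_to_{cond[1]}": acc_ab,
                           f"{cond[1]}_to_{cond[0]}": acc_ba})


def cross_phase_accuracy(samples_instruction: Sequence[PatternSample],
                         samples_action: Sequence[PatternSample],
                         margin_penalty: float = DEFAULT_MARGIN_PENALTY) -> DecodingResult:
    """Cross-phase accuracy within one condition: train on one phase, test
    on the other, both directions averaged."""
    ins, act = list(samples_instruction), list(samples_action)
    acc_ia = _train_test_accuracy(ins, act, margin_penalty)
    acc_ai = _train_test_accuracy(act, ins, margin_penalty)
    first = ins[0]
    phases = (ins[0].phase, act[0].phase)
    return DecodingResult(first.participant_id, first.roi_name, "cross_phase",
                          phases, first.condition, float((acc_ia + acc_ai) / 2.0),
                          [acc_ia, acc_ai],
                          {f"{phases[0]}_to_{phases[1]}": acc_ia,
                           f"{phases[1]}_to_{phases[0]}": acc_ai})
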
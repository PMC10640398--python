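"""Scoring of predicted spot-type assignments against ground truth.

Metrics: overall accuracy, macro F1 (mean of one-vs-rest F1 over the
classes present in the truth; a class with zero precision+recall scores
0), and the multiclass Matthews correlation coefficient in its covariance
(Gorodkin) form, with the zero-denominator convention MCC = 0. For
unsupervised predictions whose cluster identities are arbitrary,
``match_labels`` finds the one-to-one relabeling maximizing agreement
(Hungarian assignment on the confusion matrix); surplus predicted
clusters stay unmatched and score as errors.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import accuracy_score, f1_score, matthews_corrcoef

__all__ = ["confusion_matrix", "score_assignment", "match_labels"]


def _check(z_true, z_pred):
    z_true = np.asarray(z_true)
    z_pred = np.asarray(z_pred)
    if z_true.shape != z_pred.shape or z_true.ndim != 1:
        raise ValueError("truth and prediction must be 1-D vectors of equal length")
    return z_true, z_pred


def confusion_matrix(z_true, z_pred, labels=None) -> tuple[np.ndarray, np.ndarray]:
    """Counts of (true, predicted) label pairs over a shared label space."""
    z_true, z_pred = _check(z_true, z_pred)
    if labels is None:
        labels = np.unique(np.concatenate([z_true, z_pred]))
    labels = np.asarray(labels)
    lut = {lab: i for i, lab in enumerate(labels)}
    C = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(z_true, z_pred):
        C[lut[t], lut[p]] += 1
    return C, labels


def score_assignment(z_true, z_pred) -> tuple[float, float, float]:
    """(accuracy, macro F1, MCC) of a predicted assignment."""
    z_true, z_pred = _check(z_true, z_pred)
    acc = accuracy_score(z_true, z_pred)
    macro = f1_score(z_true, z_pred, labels=np.unique(z_true), average="macro",
                     zero_division=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-denominator MCC -> 0 by convention
        mcc = matthews_corrcoef(z_true, z_pred)
    return float(acc), float(macro), float(mcc)


def match_labels(z_true, z_pred):
    """Optimally relabel anonymous predicted clusters onto the truth.

    Solves the one-to-one assignment maximizing the confusion-matrix trace.
    Predicted clusters left over when there are more of them than truth
    classes keep a fresh sentinel label absent from the truth, so they
    count as errors under every metric.
    """
    z_true, z_pred = _check(z_true, z_pred)
    true_labels = np.unique(z_true)
    pred_labels = np.unique(z_pred)
    C = np.zeros((len(pred_labels), len(true_labels)), dtype=np.int64)
    t_lut = {lab: i for i, lab in enumerate(true_labels)}
    p_lut = {lab: i for i, lab in enumerate(pred_labels)}
    for t, p in zip(z_true, z_pred):
        C[p_lut[p], t_lut[t]] += 1
    rows, cols = linear_sum_assignment(C, maximize=True)
    mapping = {pred_labels[r]: true_labels[c] for r, c in zip(rows, cols)}
    # surplus predicted clusters: give labels guaranteed outside the truth
    sentinel = 0
    for lab in pred_labels:
        if lab not in mapping:
            mapping[lab] = (f"_unmatched_{sentinel}" if z_pred.dtype.kind in "OU"
                            else -1 - sentinel)
            sentinel += 1
    return np.array([mapping[p] for p in z_pred])
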
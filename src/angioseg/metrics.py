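"""Segmentation quality metrics: DSC, weighted vessel score, recall.

The vessel score (V-score) is a weighted recall designed to expose loss of
vessel continuity: ground-truth voxels carry positive weights that decrease
from proximal (aortic root) to distal (intracranial periphery), so a missed
proximal segment costs more than an equally sized distal one. With uniform
weights it reduces exactly to recall.
"""

from __future__ import annotations

import numpy as np


def _as_bool(mask) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def _check_shapes(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred, truth = _as_bool(pred), _as_bool(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    return pred, truth


def dsc(pred, truth, *, empty_value: float = 1.0) -> float:
    """Dice similarity coefficient ``2|Y ∩ Ŷ| / (|Y| + |Ŷ|)``.

    Symmetric overlap in [0, 1]. When both masks are empty the ratio is
    undefined; by convention we report ``empty_value`` (default 1.0, perfect
    agreement).
    """
    pred, truth = _check_shapes(pred, truth)
    denom = int(pred.sum()) + int(truth.sum())
    if denom == 0:
        return float(empty_value)
    return 2.0 * int((pred & truth).sum()) / denom


def recall(pred, truth) -> float:
    """Sensitivity ``|Ŷ ∩ Y| / |Y|``: fraction of true voxels recovered."""
    pred, truth = _check_shapes(pred, truth)
    n_truth = int(truth.sum())
    if n_truth == 0:
        raise ValueError("recall is undefined for an empty ground truth")
    return int((pred & truth).sum()) / n_truth


def v_score(pred, truth, weights, *, negate: bool = False) -> float:
    """Weighted vessel-continuity score ``Σ w(Ŷ ∩ Y) / Σ w(Y)``.

    ``weights`` must be non-negative and aligned with ``truth``; weights
    outside the ground-truth support are ignored. ``negate=True`` flips the
    sign for parity with conventions that report the score negated.
    """
    pred, truth = _check_shapes(pred, truth)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != truth.shape:
        raise ValueError(f"weights shape {weights.shape} != mask shape {truth.shape}")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    denom = float(weights[truth].sum())
    if denom == 0:
        raise ValueError("v_score undefined: zero total weight on the ground truth")
    score = float(weights[pred & truth].sum()) / denom
    return -score if negate else score


def binarize(prob, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability field: ``mask = (p >= t)``.

    Monotone in ``t``: raising the threshold never adds voxels.
    """
    prob = np.asarray(prob)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    if prob.size and (prob.min() < 0 or prob.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return prob >= threshold


def case_accuracy(
    cases: list[dict],
    *,
    dsc_threshold: float = 0.8,
    v_score_threshold: float | None = None,
) -> float:
    """Fraction of cases whose metrics clear the configured pass thresholds.

    Each case is a dict with at least ``"dsc"`` and optionally ``"v_score"``.
    A case passes when every configured threshold is met.
    """
    if not cases:
        raise ValueError("case_accuracy needs at least one case")
    passed = 0
    for case in cases:
        ok = case["dsc"] >= dsc_threshold
        if v_score_threshold is not None:
            ok = ok and case.get("v_score", 0.0) >= v_score_threshold
        passed += bool(ok)
    return passed / len(cases)


def evaluate_masks(pred, truth, weights=None) -> dict:
    """Bundle DSC, recall and (given weights) V-score into one report."""
    report = {"dsc": dsc(pred, truth)}
    if int(_as_bool(truth).sum()) > 0:
        report["recall"] = recall(pred, truth)
    if weights is not None:
        report["v_score"] = v_score(pred, truth, weights)
    return report
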
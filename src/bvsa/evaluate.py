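"""Scoring inferred networks against a reference topology.

Predictions are scored over ordered off-diagonal node pairs (self-edges
are never modeled).  An edge is predicted at threshold p_th when its
score is >= p_th; sweeping the threshold traces the ROC and
precision-recall curves, whose areas (AUROC, AUPR) summarize recovery
accuracy.  Thresholds always include every unique achieved score, which
makes the trapezoidal AUROC identical to the midrank Mann-Whitney
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class EvaluationResult:
    roc: np.ndarray  # (n_points, 2): FP rate, TP rate
    pr: np.ndarray  # (n_points, 2): recall, precision
    auroc: float
    aupr: float
    threshold_grid: np.ndarray


@dataclass
class RunSummary:
    mean_auroc: float
    sd_auroc: float
    mean_aupr: float
    sd_aupr: float
    n_runs: int


def _off_diagonal_pairs(scores: np.ndarray, truth: np.ndarray):
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape or scores.ndim != 2:
        raise ValueError("score and truth matrices must have the same n x n shape")
    off = ~np.eye(scores.shape[0], dtype=bool)
    return scores[off], (truth[off] != 0)


def confusion_at_threshold(
    scores: np.ndarray, truth: np.ndarray, p_th: float
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) over ordered off-diagonal pairs at one threshold."""
    s, t = _off_diagonal_pairs(scores, truth)
    pred = s >= p_th
    tp = int(np.sum(pred & t))
    fp = int(np.sum(pred & ~t))
    fn = int(np.sum(~pred & t))
    tn = int(np.sum(~pred & ~t))
    return tp, fp, tn, fn


def sweep_and_areas(
    scores: np.ndarray,
    truth: np.ndarray,
    grid: np.ndarray | None = None,
) -> EvaluationResult:
    """Threshold sweep with trapezoidal AUROC/AUPR.

    For probability matrices the default grid runs 0 to 1 in steps of
    0.01; for unbounded score matrices (e.g. |connection coefficients|)
    it is the set of unique absolute values.  Unique achieved scores and
    an above-maximum sentinel are always added so every attainable
    confusion point contributes.  The zero-prediction end of the PR
    curve uses the conventional precision of 1.
    """
    s, t = _off_diagonal_pairs(scores, truth)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores contain non-finite off-diagonal entries")
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0:
        raise ValueError("truth has no positive edges; AUPR is undefined")
    bounded = s.min() >= 0 and s.max() <= 1
    if grid is None:
        grid = np.round(np.arange(0, 101) * 0.01, 2) if bounded else np.array([])
    grid = np.asarray(grid, dtype=float)
    thresholds = np.unique(np.concatenate([grid, s, [s.max() + 1.0]]))[::-1]

    roc_pts = []
    pr_pts = []
    for th in thresholds:  # descending: curves grow from (0,0)
        pred = s >= th
        tp = int(np.sum(pred & t))
        fp = int(np.sum(pred & ~t))
        tpr = tp / n_pos
        fpr = fp / n_neg if n_neg else 0.0
        prec = tp / (tp + fp) if (tp + fp) else 1.0
        roc_pts.append((fpr, tpr))
        pr_pts.append((tpr, prec))
    roc = np.array(roc_pts)
    pr = np.array(pr_pts)
    auroc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    aupr = float(np.trapezoid(pr[:, 1], pr[:, 0]))
    return EvaluationResult(
        roc=roc, pr=pr, auroc=auroc, aupr=aupr, threshold_grid=thresholds
    )


def repeated_run_summary(results: list[EvaluationResult]) -> RunSummary:
    """Mean and standard deviation of AUROC/AUPR across repeated runs."""
    if len(results) < 2:
        raise ValueError("need at least two runs to summarize")
    aurocs = np.array([r.auroc for r in results])
    auprs = np.array([r.aupr for r in results])
    return RunSummary(
        mean_auroc=float(aurocs.mean()),
        sd_auroc=float(aurocs.std(ddof=1)),
        mean_aupr=float(auprs.mean()),
        sd_aupr=float(auprs.std(ddof=1)),
        n_runs=len(results),
    )


def plot_curves(result: EvaluationResult, path: str) -> None:
    """Write ROC and PR curves side by side to ``path`` (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(result.roc[:, 0], result.roc[:, 1])
    ax1.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax1.set(xlabel="FP rate", ylabel="TP rate", title=f"ROC (AUROC={result.auroc:.3f})")
    ax2.plot(result.pr[:, 0], result.pr[:, 1])
    ax2.set(xlabel="recall", ylabel="precision", title=f"PR (AUPR={result.aupr:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
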
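"""Discriminant evaluation of markers: ROC curves, Youden-optimal cutoffs,
AUC confidence intervals, and logistic predicted-probability fusion.

Conventions: the impaired (MCI) group is the positive class throughout.
Markers where larger values call the positive class use
``direction="higher_is_positive"``; screening scores where smaller values
call it (MoCA-K) use ``"lower_is_positive"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

HIGHER = "higher_is_positive"
LOWER = "lower_is_positive"

POSITIVE_LABEL = "MCI"


@dataclass
class RocCurve:
    """Empirical ROC over the exhaustive midpoint threshold set."""

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    direction: str
    score_median: float
    auc_ci_low: float | None = None
    auc_ci_high: float | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass
class CombinedMarker:
    """Logistic fusion of one or more markers into a predicted probability."""

    coefficients: np.ndarray  # intercept first, then one slope per marker
    probabilities: np.ndarray
    separation_flag: bool
    converged: bool
    n_iter: int


def _as_binary_labels(labels: Sequence, positive_label=POSITIVE_LABEL) -> np.ndarray:
    """Map labels to a {0,1} array with the positive class as 1."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "biufc":
        if set(np.unique(arr)) - {0, 1}:
            raise ValueError("labels must be binary")
        return arr.astype(int)
    return (arr == positive_label).astype(int)


def empirical_roc(
    scores: Sequence[float],
    labels: Sequence,
    direction: str = HIGHER,
    positive_label=POSITIVE_LABEL,
) -> RocCurve:
    """Empirical ROC curve of a marker.

    Candidate thresholds are the midpoints between consecutive distinct
    score values plus sentinels outside the observed range; sensitivity and
    specificity are evaluated at each. The AUC is the trapezoidal area,
    which equals the all-pairs concordance probability with ties counted
    one half.
    """
    if direction not in (HIGHER, LOWER):
        raise ValueError(f"unknown direction {direction!r}")
    scores = np.asarray(scores, dtype=float)
    y = _as_binary_labels(labels, positive_label)
    if scores.shape[0] != y.shape[0]:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int(y.shape[0] - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate labels: both classes must be non-empty")

    warns: list[str] = []
    # orient so that larger oriented score = more positive
    oriented = scores if direction == HIGHER else -scores
    distinct = np.unique(oriented)
    if distinct.size == 1:
        warns.append("all scores identical; AUC is 0.5 by convention")
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    thr = np.concatenate(([-np.inf], midpoints, [np.inf]))

    # positive call: oriented score > threshold (vectorized via sorted counts)
    pos_sorted = np.sort(oriented[y == 1])
    neg_sorted = np.sort(oriented[y == 0])
    sens = 1.0 - np.searchsorted(pos_sorted, thr, side="right") / n_pos
    spec = np.searchsorted(neg_sorted, thr, side="right") / n_neg

    # trapezoidal AUC over (FPR, TPR): as the threshold decreases both
    # coordinates are non-decreasing, so reversed threshold order walks the
    # ROC staircase from (0,0) to (1,1); equals concordance with ties 1/2
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    # map thresholds back to the original score scale
    thresholds = thr if direction == HIGHER else -thr
    return RocCurve(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        direction=direction,
        score_median=float(np.median(scores)),
        warnings=warns,
    )


def _delong_variance(oriented_scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and variance via midrank structural components."""
    pos = oriented_scores[y == 1]
    neg = oriented_scores[y == 0]
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    rank_all = stats.rankdata(combined)  # midranks
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rank_all[:m] - rank_pos) / n        # per-positive components
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m  # per-negative components
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def auc_confidence_interval(
    scores: Sequence[float],
    labels: Sequence,
    direction: str = HIGHER,
    level: float = 0.95,
    method: str = "delong",
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
    positive_label=POSITIVE_LABEL,
) -> tuple[float, float]:
    """Confidence interval for the empirical AUC.

    ``method="delong"`` uses the DeLong variance estimate with a normal
    approximation truncated to [0, 1]; ``method="bootstrap"`` uses a
    stratified nonparametric percentile bootstrap. A zero-variance AUC
    (e.g. perfect separation) yields the degenerate interval [auc, auc]
    with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary_labels(labels, positive_label)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need at least 2 subjects per class for a CI")
    if not 0 <= level < 1:
        raise ValueError("level must be in [0, 1)")
    oriented = scores if direction == HIGHER else -scores
    auc, var = _delong_variance(oriented, y)
    if level == 0:
        return auc, auc
    if method == "delong":
        if var <= 0:
            warnings.warn("zero DeLong variance; degenerate AUC interval", stacklevel=2)
            return auc, auc
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(var)
        return float(max(0.0, auc - half)), float(min(1.0, auc + half))
    if method == "bootstrap":
        rng = np.random.default_rng(rng)
        pos = oriented[y == 1]
        neg = oriented[y == 0]
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            bp = rng.choice(pos, size=len(pos), replace=True)
            bn = rng.choice(neg, size=len(neg), replace=True)
            aucs[b] = stats.mannwhitneyu(bp, bn).statistic / (len(pos) * len(neg))
        lo, hi = np.quantile(aucs, [0.5 - level / 2.0, 0.5 + level / 2.0])
        return float(lo), float(hi)
    raise ValueError(f"unknown CI method {method!r}")


def youden_optimal_cutoff(curve: RocCurve) -> CutoffResult:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken by higher sensitivity, then by the cutoff closest to
    the score median (the least extreme choice).
    """
    j = curve.sensitivities + curve.specificities - 1.0
    best = np.flatnonzero(np.isclose(j, j.max(), rtol=0, atol=1e-12))
    if len(best) > 1:
        sens_best = curve.sensitivities[best]
        best = best[np.isclose(sens_best, sens_best.max(), rtol=0, atol=1e-12)]
    if len(best) > 1:
        dist = np.abs(curve.thresholds[best] - curve.score_median)
        best = best[[int(np.argmin(dist))]]
    i = int(best[0])
    return CutoffResult(
        cutoff=float(curve.thresholds[i]),
        sensitivity=float(curve.sensitivities[i]),
        specificity=float(curve.specificities[i]),
        youden_j=float(j[i]),
    )


def fit_logistic_combiner(
    markers: Sequence[Sequence[float]] | np.ndarray,
    labels: Sequence,
    *,
    max_iter: int = 100,
    tol: float = 1e-8,
    ridge: float = 0.0,
    positive_label=POSITIVE_LABEL,
) -> CombinedMarker:
    """Fuse markers into one score via logistic-regression probability.

    Maximum-likelihood logit fit by iteratively reweighted least squares.
    Complete/quasi-separation is detected from a diverging coefficient norm
    and flagged, not penalized: the fused ROC depends only on the ordering
    of the predicted probabilities. ``ridge`` adds an optional L2 stabilizer
    on the slopes.
    """
    X = np.atleast_2d(np.asarray(markers, dtype=float))
    if X.shape[0] != len(labels) and X.shape[1] == len(labels):
        X = X.T
    n = X.shape[0]
    y = _as_binary_labels(labels, positive_label).astype(float)
    if len(y) != n:
        raise ValueError("markers and labels must have equal length")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary")
    if np.isnan(X).any():
        raise ValueError("missing marker values are not allowed")

    # drop constant columns (intercept-only fit with a warning)
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn("constant marker dropped; fit includes intercept only for it", stacklevel=2)
    Xk = X[:, keep]
    # standardize for IRLS stability; coefficients mapped back afterwards
    mu, sd = Xk.mean(axis=0), Xk.std(axis=0)
    Z = np.column_stack([np.ones(n), (Xk - mu) / sd]) if Xk.shape[1] else np.ones((n, 1))
    k = Z.shape[1]
    beta = np.zeros(k)
    beta[0] = np.log(y.mean() / (1 - y.mean())) if 0 < y.mean() < 1 else 0.0

    def loglik(b: np.ndarray) -> float:
        eta = Z @ b
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    ll_old = loglik(beta)
    converged = False
    separation = False
    n_iter = 0
    penalty = np.zeros(k)
    penalty[1:] = ridge
    for n_iter in range(1, max_iter + 1):
        eta = Z @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1 - p), 1e-12, None)
        # IRLS normal equations with optional ridge on slopes
        H = (Z * w[:, None]).T @ Z + np.diag(penalty)
        g = Z.T @ (y - p) - penalty * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            # collinear markers: move along the identifiable directions
            step = np.linalg.pinv(H) @ g
        beta = beta + step
        ll_new = loglik(beta)
        if np.linalg.norm(beta[1:], ord=np.inf) > 30.0 or ll_new > -1e-6:
            # a near-zero log-likelihood or a diverging standardized slope
            # means the classes are (quasi-)separated
            separation = True
        if abs(ll_new - ll_old) < tol:
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    if separation:
        logger.warning("complete or quasi-separation detected in logistic fusion")

    probs = 1.0 / (1.0 + np.exp(-(Z @ beta)))
    # map standardized coefficients back to the raw marker scale
    coefs = np.zeros(1 + X.shape[1])
    if Xk.shape[1]:
        slopes = beta[1:] / sd
        coefs[0] = beta[0] - float((beta[1:] * mu / sd).sum())
        coefs[1:][keep] = slopes
    else:
        coefs[0] = beta[0]
    return CombinedMarker(
        coefficients=coefs,
        probabilities=probs,
        separation_flag=separation,
        converged=converged,
        n_iter=n_iter,
    )


DEFAULT_PANEL: list[tuple[str, list[str], str]] = [
    ("MoCA-K", ["moca_k"], LOWER),
    ("HT", ["mean_ht_ms"], HIGHER),
    ("FT", ["mean_ft_ms"], HIGHER),
    ("MoCA-K+HT", ["moca_k", "mean_ht_ms"], HIGHER),
    ("MoCA-K+FT", ["moca_k", "mean_ft_ms"], HIGHER),
]


def evaluate_marker_panel(
    records: pd.DataFrame,
    panel: Sequence[tuple[str, Sequence[str], str]] | None = None,
    *,
    group_col: str = "group",
    positive_label: str = POSITIVE_LABEL,
    ci_method: str = "delong",
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Evaluate each marker (or fused marker pair) of a panel.

    Multi-column entries are fused into a single predicted probability by
    logistic regression before ROC analysis. Returns one row per panel
    entry with AUC, its CI, the Youden-optimal cutoff and the
    sensitivity/specificity attained there.
    """
    panel = list(panel) if panel is not None else DEFAULT_PANEL
    labels = records[group_col].to_numpy()
    rows = []
    for name, cols, direction in panel:
        cols = list(cols)
        sub = records[cols].to_numpy(dtype=float)
        if np.isnan(sub).any():
            raise ValueError(f"missing values in marker columns {cols}")
        separation = None
        if len(cols) == 1:
            scores = sub[:, 0]
        else:
            fused = fit_logistic_combiner(sub, labels, positive_label=positive_label)
            scores = fused.probabilities
            separation = fused.separation_flag
            direction = HIGHER
        curve = empirical_roc(scores, labels, direction, positive_label=positive_label)
        lo, hi = auc_confidence_interval(
            scores, labels, direction, level=level, method=ci_method, rng=rng,
            positive_label=positive_label,
        )
        cut = youden_optimal_cutoff(curve)
        rows.append(
            {
                "marker": name,
                "direction": direction,
                "auc": curve.auc,
                "auc_ci_low": lo,
                "auc_ci_high": hi,
                "cutoff": cut.cutoff,
                "sensitivity": cut.sensitivity,
                "specificity": cut.specificity,
                "youden_j": cut.youden_j,
                "separation_flag": separation,
            }
        )
    return pd.DataFrame(rows)


def plot_roc(curve: RocCurve, path, title: str = "ROC") -> None:
    """Write a ROC curve plot to ``path`` (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    fpr = 1.0 - curve.specificities
    order = np.argsort(fpr)
    ax.plot(fpr[order], curve.sensitivities[order], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{title} (AUC={curve.auc:.3f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
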
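"""Weighted empirical ROC curves and optimal diagnostic cut-points.

The score (HOMA-IR by default) is oriented so that higher values indicate
disease: a subject tests positive when score >= threshold. Candidate
thresholds are the midpoints between consecutive distinct observed scores
plus -inf/+inf sentinels, which enumerate every achievable classification.
At each threshold, sensitivity is the weighted fraction of cases at or
above it and specificity the weighted fraction of non-cases below it.

AUC is the trapezoidal area in (1 - specificity, sensitivity) space, which
for this construction equals the weighted concordance probability
P(score_case > score_control) + 1/2 P(tie). Confidence intervals come from
a seeded percentile bootstrap over subjects (each resampled subject keeps
its survey weight). Cut-points are selected by maximizing the Youden index
J = sensitivity + specificity - 1 or minimizing the squared distance to the
perfect corner (0, 1) of the ROC plot, (1-se)^2 + (1-sp)^2; criterion
plateaus are resolved to the lowest threshold and reported as an interval.

Because some literature prints the Youden criterion on a 1 + J scale
(sensitivity + specificity, in 0..2), both scales are carried in results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateLabelsError,
    InvalidArgumentError,
    NoCutpointError,
)
from .survey_weighting import weighted_percentile

logger = logging.getLogger(__name__)

#: Criterion values within this tolerance of the optimum form the reported
#: plateau interval.
PLATEAU_TOL = 1e-12

#: Default percentile grid for threshold tables, percent.
DEFAULT_PERCENTILE_GRID = tuple(range(50, 100, 5))


@dataclass(frozen=True)
class RocCurve:
    """Weighted empirical ROC curve over ascending candidate thresholds.

    ``thresholds`` starts at -inf (sensitivity 1, specificity 0) and ends at
    +inf (sensitivity 0, specificity 1). ``score_cdf`` is the weighted
    fraction of *all* subjects with score strictly below each threshold,
    used to express a chosen threshold as a percentile of the score
    distribution.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    pos_total: float
    neg_total: float
    score_cdf: np.ndarray


@dataclass(frozen=True)
class CutpointResult:
    """A selected cut-off and its operating characteristics."""

    threshold: float
    criterion: str  # 'youden' or 'distance'
    sensitivity: float
    specificity: float
    youden_j: float
    youden_plus_one: float
    distance_sq: float
    plr: float
    percentile_of_threshold: float
    #: Threshold interval over which the criterion is within tolerance of
    #: its optimum (plateau); the reported threshold is its lower edge.
    plateau: tuple[float, float] = field(default=(np.nan, np.nan))


def _scores_labels_weights(scores, labels, weights):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if weights is None:
        w = np.ones_like(s)
    else:
        w = np.asarray(weights, dtype=float)
    if not (s.ndim == 1 and s.shape == y.shape == w.shape):
        raise InvalidArgumentError("scores, labels, weights must be 1-D, equal length")
    if len(s) == 0 or not np.isfinite(s).all():
        raise InvalidArgumentError("scores must be non-empty and finite")
    if not (w > 0).all():
        raise InvalidArgumentError("weights must be strictly positive")
    return s, y, w


def empirical_roc(scores, labels, weights=None) -> RocCurve:
    """Build the weighted empirical ROC curve (positivity: score >= threshold).

    Raises
    ------
    DegenerateLabelsError
        If only one class carries positive weight.
    """
    s, y, w = _scores_labels_weights(scores, labels, weights)
    pos_total = float(w[y].sum())
    neg_total = float(w[~y].sum())
    if pos_total == 0 or neg_total == 0:
        raise DegenerateLabelsError("both outcome classes must be present")

    order = np.argsort(s, kind="stable")
    ss, ys, ws = s[order], y[order], w[order]
    uniq, start = np.unique(ss, return_index=True)
    pos_w = np.add.reduceat(np.where(ys, ws, 0.0), start)
    neg_w = np.add.reduceat(np.where(ys, 0.0, ws), start)
    tot_w = pos_w + neg_w

    # thresholds: -inf, midpoints between consecutive distinct scores, +inf
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    # at threshold index i (i distinct values strictly below it):
    # sens = weight of positives at/above / pos_total
    cum_pos_below = np.concatenate(([0.0], np.cumsum(pos_w)))
    cum_neg_below = np.concatenate(([0.0], np.cumsum(neg_w)))
    cum_all_below = np.concatenate(([0.0], np.cumsum(tot_w)))
    # clip: cumulative float error can push proportions a few ulp outside [0,1]
    sens = np.clip((pos_total - cum_pos_below) / pos_total, 0.0, 1.0)
    spec = np.clip(cum_neg_below / neg_total, 0.0, 1.0)
    cdf = np.clip(cum_all_below / (pos_total + neg_total), 0.0, 1.0)
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        pos_total=pos_total,
        neg_total=neg_total,
        score_cdf=cdf,
    )


def auc(roc: RocCurve) -> float:
    """Trapezoidal area under the ROC curve, in [0, 1]."""
    fpr = 1.0 - roc.specificity
    # thresholds ascend => fpr descends; integrate over ascending fpr
    return float(np.trapezoid(roc.sensitivity[::-1], fpr[::-1]))


def youden(sensitivity: float, specificity: float) -> tuple[float, float]:
    """Youden index J = sens + spec - 1, and the 1 + J scale some reports print."""
    _check_unit_interval(sensitivity, specificity)
    j = sensitivity + specificity - 1.0
    return j, j + 1.0


def distance_sq(sensitivity: float, specificity: float) -> float:
    """Squared distance from the ROC point to the perfect corner (0, 1)."""
    _check_unit_interval(sensitivity, specificity)
    return (1.0 - sensitivity) ** 2 + (1.0 - specificity) ** 2


def plr(sensitivity: float, specificity: float) -> float:
    """Positive likelihood ratio sens/(1 - spec); +inf at specificity 1."""
    _check_unit_interval(sensitivity, specificity)
    if specificity == 1.0:
        return np.inf
    return sensitivity / (1.0 - specificity)


def _check_unit_interval(*vals):
    for v in vals:
        if not (0.0 <= v <= 1.0):
            raise InvalidArgumentError(f"proportion outside [0, 1]: {v}")


def optimal_cutpoint(roc: RocCurve, method: str = "youden") -> CutpointResult:
    """Select the optimal threshold by the Youden or distance criterion.

    Ties (criterion within 1e-12 of the optimum) are broken toward the
    lowest threshold; the full plateau interval is reported alongside.

    Raises
    ------
    NoCutpointError
        If the curve has no finite candidate threshold (all scores tied).
    """
    if method not in ("youden", "distance"):
        raise InvalidArgumentError(f"unknown cut-point method {method!r}")
    finite = np.isfinite(roc.thresholds)
    if not finite.any():
        raise NoCutpointError("degenerate ROC curve: no finite threshold")
    thr = roc.thresholds[finite]
    se = roc.sensitivity[finite]
    sp = roc.specificity[finite]
    if method == "youden":
        crit = se + sp - 1.0
        best = crit.max()
        on_plateau = crit >= best - PLATEAU_TOL
    else:
        crit = (1.0 - se) ** 2 + (1.0 - sp) ** 2
        best = crit.min()
        on_plateau = crit <= best + PLATEAU_TOL
    idx = int(np.flatnonzero(on_plateau)[0])  # lowest threshold on plateau
    j, j_plus_one = youden(float(se[idx]), float(sp[idx]))
    return CutpointResult(
        threshold=float(thr[idx]),
        criterion=method,
        sensitivity=float(se[idx]),
        specificity=float(sp[idx]),
        youden_j=j,
        youden_plus_one=j_plus_one,
        distance_sq=distance_sq(float(se[idx]), float(sp[idx])),
        plr=plr(float(se[idx]), float(sp[idx])),
        percentile_of_threshold=float(100.0 * roc.score_cdf[finite][idx]),
        plateau=(float(thr[on_plateau].min()), float(thr[on_plateau].max())),
    )


def sens_spec_at(scores, labels, weights, threshold: float) -> tuple[float, float]:
    """Weighted sensitivity and specificity of the rule score >= threshold."""
    s, y, w = _scores_labels_weights(scores, labels, weights)
    pos_total = float(w[y].sum())
    neg_total = float(w[~y].sum())
    if pos_total == 0 or neg_total == 0:
        raise DegenerateLabelsError("both outcome classes must be present")
    test_pos = s >= threshold
    sens = float(w[y & test_pos].sum() / pos_total)
    spec = float(w[~y & ~test_pos].sum() / neg_total)
    return sens, spec


def percentile_table(
    scores, labels, weights=None, p_grid=DEFAULT_PERCENTILE_GRID
) -> pd.DataFrame:
    """Score thresholds at distribution percentiles with their test accuracy.

    One row per grid percentile (default 50, 55, ..., 95): the weighted
    score percentile as threshold, then sensitivity, specificity and PLR of
    score >= threshold.
    """
    s, y, w = _scores_labels_weights(scores, labels, weights)
    grid = np.asarray(list(p_grid), dtype=float)
    thresholds = weighted_percentile(s, w, grid)
    rows = []
    for p, t in zip(grid, np.atleast_1d(thresholds)):
        sens, spec = sens_spec_at(s, y, w, float(t))
        rows.append(
            {
                "percentile": p,
                "threshold": float(t),
                "sensitivity": sens,
                "specificity": spec,
                "plr": plr(sens, spec),
            }
        )
    return pd.DataFrame(rows)


def auc_bootstrap_ci(
    scores,
    labels,
    weights=None,
    n_boot: int = 2000,
    level: float = 0.95,
    seed=None,
) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval for the weighted AUC.

    Subjects are resampled with replacement (each drawn subject keeps its
    survey weight); replicates that lose an entire outcome class are
    redrawn and counted in the log. Deterministic given *seed* (an int or a
    ``numpy.random.Generator``).
    """
    if n_boot < 100:
        raise InvalidArgumentError("n_boot must be at least 100")
    if not 0.0 < level < 1.0:
        raise InvalidArgumentError("level must be in (0, 1)")
    s, y, w = _scores_labels_weights(scores, labels, weights)
    if not (y.any() and (~y).any()):
        raise DegenerateLabelsError("both outcome classes must be present")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(s)

    # Pre-sort once; a bootstrap replicate is a multinomial reweighting of
    # the sorted sample, so each replicate AUC is a cumulative-sum pass.
    order = np.argsort(s, kind="stable")
    ss, ys, ws = s[order], y[order], w[order]
    _, start = np.unique(ss, return_index=True)
    pvals = np.full(n, 1.0 / n)

    aucs = np.empty(n_boot)
    filled = 0
    redraws = 0
    max_block = max(1, int(2e7) // n)
    while filled < n_boot:
        b = min(n_boot - filled, max_block)
        counts = rng.multinomial(n, pvals, size=b)
        w_rep = counts * ws  # (b, n)
        pos_w = np.add.reduceat(np.where(ys, w_rep, 0.0), start, axis=1)
        neg_w = np.add.reduceat(np.where(ys, 0.0, w_rep), start, axis=1)
        pos_tot = pos_w.sum(axis=1)
        neg_tot = neg_w.sum(axis=1)
        ok = (pos_tot > 0) & (neg_tot > 0)
        redraws += int((~ok).sum())
        cum_neg_below = np.cumsum(neg_w, axis=1) - neg_w
        conc = (pos_w * (cum_neg_below + 0.5 * neg_w)).sum(axis=1)
        vals = conc[ok] / (pos_tot[ok] * neg_tot[ok])
        take = min(len(vals), n_boot - filled)
        aucs[filled : filled + take] = vals[:take]
        filled += take
    if redraws:
        logger.info("auc_bootstrap_ci: redrew %d degenerate replicates", redraws)
    alpha = 1.0 - level
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)
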
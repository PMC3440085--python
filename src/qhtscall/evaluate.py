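"""Operating characteristics, ROC/AUC, and single-stage comparators.

Performance of a call procedure on a labeled simulated data set is
summarized by the empirical type I error rate (fraction of true nulls
called active), power (fraction of true actives called active), and the
share of active calls made in stage 1.  ``INCONCLUSIVE`` calls count as
not active throughout.  ROC curves sweep the significance level alpha,
the only continuous decision threshold in the algorithm; the fits are
computed once and re-read at each alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classify import (
    CallRecord,
    ClassifierConfig,
    call_at_alpha,
    classify_profiles,
    is_active_call,
    neighbor_weights,
    weighted_t_test,
)
from .fitting import fit_constant, fit_hill_nls, fit_hill_wnls, overall_f_test
from .hill import Profile
from .simulate import SimDataset

__all__ = [
    "OperatingCharacteristics",
    "RocCurve",
    "operating_characteristics",
    "roc_curve",
    "auc_trapezoid",
    "comparator_call",
    "COMPARATOR_METHODS",
]

COMPARATOR_METHODS = ("nls_f", "wnls_f", "robust_linreg", "student_t", "weighted_t")


@dataclass
class OperatingCharacteristics:
    """Empirical error rates of a call procedure on labeled data.

    ``active1_share`` is ACTIVE[+/-1] / (ACTIVE[+/-1] + ACTIVE[+/-2]) x 100,
    computed over the true actives when present (matching how operating
    tables report it next to power), over all substances otherwise; NaN
    when no active calls were made.
    """

    type1: float
    power: float
    active1_share: float
    n_null: int
    n_active: int


def _share_active1(calls: list[str]) -> float:
    a1 = sum(c in ("ACTIVE[1]", "ACTIVE[-1]") for c in calls)
    a2 = sum(c in ("ACTIVE[2]", "ACTIVE[-2]") for c in calls)
    if a1 + a2 == 0:
        return math.nan
    return 100.0 * a1 / (a1 + a2)


def operating_characteristics(calls, truth_labels) -> OperatingCharacteristics:
    """Type I error, power and stage-1 share from aligned calls and labels.

    ``calls`` may be :class:`CallRecord` objects or bare call strings;
    ``truth_labels`` holds "active"/"null" per substance.
    """
    labels = np.asarray(truth_labels)
    call_strs = [c.call if isinstance(c, CallRecord) else str(c) for c in calls]
    if len(call_strs) != labels.size:
        raise ValueError("calls and truth labels must be aligned")
    is_act = np.array([is_active_call(c) for c in call_strs])
    null_mask = labels == "null"
    active_mask = labels == "active"
    n_null = int(null_mask.sum())
    n_active = int(active_mask.sum())
    type1 = float(is_act[null_mask].mean()) if n_null else math.nan
    power = float(is_act[active_mask].mean()) if n_active else math.nan
    pool = (
        [c for c, a in zip(call_strs, active_mask) if a] if n_active else call_strs
    )
    return OperatingCharacteristics(
        type1=type1,
        power=power,
        active1_share=_share_active1(pool),
        n_null=n_null,
        n_active=n_active,
    )


@dataclass
class RocCurve:
    """(false positive rate, sensitivity) pairs along an alpha sweep."""

    points: np.ndarray  # shape (k, 2), fpr-sorted, anchored at (0,0),(1,1)
    auc: float
    alphas: np.ndarray


def auc_trapezoid(points) -> float:
    """Trapezoid-rule area under (x, y) points with nondecreasing x."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need at least two (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(np.diff(x) < 0):
        raise ValueError("x coordinates must be nondecreasing")
    return float(np.trapezoid(y, x))


def default_alpha_grid(n: int = 30) -> np.ndarray:
    """Log-spaced significance levels from 1e-6 to 0.999."""
    return np.concatenate([np.geomspace(1e-6, 0.9, n - 1), [0.999]])


def roc_curve(
    dataset: SimDataset,
    alpha_grid=None,
    config: ClassifierConfig | None = None,
) -> RocCurve:
    """ROC over a sweep of the significance level.

    The data set is classified once; each record's stored p-values are
    then re-read at every alpha in the grid.  (0,0) and (1,1) anchors
    are appended before the trapezoid integration.
    """
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alphas = np.asarray(alpha_grid, dtype=float)
    if np.any((alphas <= 0) | (alphas >= 1)):
        raise ValueError("alpha grid must lie strictly inside (0, 1)")
    alphas = np.sort(alphas)
    if config is None:
        config = ClassifierConfig()
    base = ClassifierConfig(
        alpha=float(alphas[-1]),
        detlim=config.detlim,
        run_outlier_detection=config.run_outlier_detection,
        always_fit=config.always_fit,
    )
    records = classify_profiles(dataset.profiles, base)
    labels = dataset.labels
    pts = []
    for a in alphas:
        calls = [call_at_alpha(r, float(a)) for r in records]
        oc = operating_characteristics(calls, labels)
        pts.append((oc.type1, oc.power))
    pts = np.array(pts, dtype=float)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    full = np.vstack([[0.0, 0.0], pts, [1.0, 1.0]])
    return RocCurve(points=full, auc=auc_trapezoid(full), alphas=alphas)


def _one_sided_f(profile: Profile, weighted: bool, alpha: float) -> tuple[bool, int]:
    if profile.n_used <= 4:
        return False, 0
    if weighted:
        w = neighbor_weights(profile)
        fit = fit_hill_wnls(profile, w)
        ft = overall_f_test(fit, fit_constant(profile, w))
    else:
        fit = fit_hill_nls(profile)
        ft = overall_f_test(fit, fit_constant(profile))
    return bool(ft.rejects(alpha)), fit.direction


def comparator_call(
    profile: Profile, method: str, config: ClassifierConfig | None = None
) -> tuple[bool, int]:
    """Single-stage comparator strategies.

    Returns ``(active, direction)`` with direction +1 (increasing), -1
    (decreasing) or 0.  Methods:

    - ``nls_f`` / ``wnls_f``: overall F-test of the Hill fit vs. a flat
      line, direction from the fitted trend;
    - ``robust_linreg``: Huber M-estimated regression of response on
      log10 concentration, active iff the slope differs from zero;
    - ``student_t`` / ``weighted_t``: one-sided mean test against the
      positive (greater) and negative (less) detection limits.
    """
    if config is None:
        config = ClassifierConfig()
    alpha = config.alpha
    _, R = profile.used()
    if method in ("nls_f", "wnls_f"):
        rej, direction = _one_sided_f(profile, method == "wnls_f", alpha)
        return (rej and direction != 0, direction if rej else 0)
    if method == "robust_linreg":
        import statsmodels.api as sm

        C, R = profile.used()
        X = sm.add_constant(np.log10(C))
        res = sm.RLM(R, X, M=sm.robust.norms.HuberT(t=1.345)).fit()
        slope, se = res.params[1], res.bse[1]
        if se == 0 or not np.isfinite(se):
            return False, 0
        p = 2.0 * stats.norm.sf(abs(slope / se))
        return (p < alpha, int(np.sign(slope)) if p < alpha else 0)
    if method == "student_t":
        if R.size < 2:
            return False, 0
        p_pos = stats.ttest_1samp(R, config.detlim.pos, alternative="greater").pvalue
        p_neg = stats.ttest_1samp(R, config.detlim.neg, alternative="less").pvalue
    elif method == "weighted_t":
        w = neighbor_weights(profile)
        p_pos = weighted_t_test(R, w, config.detlim.pos, "greater")
        p_neg = weighted_t_test(R, w, config.detlim.neg, "less")
    else:
        raise ValueError(f"unknown comparator method {method!r}")
    if p_pos < alpha and (p_neg >= alpha or R.mean() >= 0):
        return True, 1
    if p_neg < alpha:
        return True, -1
    return False, 0
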
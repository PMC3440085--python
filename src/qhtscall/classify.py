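"""Three-stage activity calls for qHTS concentration-response profiles.

A substance is pushed through three stages until a call is made:

* **Stage 1** (robust concentration-response): the response exceeds the
  detection limit, the Hill model beats the flat line in *both* the
  unweighted (NLS) and neighbor-weighted (WNLS) F-tests, and both fits
  agree on the direction -> ``ACTIVE[1]`` / ``ACTIVE[-1]``.
* **Stage 2** (potent responder): the weighted mean response differs
  significantly from the detection limit by a one-sided weighted t-test,
  indicating activity already at the lowest tested concentration ->
  ``ACTIVE[2]`` / ``ACTIVE[-2]``.
* **Stage 3** (nonrobust response): the detection limit is exceeded and
  exactly the statistical support of stage 1 holds for *at least one* of
  the two fits -> ``INCONCLUSIVE[3]`` / ``INCONCLUSIVE[-3]``.

Anything else is ``INACTIVE``.  Stage order matters: the first stage
that fires terminates the walk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .fitting import (
    FitResult,
    FTestResult,
    Weights,
    detect_outliers,
    fit_constant,
    fit_hill_nls,
    fit_hill_wnls,
    neighbor_weights,
    overall_f_test,
)
from .hill import Profile

__all__ = [
    "CALL_LABELS",
    "DetectionLimits",
    "ClassifierConfig",
    "CallRecord",
    "detection_limits_from_controls",
    "weighted_t_test",
    "stage1",
    "stage2",
    "stage3",
    "classify",
    "classify_profiles",
    "call_at_alpha",
    "is_active_call",
    "ThreeStageClassifier",
]

CALL_LABELS = (
    "ACTIVE[1]",
    "ACTIVE[-1]",
    "ACTIVE[2]",
    "ACTIVE[-2]",
    "INCONCLUSIVE[3]",
    "INCONCLUSIVE[-3]",
    "INACTIVE",
)


def is_active_call(call: str) -> bool:
    """ACTIVE[+/-1] and ACTIVE[+/-2] count as active; inconclusive and
    inactive calls both count as not active."""
    return call.startswith("ACTIVE")


@dataclass(frozen=True)
class DetectionLimits:
    """Response band within which the normalized signal is not reliably
    distinguishable from the negative control (percent of positive
    control)."""

    pos: float = 25.0
    neg: float = -25.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pos) and np.isfinite(self.neg)):
            raise ValueError("detection limits must be finite")
        if self.neg > self.pos:
            raise ValueError("negative limit must not exceed positive limit")


@dataclass(frozen=True)
class ClassifierConfig:
    alpha: float = 0.05
    detlim: DetectionLimits = field(default_factory=DetectionLimits)
    run_outlier_detection: bool = True
    #: force the Hill fits even when they provably cannot influence the
    #: call (record completeness at the cost of speed).
    always_fit: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie strictly between 0 and 1")


def detection_limits_from_controls(neg_control_responses) -> DetectionLimits:
    """Detection limits as mean +/- 3 SD of negative-control responses."""
    x = np.asarray(neg_control_responses, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 negative-control values")
    m = float(x.mean())
    sd = float(x.std(ddof=1))
    return DetectionLimits(pos=m + 3.0 * sd, neg=m - 3.0 * sd)


def weighted_t_test(
    responses, weights: Weights, threshold: float, direction: str
) -> float:
    """One-sided weighted one-sample t-test against a response threshold.

    The statistic is ``t = (m_w - threshold) / (s_w / sqrt(n))`` with the
    weighted mean ``m_w = sum(w R)/sum(w)`` and the weighted sample
    variance ``s_w^2 = sum(w (R - m_w)^2)/(sum(w) - 1)`` (weights are
    normalized to ``sum(w) = n``), referred to a t distribution on n - 1
    degrees of freedom.  With equal weights this is exactly the Student
    one-sided one-sample t-test.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    R = np.asarray(responses, dtype=float)
    w = np.asarray(weights.w, dtype=float)
    n = R.size
    if n < 2:
        raise ValueError("weighted t-test needs at least 2 points")
    if w.size != n:
        raise ValueError("weights length must match responses")
    sw = w.sum()
    m = float(np.dot(w, R) / sw)
    s2 = float(np.dot(w, (R - m) ** 2) / (sw - 1.0))
    if s2 <= 0.0:
        if m == threshold:
            return 1.0
        matches = m > threshold if direction == "greater" else m < threshold
        return 0.0 if matches else 1.0
    t = (m - threshold) / math.sqrt(s2 / n)
    if direction == "greater":
        return float(stats.t.sf(t, n - 1))
    return float(stats.t.cdf(t, n - 1))


@dataclass
class CallRecord:
    """Final call plus every stage-level statistic for one substance."""

    substance_id: str
    call: str
    stage: int | None
    p_f_nls: float
    p_f_wnls: float
    p_t_weighted_pos: float
    p_t_weighted_neg: float
    fit_nls: FitResult | None
    fit_wnls: FitResult | None
    n_used: int
    outliers_removed: tuple[int, ...]
    max_response: float
    min_response: float
    weighted_mean: float
    dir_nls: int
    dir_wnls: int
    f_defined_nls: bool
    f_defined_wnls: bool
    detlim: DetectionLimits
    flags: tuple[str, ...] = ()


def _f_rejects(p: float, defined: bool, alpha: float) -> bool:
    return defined and p < alpha


def _decide(rec: CallRecord, alpha: float) -> tuple[str, int | None]:
    """Walk the decision tree using the statistics stored in ``rec``.

    Separated from :func:`classify` so the same fits can be re-read at a
    different significance level (ROC sweeps).
    """
    dl = rec.detlim
    nls_rej = _f_rejects(rec.p_f_nls, rec.f_defined_nls, alpha)
    wnls_rej = _f_rejects(rec.p_f_wnls, rec.f_defined_wnls, alpha)

    # Stage 1: robust concentration-response (both fits significant).
    up = (
        rec.max_response > dl.pos
        and nls_rej
        and wnls_rej
        and rec.dir_nls > 0
        and rec.dir_wnls > 0
    )
    down = (
        rec.min_response < dl.neg
        and nls_rej
        and wnls_rej
        and rec.dir_nls < 0
        and rec.dir_wnls < 0
    )
    if up and down:  # unreachable with a single fitted direction; kept for safety
        up = (rec.max_response - dl.pos) >= (dl.neg - rec.min_response)
        down = not up
    if up:
        return "ACTIVE[1]", 1
    if down:
        return "ACTIVE[-1]", 1

    # Stage 2: potent responder at the lowest tested concentration.
    up = rec.p_t_weighted_pos < alpha
    down = rec.p_t_weighted_neg < alpha
    if up and down:  # degenerate (requires pos <= mean <= neg); sign decides
        up = rec.weighted_mean >= 0.0
        down = not up
    if up:
        return "ACTIVE[2]", 2
    if down:
        return "ACTIVE[-2]", 2

    # Stage 3: significant under exactly one weighting (nonrobust).
    up = rec.max_response > dl.pos and (
        (nls_rej and rec.dir_nls > 0) or (wnls_rej and rec.dir_wnls > 0)
    )
    down = rec.min_response < dl.neg and (
        (nls_rej and rec.dir_nls < 0) or (wnls_rej and rec.dir_wnls < 0)
    )
    if up and down:
        up = (rec.max_response - dl.pos) >= (dl.neg - rec.min_response)
        down = not up
    if up:
        return "INCONCLUSIVE[3]", 3
    if down:
        return "INCONCLUSIVE[-3]", 3
    return "INACTIVE", None


def stage1(
    profile: Profile,
    fit_nls: FitResult,
    fit_wnls: FitResult,
    ftest_nls: FTestResult,
    ftest_wnls: FTestResult,
    config: ClassifierConfig,
) -> str | None:
    """Stage-1 call (``ACTIVE[+/-1]``) or ``None`` if not called."""
    _, R = profile.used()
    rec = _summary_record(profile, R, None, fit_nls, fit_wnls, ftest_nls, ftest_wnls, config)
    call, stage = _decide(rec, config.alpha)
    return call if stage == 1 else None


def stage2(profile: Profile, weights: Weights, config: ClassifierConfig) -> str | None:
    """Stage-2 call (``ACTIVE[+/-2]``) or ``None``; assumes stage 1 did
    not fire."""
    _, R = profile.used()
    p_pos = weighted_t_test(R, weights, config.detlim.pos, "greater")
    p_neg = weighted_t_test(R, weights, config.detlim.neg, "less")
    wm = float(np.dot(weights.w, R) / np.sum(weights.w))
    up = p_pos < config.alpha
    down = p_neg < config.alpha
    if up and down:
        up = wm >= 0.0
        down = not up
    if up:
        return "ACTIVE[2]"
    if down:
        return "ACTIVE[-2]"
    return None


def stage3(
    profile: Profile,
    fit_nls: FitResult,
    fit_wnls: FitResult,
    ftest_nls: FTestResult,
    ftest_wnls: FTestResult,
    config: ClassifierConfig,
) -> str:
    """Stage-3 call: ``INCONCLUSIVE[+/-3]`` or ``INACTIVE``; assumes
    stages 1 and 2 did not fire."""
    _, R = profile.used()
    rec = _summary_record(profile, R, None, fit_nls, fit_wnls, ftest_nls, ftest_wnls, config)
    # suppress stages 1-2 by construction: stage 1 cannot fire again here
    # because callers only reach stage 3 when it did not; re-deciding is
    # still correct because _decide walks stages in order.
    call, stage = _decide(rec, config.alpha)
    if stage == 3:
        return call
    return "INACTIVE"


def _summary_record(
    profile: Profile,
    R: np.ndarray,
    weights: Weights | None,
    fit_nls: FitResult | None,
    fit_wnls: FitResult | None,
    ftest_nls: FTestResult | None,
    ftest_wnls: FTestResult | None,
    config: ClassifierConfig,
    outliers_removed: tuple[int, ...] = (),
    flags: tuple[str, ...] = (),
) -> CallRecord:
    if weights is None and R.size >= 2:
        weights = neighbor_weights(profile)
    if weights is not None:
        wm = float(np.dot(weights.w, R) / np.sum(weights.w))
        p_pos = weighted_t_test(R, weights, config.detlim.pos, "greater")
        p_neg = weighted_t_test(R, weights, config.detlim.neg, "less")
    else:
        wm = float(R.mean())
        p_pos = p_neg = math.nan
    return CallRecord(
        substance_id=profile.substance_id,
        call="",
        stage=None,
        p_f_nls=ftest_nls.p if ftest_nls is not None else math.nan,
        p_f_wnls=ftest_wnls.p if ftest_wnls is not None else math.nan,
        p_t_weighted_pos=p_pos,
        p_t_weighted_neg=p_neg,
        fit_nls=fit_nls,
        fit_wnls=fit_wnls,
        n_used=int(R.size),
        outliers_removed=outliers_removed,
        max_response=float(R.max()),
        min_response=float(R.min()),
        weighted_mean=wm,
        dir_nls=fit_nls.direction if fit_nls is not None else 0,
        dir_wnls=fit_wnls.direction if fit_wnls is not None else 0,
        f_defined_nls=bool(ftest_nls is not None and ftest_nls.defined),
        f_defined_wnls=bool(ftest_wnls is not None and ftest_wnls.defined),
        detlim=config.detlim,
        flags=flags,
    )


def classify(profile: Profile, config: ClassifierConfig | None = None) -> CallRecord:
    """Run the full three-stage algorithm on one profile.

    Outlier detection (when enabled) updates the point mask first; the
    neighbor weights, both Hill fits, both flat-line fits and both
    F-tests are then computed on the surviving points, and the stages
    are walked in order.  Profiles with fewer than 4 usable points are
    returned ``INACTIVE`` with an ``insufficient_points`` flag.

    The Hill fits are skipped when they provably cannot influence the
    call: with 4 usable points the F-test has zero residual degrees of
    freedom, and when no response leaves the detection-limit band the
    stage-1/3 response conditions already fail.  Set
    ``config.always_fit=True`` to force them.
    """
    if config is None:
        config = ClassifierConfig()
    mask = detect_outliers(profile) if config.run_outlier_detection else profile.included
    removed = tuple(int(i) for i in np.flatnonzero(profile.included & ~mask))
    work = profile.with_mask(mask) if removed else profile
    n_used = work.n_used
    flags: tuple[str, ...] = ()

    if n_used < 4:
        rec = _summary_record(
            work,
            work.used()[1],
            None if n_used < 2 else neighbor_weights(work),
            None,
            None,
            None,
            None,
            config,
            outliers_removed=removed,
            flags=("insufficient_points",),
        )
        rec.call, rec.stage = "INACTIVE", None
        return rec

    weights = neighbor_weights(work)
    _, R = work.used()
    exceed = (R.max() > config.detlim.pos) or (R.min() < config.detlim.neg)
    fit_n = fit_w = ft_n = ft_w = None
    if config.always_fit or (n_used > 4 and exceed):
        fit_n = fit_hill_nls(work)
        ft_n = overall_f_test(fit_n, fit_constant(work))
        fit_w = fit_hill_wnls(work, weights)
        ft_w = overall_f_test(fit_w, fit_constant(work, weights))
    rec = _summary_record(
        work, R, weights, fit_n, fit_w, ft_n, ft_w, config,
        outliers_removed=removed, flags=flags,
    )
    rec.call, rec.stage = _decide(rec, config.alpha)
    return rec


def classify_profiles(
    profiles, config: ClassifierConfig | None = None
) -> list[CallRecord]:
    """Classify a sequence of profiles (see :func:`classify`)."""
    if config is None:
        config = ClassifierConfig()
    return [classify(p, config) for p in profiles]


def call_at_alpha(rec: CallRecord, alpha: float) -> str:
    """Re-read a classified record at a different significance level.

    All fits and p-values are reused; only the rejection threshold
    changes.  Used for ROC sweeps.
    """
    call, _ = _decide(rec, alpha)
    return call


class ThreeStageClassifier(BaseEstimator, ClassifierMixin):
    """Estimator-style front end to the three-stage call algorithm.

    Parameters
    ----------
    alpha : float
        Significance level for every statistical test.
    pos_limit, neg_limit : float
        Default detection limits (% of positive control) used when no
        negative controls are supplied to :meth:`fit`.
    outlier_detection : bool
        Run two-step outlier removal before fitting.

    Examples
    --------
    >>> clf = ThreeStageClassifier().fit()
    >>> calls = clf.predict(profiles)          # doctest: +SKIP
    """

    def __init__(
        self,
        alpha: float = 0.05,
        pos_limit: float = 25.0,
        neg_limit: float = -25.0,
        outlier_detection: bool = True,
    ):
        self.alpha = alpha
        self.pos_limit = pos_limit
        self.neg_limit = neg_limit
        self.outlier_detection = outlier_detection

    def fit(self, X=None, y=None):
        """Set detection limits, from negative-control responses if given.

        ``X`` may be a 1-D vector of negative-control responses; the
        limits are then mean +/- 3 SD.  With ``X=None`` the configured
        ``pos_limit``/``neg_limit`` are used.
        """
        if X is None:
            self.detection_limits_ = DetectionLimits(self.pos_limit, self.neg_limit)
        else:
            self.detection_limits_ = detection_limits_from_controls(X)
        return self

    def _config(self) -> ClassifierConfig:
        detlim = getattr(
            self, "detection_limits_", DetectionLimits(self.pos_limit, self.neg_limit)
        )
        return ClassifierConfig(
            alpha=self.alpha,
            detlim=detlim,
            run_outlier_detection=self.outlier_detection,
        )

    def predict_records(self, X) -> list[CallRecord]:
        """Full :class:`CallRecord` per profile in ``X``."""
        return classify_profiles(X, self._config())

    def predict(self, X) -> np.ndarray:
        """Activity-call labels (one of ``CALL_LABELS``) per profile."""
        return np.array([r.call for r in self.predict_records(X)], dtype=object)
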
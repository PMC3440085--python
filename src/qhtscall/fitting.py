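"""Hill-model regression, neighbor weighting, outlier detection, F-test.

Two regression flavours are used throughout: unweighted nonlinear least
squares (NLS), and weighted nonlinear least squares (WNLS) in which each
point is weighted by how well it agrees with its concentration
neighbors.  Both are compared against a one-parameter flat-line fit with
an extra-sum-of-squares F-test; a profile with a real concentration-
response trend fits the four-parameter Hill model much better than a
horizontal line.

Fitting strategy
----------------
The Hill model is linear in ``(r0, rmax)`` once ``(ac50, slope)`` are
fixed.  We therefore scan a log-spaced grid of ``(ac50, slope)`` pairs,
solving the 2x2 weighted linear problem in closed form at each node, and
polish the best few candidates with a Levenberg-Marquardt run using the
analytic Jacobian, with the parameter box folded into a sigmoid change
of variables (a bounded trust-region solver is the fallback).  This is
a dense, deterministic multi-start: given the data it always visits the
same starts in the same order, so refits are reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .hill import HillParams, Profile

__all__ = [
    "Weights",
    "FitResult",
    "FTestResult",
    "neighbor_weights",
    "fit_hill_nls",
    "fit_hill_wnls",
    "fit_constant",
    "overall_f_test",
    "detect_outliers",
]

#: additive regularizer (in % response units) of the neighbor-disagreement
#: weight 1/(eps + d_i); keeps weights finite on perfectly flat stretches.
WEIGHT_EPS = 1.0

#: floor (in % response units) on the robust residual scale, so that
#: numerically clean profiles are never flagged.
OUTLIER_SCALE_FLOOR = 1.0

_SLOPE_MAX = 20.0
_SLOPE_MIN = 1e-2
_GRID_SLOPES = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0])
_N_AC50_GRID = 24
_N_POLISH = 3


@dataclass(frozen=True)
class Weights:
    """Per-point nonnegative weights, normalized so that sum(w) == n."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if np.any(~np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be finite and nonnegative")
        if abs(w.sum() - w.size) > 1e-8 * max(1, w.size):
            raise ValueError("weights must be normalized to sum to n")

    @classmethod
    def equal(cls, n: int) -> "Weights":
        return cls(np.ones(n, dtype=float))


@dataclass
class FitResult:
    """Outcome of one regression (Hill or flat-line, NLS or WNLS)."""

    model_kind: str  # "hill" | "constant"
    weighted: bool
    params: HillParams | float
    sse: float
    n_used: int
    n_params: int
    converged: bool
    weights: Weights | None = None
    outliers_removed: tuple[int, ...] = ()

    @property
    def df_resid(self) -> int:
        return self.n_used - self.n_params

    @property
    def direction(self) -> int:
        """Sign of the fitted trend: +1 activator, -1 inhibitor, 0 flat."""
        if isinstance(self.params, HillParams):
            return self.params.direction
        return 0


@dataclass
class FTestResult:
    """Extra-sum-of-squares F-test of the Hill fit vs. the flat line."""

    F: float
    df1: int
    df2: int
    p: float
    defined: bool = True

    def rejects(self, alpha: float) -> bool:
        return self.defined and self.p < alpha


def neighbor_weights(profile: Profile) -> Weights:
    """Down-weight points that disagree with their concentration neighbors.

    For each included point the local disagreement ``d_i`` is the mean
    absolute response difference to the adjacent included points; raw
    weights ``1/(eps + d_i)`` are normalized so their sum equals the
    effective sample size n.  A flat profile gets all-equal weights; an
    isolated spike gets the smallest weight in the profile.
    """
    _, R = profile.used()
    n = R.size
    if n < 2:
        raise ValueError("neighbor weights need at least 2 included points")
    diffs = np.abs(np.diff(R))
    d = np.empty(n, dtype=float)
    d[0] = diffs[0]
    d[-1] = diffs[-1]
    if n > 2:
        d[1:-1] = 0.5 * (diffs[:-1] + diffs[1:])
    raw = 1.0 / (WEIGHT_EPS + d)
    return Weights(n * raw / raw.sum())


def _param_bounds(C: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    span = max(float(R.max() - R.min()), 1.0)
    lo_r = float(R.min()) - 1.5 * span
    hi_r = float(R.max()) + 1.5 * span
    lo = np.array([lo_r, lo_r, float(C.min()) / 100.0, _SLOPE_MIN])
    hi = np.array([hi_r, hi_r, float(C.max()) * 100.0, _SLOPE_MAX])
    return lo, hi


def _grid_candidates(
    C: np.ndarray, R: np.ndarray, w: np.ndarray
) -> list[tuple[float, np.ndarray]]:
    """Closed-form (r0, rmax) solutions over an (ac50, slope) grid.

    Returns ``[(sse, [r0, rmax, ac50, slope]), ...]`` sorted by sse.
    """
    logC = np.log(C)
    ac50s = np.geomspace(C.min() / 50.0, C.max() * 50.0, _N_AC50_GRID)
    out: list[tuple[float, np.ndarray]] = []
    swr = float(np.sum(w * R))
    for s in _GRID_SLOPES:
        # f has shape (n_ac50, n_points)
        f = expit(s * (logC[None, :] - np.log(ac50s)[:, None]))
        wf = w[None, :] * f
        a11 = np.sum(w) - 2 * wf.sum(axis=1) + np.sum(wf * f, axis=1)  # sum w (1-f)^2
        a12 = wf.sum(axis=1) - np.sum(wf * f, axis=1)  # sum w f (1-f)
        a22 = np.sum(wf * f, axis=1)  # sum w f^2
        b1 = swr - np.sum(wf * R[None, :], axis=1)
        b2 = np.sum(wf * R[None, :], axis=1)
        det = a11 * a22 - a12 * a12
        ok = det > 1e-10 * max(1.0, float(np.sum(w)) ** 2)
        r0 = np.where(ok, (b1 * a22 - b2 * a12) / np.where(ok, det, 1.0), swr / np.sum(w))
        rmax = np.where(ok, (a11 * b2 - a12 * b1) / np.where(ok, det, 1.0), swr / np.sum(w))
        pred = r0[:, None] + (rmax - r0)[:, None] * f
        sse = np.sum(w[None, :] * (R[None, :] - pred) ** 2, axis=1)
        for j in range(ac50s.size):
            out.append((float(sse[j]), np.array([r0[j], rmax[j], ac50s[j], s])))
    out.sort(key=lambda t: (t[0], t[1][3]))
    return out


def _polish(
    C: np.ndarray,
    R: np.ndarray,
    w: np.ndarray,
    start: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, float, bool]:
    sw = np.sqrt(w)
    logC = np.log(C)
    lo, hi = bounds
    x0 = np.clip(start, lo + 1e-12 * np.abs(lo), hi - 1e-12 * np.abs(hi))

    def resid(x: np.ndarray) -> np.ndarray:
        f = expit(x[3] * (logC - math.log(x[2])))
        return sw * (R - x[0] - (x[1] - x[0]) * f)

    def jac(x: np.ndarray) -> np.ndarray:
        f = expit(x[3] * (logC - math.log(x[2])))
        df = (x[1] - x[0]) * f * (1.0 - f)
        J = np.empty((C.size, 4))
        J[:, 0] = 1.0 - f
        J[:, 1] = f
        J[:, 2] = -df * x[3] / x[2]
        J[:, 3] = df * (logC - math.log(x[2]))
        return -sw[:, None] * J

    # The box constraints are folded into the parameterization
    # x = lo + (hi - lo) * sigmoid(z) (ac50 and slope on a log scale),
    # so the cheap unbounded Levenberg-Marquardt solver applies; bounds
    # are approached asymptotically instead of being active constraints.
    span = hi - lo
    log_lo = np.log(lo[2:])
    log_span = np.log(hi[2:]) - log_lo

    def to_x(z: np.ndarray) -> np.ndarray:
        s = expit(z)
        x = np.empty(4)
        x[:2] = lo[:2] + span[:2] * s[:2]
        x[2:] = np.exp(log_lo + log_span * s[2:])
        return x

    def resid_z(z: np.ndarray) -> np.ndarray:
        x = to_x(z)
        f = expit(x[3] * (logC - math.log(x[2])))
        return sw * (R - x[0] - (x[1] - x[0]) * f)

    def jac_z(z: np.ndarray) -> np.ndarray:
        x = to_x(z)
        f = expit(x[3] * (logC - math.log(x[2])))
        df = (x[1] - x[0]) * f * (1.0 - f)
        sig = expit(z)
        dsig = sig * (1.0 - sig)
        J = np.empty((C.size, 4))
        J[:, 0] = (1.0 - f) * span[0] * dsig[0]
        J[:, 1] = f * span[1] * dsig[1]
        J[:, 2] = -df * x[3] * log_span[0] * dsig[2]  # via ln ac50
        J[:, 3] = df * (logC - math.log(x[2])) * x[3] * log_span[1] * dsig[3]
        return -sw[:, None] * J

    frac = np.clip((x0 - lo) / span, 1e-9, 1 - 1e-9)
    frac[2:] = np.clip((np.log(x0[2:]) - log_lo) / log_span, 1e-9, 1 - 1e-9)
    z0 = np.clip(np.log(frac / (1.0 - frac)), -4.0, 4.0)
    try:
        res = optimize.least_squares(
            resid_z, z0, jac=jac_z, method="lm", ftol=1e-8, xtol=1e-8, max_nfev=250
        )
        x = to_x(res.x)
        if np.all(np.isfinite(x)):
            return x, float(2.0 * res.cost), bool(res.success)
    except Exception:
        pass
    try:
        res = optimize.least_squares(
            resid,
            x0,
            jac=jac,
            bounds=(lo, hi),
            method="trf",
            ftol=1e-8,
            xtol=1e-8,
            gtol=1e-8,
            max_nfev=120,
        )
    except Exception:
        return x0, float(np.sum(resid(x0) ** 2)), False
    return res.x, float(2.0 * res.cost), bool(res.success)


def _fit_hill_core(
    C: np.ndarray, R: np.ndarray, w: np.ndarray
) -> tuple[HillParams, float, bool]:
    bounds = _param_bounds(C, R)
    cands = _grid_candidates(C, R, w)
    best: tuple[float, float, np.ndarray, bool] | None = None  # (sse, slope, x, ok)
    for _, x0 in cands[:_N_POLISH]:
        x, sse, ok = _polish(C, R, w, x0, bounds)
        # ties between equally good optima broken by the smaller slope
        if (
            best is None
            or sse < best[0] - 1e-12
            or (abs(sse - best[0]) <= 1e-12 and x[3] < best[1])
        ):
            best = (sse, float(x[3]), x, ok)
    assert best is not None
    sse, _, x, ok = best
    params = HillParams(float(x[0]), float(x[1]), float(x[2]), float(x[3]))
    return params, float(sse), ok


def fit_hill_nls(profile: Profile) -> FitResult:
    """Unweighted nonlinear least-squares Hill fit over included points."""
    C, R = profile.used()
    if C.size < 4:
        raise ValueError("Hill fit needs at least 4 included points")
    params, sse, ok = _fit_hill_core(C, R, np.ones(C.size))
    return FitResult(
        model_kind="hill",
        weighted=False,
        params=params,
        sse=sse,
        n_used=C.size,
        n_params=4,
        converged=ok,
    )


def fit_hill_wnls(profile: Profile, weights: Weights) -> FitResult:
    """Weighted Hill fit minimizing ``sum w_i (R_i - hill(C_i))^2``.

    With all-equal weights this reduces to :func:`fit_hill_nls` exactly
    (identical code path).
    """
    C, R = profile.used()
    if C.size < 4:
        raise ValueError("Hill fit needs at least 4 included points")
    w = np.asarray(weights.w, dtype=float)
    if w.size != C.size:
        raise ValueError("weights length must equal number of included points")
    params, sse, ok = _fit_hill_core(C, R, w)
    return FitResult(
        model_kind="hill",
        weighted=True,
        params=params,
        sse=sse,
        n_used=C.size,
        n_params=4,
        converged=ok,
        weights=weights,
    )


def fit_constant(profile: Profile, weights: Weights | None = None) -> FitResult:
    """Flat-line null fit: level is the (weighted) mean of included points."""
    _, R = profile.used()
    if weights is None:
        w = np.ones(R.size)
    else:
        w = np.asarray(weights.w, dtype=float)
        if w.size != R.size:
            raise ValueError("weights length must equal number of included points")
    level = float(np.sum(w * R) / np.sum(w))
    sse = float(np.sum(w * (R - level) ** 2))
    return FitResult(
        model_kind="constant",
        weighted=weights is not None,
        params=level,
        sse=sse,
        n_used=R.size,
        n_params=1,
        converged=True,
        weights=weights,
    )


def overall_f_test(full: FitResult, null: FitResult) -> FTestResult:
    """Extra-sum-of-squares F-test: 4-parameter Hill vs. flat line.

    ``F = [(sse_null - sse_full)/3] / [sse_full/(n-4)]`` referred to an
    F(3, n-4) distribution.  With n = 4 included points (or a perfect
    zero-residual fit) the test is undefined and never significant.
    """
    if full.model_kind != "hill" or null.model_kind != "constant":
        raise ValueError("expected a hill fit and a constant fit")
    if full.n_used != null.n_used or full.weighted != null.weighted:
        raise ValueError("fits must share included points and weighting")
    if full.weighted and null.weights is not None and full.weights is not None:
        if not np.allclose(full.weights.w, null.weights.w):
            raise ValueError("fits must share the same weights")
    df1 = 3
    df2 = full.n_used - 4
    if df2 <= 0 or full.sse == 0.0 or not full.converged:
        return FTestResult(F=math.nan, df1=df1, df2=df2, p=math.nan, defined=False)
    if full.sse >= null.sse:
        return FTestResult(F=0.0, df1=df1, df2=df2, p=1.0)
    F = ((null.sse - full.sse) / df1) / (full.sse / df2)
    p = float(stats.f.sf(F, df1, df2))
    return FTestResult(F=float(F), df1=df1, df2=df2, p=p)


def detect_outliers(profile: Profile, fdr_q: float = 0.01) -> np.ndarray:
    """Two-step outlier flagging combined with curve fitting.

    Step 1 fits the Hill model with a robust soft-L1 loss, so that the
    preliminary curve is not dragged toward the very points under
    suspicion.  Step 2 refers each scaled residual ``|r_i| / RSDR`` (the
    robust residual SD, from the 68.27th percentile of ``|r|`` inflated
    by ``n/(n-4)``) to a t distribution on ``n - 4`` degrees of freedom
    and flags points by a Benjamini-Hochberg step-up at false-discovery
    rate ``fdr_q``.  The FDR form keeps removals essentially nil on
    well-behaved Gaussian noise while still catching gross artifacts.
    At most ``ceil(n/7)`` points are removed, never below 4 survivors,
    and profiles with fewer than 6 included points are returned
    unchanged.  Returns the updated ``included`` mask.
    """
    mask = profile.included.copy()
    n = int(mask.sum())
    if n < 6:
        return mask
    C, R = profile.used()
    w = np.ones(n)
    logC = np.log(C)
    bounds = _param_bounds(C, R)
    cands = _grid_candidates(C, R, w)
    x0 = np.clip(cands[0][1], bounds[0], bounds[1])

    def resid(x: np.ndarray) -> np.ndarray:
        f = expit(x[3] * (logC - math.log(x[2])))
        return R - x[0] - (x[1] - x[0]) * f

    def jac(x: np.ndarray) -> np.ndarray:
        f = expit(x[3] * (logC - math.log(x[2])))
        df = (x[1] - x[0]) * f * (1.0 - f)
        J = np.empty((n, 4))
        J[:, 0] = 1.0 - f
        J[:, 1] = f
        J[:, 2] = -df * x[3] / x[2]
        J[:, 3] = df * (logC - math.log(x[2]))
        return -J

    scale0 = float(stats.median_abs_deviation(resid(x0), scale="normal"))
    try:
        res = optimize.least_squares(
            resid,
            x0,
            jac=jac,
            bounds=bounds,
            method="trf",
            loss="soft_l1",
            f_scale=max(scale0, OUTLIER_SCALE_FLOOR),
            ftol=1e-6,
            xtol=1e-6,
            max_nfev=60,
        )
        r = resid(res.x)
    except Exception:
        r = resid(x0)
    df_resid = n - 4
    rsdr = float(np.percentile(np.abs(r), 68.27)) * n / df_resid
    rsdr = max(rsdr, OUTLIER_SCALE_FLOOR)
    pvals = 2.0 * stats.t.sf(np.abs(r) / rsdr, df_resid)
    order = np.argsort(pvals)
    ranked = pvals[order]
    below = ranked <= fdr_q * (np.arange(1, n + 1) / n)
    if not below.any():
        return mask
    k = int(np.max(np.flatnonzero(below))) + 1  # BH step-up
    cap = min(math.ceil(n / 7), n - 4)
    if cap <= 0:
        return mask
    removed = order[: min(k, cap)]
    used_idx = np.flatnonzero(mask)
    mask[used_idx[removed]] = False
    return mask
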
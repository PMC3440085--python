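"""Four-parameter Hill concentration-response model.

The Hill equation describes a sigmoidal response as a function of test
concentration ``C`` (in uM)::

    R(C) = R0 + (RMAX - R0) / (1 + (AC50 / C)**SLOPE)

where ``R0`` is the baseline activity (response as ``C -> 0``), ``RMAX``
the maximal activity (response as ``C -> inf``), ``AC50`` the
concentration producing the half-maximal response, and ``SLOPE`` a
positive shape parameter.  Responses are expressed as percent of the
positive-control activity, so an activator has ``RMAX > R0`` and an
inhibitor ``RMAX < R0``; the same parameterization covers both
directions without a sign convention on ``SLOPE``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = ["HillParams", "Profile", "hill_response", "hill_gradient"]


@dataclass(frozen=True)
class HillParams:
    """Parameters of the four-parameter Hill model.

    Attributes
    ----------
    r0 : float
        Baseline activity, % of positive control.
    rmax : float
        Maximal activity, % of positive control.  ``rmax > r0`` for
        activators, ``rmax < r0`` for inhibitors, ``rmax == r0`` for a
        flat (null) profile.
    ac50 : float
        Concentration of half-maximal response, uM.  Must be positive.
    slope : float
        Hill shape parameter, dimensionless.  Must be positive.
    """

    r0: float
    rmax: float
    ac50: float
    slope: float

    def __post_init__(self) -> None:
        for name in ("r0", "rmax", "ac50", "slope"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.ac50 <= 0:
            raise ValueError(f"ac50 must be > 0, got {self.ac50!r}")
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.r0, self.rmax, self.ac50, self.slope], dtype=float)

    @property
    def direction(self) -> int:
        """+1 activator, -1 inhibitor, 0 flat."""
        return int(np.sign(self.rmax - self.r0))


@dataclass
class Profile:
    """One substance's concentration-response series.

    ``included`` marks points surviving outlier removal or deliberate
    thinning; excluded points are retained for provenance but ignored by
    every fit and test.  Concentrations must be positive and sorted
    ascending (duplicates from replicate wells are allowed).
    """

    substance_id: str
    concentrations: np.ndarray
    responses: np.ndarray
    included: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.included is None:
            self.included = np.ones(self.concentrations.shape, dtype=bool)
        else:
            self.included = np.asarray(self.included, dtype=bool)
        if self.concentrations.ndim != 1:
            raise ValueError("concentrations must be one-dimensional")
        if not (
            self.concentrations.shape
            == self.responses.shape
            == self.included.shape
        ):
            raise ValueError(
                "concentrations, responses and included must have equal length"
            )
        if self.concentrations.size == 0:
            raise ValueError("profile must contain at least one point")
        if np.any(~np.isfinite(self.concentrations)) or np.any(
            self.concentrations <= 0
        ):
            raise ValueError("concentrations must be finite and strictly positive")
        if np.any(np.diff(self.concentrations) < 0):
            raise ValueError("concentrations must be sorted ascending")
        if np.any(~np.isfinite(self.responses)):
            raise ValueError("responses must be finite")

    @property
    def n_total(self) -> int:
        return int(self.concentrations.size)

    @property
    def n_used(self) -> int:
        return int(np.count_nonzero(self.included))

    def used(self) -> tuple[np.ndarray, np.ndarray]:
        """Concentration and response vectors of the included points."""
        m = self.included
        return self.concentrations[m], self.responses[m]

    def with_mask(self, included: np.ndarray) -> "Profile":
        return Profile(
            self.substance_id,
            self.concentrations.copy(),
            self.responses.copy(),
            np.asarray(included, dtype=bool).copy(),
        )


def _check_conc(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if np.any(~np.isfinite(C)) or np.any(C <= 0):
        raise ValueError("concentrations must be finite and strictly positive")
    return C


def _fraction(ac50: float, slope: float, C: np.ndarray) -> np.ndarray:
    # 1 / (1 + (ac50/C)**slope) computed through the logistic function to
    # stay finite for extreme slope values (e.g. slope = 100).
    return expit(slope * (np.log(C) - np.log(ac50)))


def hill_response(params: HillParams, C) -> np.ndarray | float:
    """Noiseless mean response at concentration(s) ``C`` (uM).

    Monotone in ``C``; tends to ``r0`` as ``C -> 0`` and to ``rmax`` as
    ``C -> inf``.  Scalar in, scalar out.
    """
    scalar = np.isscalar(C)
    C = _check_conc(np.atleast_1d(C))
    f = _fraction(params.ac50, params.slope, C)
    out = params.r0 + (params.rmax - params.r0) * f
    return float(out[0]) if scalar else out


def hill_gradient(params: HillParams, C) -> np.ndarray:
    """Jacobian of the Hill response w.r.t. ``(r0, rmax, ac50, slope)``.

    Returns an ``(n, 4)`` matrix of partial derivatives, used as the
    analytic Jacobian in nonlinear least-squares fitting.
    """
    C = _check_conc(np.atleast_1d(C))
    f = _fraction(params.ac50, params.slope, C)
    span = params.rmax - params.r0
    df = f * (1.0 - f)
    logratio = np.log(C) - np.log(params.ac50)
    grad = np.empty((C.size, 4), dtype=float)
    grad[:, 0] = 1.0 - f
    grad[:, 1] = f
    grad[:, 2] = -span * df * params.slope / params.ac50
    grad[:, 3] = span * df * logratio
    return grad
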
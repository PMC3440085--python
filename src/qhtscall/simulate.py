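"""Synthetic qHTS concentration-response data sets with known truth.

Each simulated data set mimics an unreplicated qHTS screen: a mixture of
true actives drawn from a Hill curve and true inactives (flat at zero),
observed on a common 14-point log-spaced concentration grid spanning
4.90e-4 to 76.63 uM with additive Gaussian residual error.  The error
is either homoscedastic (constant sigma in percent of positive control)
or heteroscedastic with sigma growing linearly in concentration,
``sigma(C) = 9.7355 + 0.1146 * C``, the noise profile observed in human
nuclear-receptor agonist-mode screens.  Defaults: 2,000 actives and
8,000 inactives per data set, R0 = 0, SLOPE = 1, sigma = 25%.

Smaller effective sample sizes are produced by masking randomly chosen
points of the 14-point grid ("thinning"), mirroring data lost to
experimental failure or outlier removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hill import HillParams, Profile, hill_response

__all__ = [
    "GRID_C_MIN",
    "GRID_C_MAX",
    "ErrorSpec",
    "SimConfig",
    "SimDataset",
    "concentration_grid",
    "simulate_profile",
    "thin_profile",
    "simulate_dataset",
    "write_dataset",
]

GRID_C_MIN = 4.90e-4  # uM, lowest tested concentration
GRID_C_MAX = 76.63  # uM, highest tested concentration


@dataclass(frozen=True)
class ErrorSpec:
    """Residual-error model: eps_i ~ N(0, sigma_i^2).

    ``kind="constant"`` uses ``sigma`` everywhere; ``kind=
    "concentration_linear"`` uses ``sigma_i = a + b * C_i`` with
    ``coefficients = (a, b)``.
    """

    kind: str = "constant"
    sigma: float = 25.0
    coefficients: tuple[float, float] = (9.7355, 0.1146)

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "concentration_linear"):
            raise ValueError(f"unknown error kind {self.kind!r}")
        if self.kind == "constant" and self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def sigma_at(self, C) -> np.ndarray:
        """Residual SD at concentration(s) C (percent of positive control)."""
        C = np.asarray(C, dtype=float)
        if self.kind == "constant":
            out = np.full(C.shape, float(self.sigma))
        else:
            a, b = self.coefficients
            out = a + b * C
        if np.any(out < 0):
            raise ValueError("error model yields negative sigma")
        return out


@dataclass(frozen=True)
class SimConfig:
    """Conditions of one simulated data set."""

    ac50: float = 1e-3
    rmax: float = 100.0
    r0: float = 0.0
    slope: float = 1.0
    error: ErrorSpec = field(default_factory=ErrorSpec)
    n_points: int = 14
    points_removed: int = 0
    n_active: int = 2000
    n_null: int = 8000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not (0 <= self.points_removed < self.n_points):
            raise ValueError("points_removed must lie in [0, n_points)")
        if self.n_active < 0 or self.n_null < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def active_params(self) -> HillParams:
        return HillParams(self.r0, self.rmax, self.ac50, self.slope)


@dataclass
class SimDataset:
    """Simulated profiles plus per-substance ground truth.

    ``truth`` has one row per profile: substance_id, label
    ("active"/"null"), r0, rmax, ac50, slope.
    """

    profiles: list[Profile]
    truth: pd.DataFrame

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def labels(self) -> np.ndarray:
        return self.truth["label"].to_numpy()


def concentration_grid(
    n_points: int = 14, c_min: float = GRID_C_MIN, c_max: float = GRID_C_MAX
) -> np.ndarray:
    """Log10-equally-spaced test concentrations from c_min to c_max (uM)."""
    if n_points < 2:
        raise ValueError("need at least 2 points")
    return np.geomspace(c_min, c_max, n_points)


def simulate_profile(
    params: HillParams,
    error: ErrorSpec,
    grid: np.ndarray,
    rng: np.random.Generator,
    substance_id: str = "sim",
) -> Profile:
    """One noisy profile: Hill mean response plus independent N(0, sigma_i^2)."""
    mu = hill_response(params, grid)
    sigma = error.sigma_at(grid)
    R = mu + rng.normal(0.0, sigma)
    return Profile(substance_id, np.asarray(grid, float), R)


def thin_profile(profile: Profile, k_remove: int, rng: np.random.Generator) -> Profile:
    """Mask ``k_remove`` points chosen uniformly without replacement."""
    n = profile.n_total
    if not (0 <= k_remove < n):
        raise ValueError("k_remove must lie in [0, n_points)")
    if k_remove == 0:
        return profile
    mask = profile.included.copy()
    idx = rng.choice(np.flatnonzero(mask), size=k_remove, replace=False)
    mask[idx] = False
    return profile.with_mask(mask)


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Simulate ``n_active`` actives and ``n_null`` flat nulls.

    Both groups share the grid, error model and thinning.  Per-profile
    random streams are spawned from the configured seed, so any single
    profile can be regenerated independently of the rest.
    """
    grid = concentration_grid(config.n_points)
    null_params = HillParams(config.r0, config.r0, config.ac50, config.slope)
    n_total = config.n_active + config.n_null
    children = np.random.SeedSequence(config.seed).spawn(n_total)
    profiles: list[Profile] = []
    rows = []
    for i in range(n_total):
        active = i < config.n_active
        params = config.active_params if active else null_params
        rng = np.random.default_rng(children[i])
        sid = f"{'A' if active else 'N'}{i:05d}"
        p = simulate_profile(params, config.error, grid, rng, substance_id=sid)
        if config.points_removed:
            p = thin_profile(p, config.points_removed, rng)
        profiles.append(p)
        rows.append(
            {
                "substance_id": sid,
                "label": "active" if active else "null",
                "r0": params.r0,
                "rmax": params.rmax,
                "ac50": params.ac50,
                "slope": params.slope,
            }
        )
    return SimDataset(profiles=profiles, truth=pd.DataFrame(rows))


def write_dataset(dataset: SimDataset, path) -> None:
    """Write a dataset as long-format CSV with ground-truth columns."""
    truth = dataset.truth.set_index("substance_id")
    frames = []
    for p in dataset.profiles:
        t = truth.loc[p.substance_id]
        frames.append(
            pd.DataFrame(
                {
                    "substance_id": p.substance_id,
                    "concentration_uM": p.concentrations,
                    "response_pct": p.responses,
                    "included": p.included.astype(int),
                    "truth_label": t["label"],
                    "truth_AC50": t["ac50"],
                    "truth_RMAX": t["rmax"],
                    "truth_SLOPE": t["slope"],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
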
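"""Long-format CSV readers and writers for profiles and activity calls.

Profiles travel as comma-separated text with one row per
substance-concentration pair and a mandatory header::

    substance_id,concentration_uM,response_pct[,included]

Calls are written one row per substance with every stage-level p-value
and both sets of fitted Hill parameters.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .classify import CallRecord
from .hill import HillParams, Profile

__all__ = ["read_profiles", "write_profiles", "write_calls"]

_REQUIRED = ["substance_id", "concentration_uM", "response_pct"]


def read_profiles(path) -> list[Profile]:
    """Read profiles from long-format CSV, grouped by substance.

    Concentrations are sorted ascending within each substance; duplicate
    concentrations are kept as distinct points.  Malformed rows raise a
    ``ValueError`` naming the offending (1-based data) row.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    for col in ("concentration_uM", "response_pct"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna() & df[col].notna()) if vals.isna().any() else []
        nonnum = np.flatnonzero(vals.isna().to_numpy())
        if len(nonnum):
            raise ValueError(f"non-numeric {col} at row {int(nonnum[0]) + 1}")
        df[col] = vals
    bad = np.flatnonzero((df["concentration_uM"] <= 0).to_numpy())
    if len(bad):
        raise ValueError(f"non-positive concentration at row {int(bad[0]) + 1}")
    if "included" in df.columns:
        df["included"] = df["included"].astype(bool)
    else:
        df["included"] = True
    profiles = []
    for sid, g in df.groupby("substance_id", sort=False):
        g = g.sort_values("concentration_uM", kind="stable")
        profiles.append(
            Profile(
                str(sid),
                g["concentration_uM"].to_numpy(float),
                g["response_pct"].to_numpy(float),
                g["included"].to_numpy(bool),
            )
        )
    return profiles


def write_profiles(profiles, path) -> None:
    """Inverse of :func:`read_profiles`."""
    frames = [
        pd.DataFrame(
            {
                "substance_id": p.substance_id,
                "concentration_uM": p.concentrations,
                "response_pct": p.responses,
                "included": p.included.astype(int),
            }
        )
        for p in profiles
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_REQUIRED + ["included"])
    )
    out.to_csv(path, index=False)


def _fit_fields(rec: CallRecord, which: str) -> dict:
    fit = rec.fit_nls if which == "nls" else rec.fit_wnls
    if fit is None or not isinstance(fit.params, HillParams):
        return {f"{k}_{which}": math.nan for k in ("r0", "rmax", "ac50", "slope")}
    p = fit.params
    return {
        f"r0_{which}": p.r0,
        f"rmax_{which}": p.rmax,
        f"ac50_{which}": p.ac50,
        f"slope_{which}": p.slope,
    }


def write_calls(records, path) -> None:
    """Write one row per substance with call, stage, p-values and fits.

    p-values carry at least 6 significant digits.
    """
    rows = []
    for rec in records:
        row = {
            "substance_id": rec.substance_id,
            "call": rec.call,
            "stage": rec.stage if rec.stage is not None else "",
            "p_f_nls": rec.p_f_nls,
            "p_f_wnls": rec.p_f_wnls,
            "p_t_weighted_pos": rec.p_t_weighted_pos,
            "p_t_weighted_neg": rec.p_t_weighted_neg,
        }
        row.update(_fit_fields(rec, "nls"))
        row.update(_fit_fields(rec, "wnls"))
        row["n_used"] = rec.n_used
        row["outliers_removed"] = ";".join(str(i) for i in rec.outliers_removed)
        rows.append(row)
    cols = [
        "substance_id",
        "call",
        "stage",
        "p_f_nls",
        "p_f_wnls",
        "p_t_weighted_pos",
        "p_t_weighted_neg",
        "r0_nls",
        "rmax_nls",
        "ac50_nls",
        "slope_nls",
        "r0_wnls",
        "rmax_wnls",
        "ac50_wnls",
        "slope_wnls",
        "n_used",
        "outliers_removed",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.8g")
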
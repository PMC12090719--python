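"""Derived regulatory statistics.

Data collapses, additivity ratios, repression/activation strength,
box-saturation timing, and the decomposition of expression dynamics into
RNAP-holoenzyme versus 0A~P-binding contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Mapping

import numpy as np
import pandas as pd

from .params import (
    BOXES,
    COHORTS,
    LABELS,
    TIME_GRID,
    ScenarioParams,
    Signal0AP,
    StrainSpec,
    canonical_label,
)
from .promoter import marginal_occupancy, predict_timecourse

__all__ = [
    "additivity_ratio",
    "normalize_collapse",
    "regulation_strength",
    "saturation_time",
    "rnap_contribution",
    "joint_shared_sigma_fit",
]


def _mean_table(data: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean activity per (cohort, boxes, time_h)."""
    df = data.copy()
    df["boxes"] = df["boxes"].map(canonical_label)
    return (
        df.groupby(["cohort", "boxes", "time_h"])["activity"].mean().reset_index()
    )


def additivity_ratio(data: pd.DataFrame) -> pd.DataFrame:
    """Per-strain, per-timepoint additivity ratio (Pv + Ps) / PvPs.

    A ratio of one at all times means the two promoters transcribe
    independently; purely kinetic control gives exactly one.  Zero
    dual-promoter activity leaves the ratio undefined (NaN, with a warning).
    """
    m = _mean_table(data)
    wide = m.pivot_table(
        index=["boxes", "time_h"], columns="cohort", values="activity"
    )
    for c in COHORTS:
        if c not in wide.columns or wide[c].isna().any():
            raise ValueError(f"cohort {c!r} incomplete: matching strains required")
    out = wide.reset_index()
    denom = out["PvPs"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (out["Pv"].to_numpy() + out["Ps"].to_numpy()) / denom
    if np.any(denom == 0):
        warnings.warn("zero PvPs activity: additivity ratio undefined", stacklevel=2)
        ratio = np.where(denom == 0, np.nan, ratio)
    out["ratio"] = ratio
    return out[["boxes", "time_h", "ratio"]]


def normalize_collapse(data: pd.DataFrame) -> pd.DataFrame:
    """Double normalization that collapses the panel onto constant curves.

    Each strain's curve is divided by its last-timepoint value and then by
    the identically normalized "none" strain of its cohort:

        y_norm(l, t) = [y(l, t) / y(l, T)] / [y(none, t) / y(none, T)].

    When RNAP dynamics are the only shared time-dependent driver and box
    occupancy is saturated, every strain collapses to one.
    """
    m = _mean_table(data)
    t_last = m["time_h"].max()
    rows = []
    for cohort, sub in m.groupby("cohort"):
        wide = sub.pivot_table(index="boxes", columns="time_h", values="activity")
        if "none" not in wide.index:
            raise ValueError(f"cohort {cohort!r} lacks a 'none' strain")
        none = wide.loc["none"]
        if none[t_last] == 0 or (wide[t_last] == 0).any() or (none == 0).any():
            raise ValueError("zero reference activity: collapse undefined")
        ref = none / none[t_last]
        for label, row in wide.iterrows():
            norm = (row / row[t_last]) / ref
            for t, val in norm.items():
                rows.append(
                    {"cohort": cohort, "boxes": label, "time_h": float(t),
                     "value": float(val)}
                )
    return pd.DataFrame(rows)


def _freeze_a(params: ScenarioParams, t_freeze: float) -> ScenarioParams:
    """Hold every promoter's RNAP term at its value at ``t_freeze``."""
    idx = int(np.nonzero(np.isclose(params.times, t_freeze))[0][0])
    a = {p: np.full_like(v, v[idx]) for p, v in params.a.items()}
    return replace(params, a=a)


def regulation_strength(
    params: ScenarioParams,
    sig: Signal0AP,
    t_ref: float = 9.0,
    t_freeze: float = 2.0,
) -> pd.DataFrame:
    """Percent change of expression vs the "none" strain at ``t_ref``.

    RNAP terms are frozen at their ``t_freeze`` values so that only the
    time-dependent 0A~P concentration drives the comparison; negative values
    are repression, positive activation.  At full box saturation the
    single-promoter strength equals 100 * (rho(bound config) - 1).
    """
    frozen = _freeze_a(params, t_freeze)
    rows = []
    for cohort in COHORTS:
        ref = predict_timecourse(StrainSpec(cohort, "none"), frozen, sig)
        i_ref = int(np.nonzero(np.isclose(frozen.times, t_ref))[0][0])
        ref_val = ref[i_ref]
        for label in LABELS:
            v = predict_timecourse(StrainSpec(cohort, label), frozen, sig)[i_ref]
            rows.append(
                {
                    "cohort": cohort,
                    "boxes": label,
                    "strength_pct": 100.0 * (v - ref_val) / ref_val,
                }
            )
    return pd.DataFrame(rows)


def saturation_time(
    params: ScenarioParams,
    label: str,
    sig: Signal0AP,
    threshold: float = 0.99,
) -> dict[str, float | None]:
    """Earliest grid time at which each present box reaches ``threshold``
    marginal occupancy, or None if never reached."""
    strain = StrainSpec("PvPs", label)
    out: dict[str, float | None] = {}
    for b in strain.boxes:
        out[b] = None
    for t in params.times:
        conc = sig.conc_at(t)
        marg = marginal_occupancy(conc, params.binding, present=strain.boxes)
        for b, occ in marg.items():
            if out[b] is None and occ >= threshold:
                out[b] = float(t)
    return out


def rnap_contribution(
    params: ScenarioParams, strain: StrainSpec, sig: Signal0AP,
    t_freeze: float = 2.0,
) -> pd.DataFrame:
    """Predicted curves with dynamic vs frozen RNAP terms, plus their ratio.

    The frozen curve holds the RNAP term at its ``t_freeze`` value, so any
    residual increase reflects 0A~P binding alone.
    """
    dyn = predict_timecourse(strain, params, sig)
    frz = predict_timecourse(strain, _freeze_a(params, t_freeze), sig)
    return pd.DataFrame(
        {
            "time_h": params.times,
            "veff_dynamic": dyn,
            "veff_frozen": frz,
            "ratio": dyn / frz,
        }
    )


def joint_shared_sigma_fit(
    curves: Mapping[str, np.ndarray], times: np.ndarray = TIME_GRID
) -> dict:
    """Joint fit of two promoter curves to a shared RNAP-dynamics shape.

    Models y_p(t) = c_p * g(t) with one free shape g (anchored g(t0) = 1)
    and a per-promoter scale c_p, by least squares (best rank-one
    approximation).  Two promoters read by the same sigma-factor RNAP should
    share g up to their binding-affinity scale.
    """
    names = list(curves)
    if len(names) != 2:
        raise ValueError("exactly two promoter curves are required")
    Y = np.vstack([np.asarray(curves[k], dtype=float) for k in names])
    if Y.shape[1] != len(times):
        raise ValueError("curves must live on the given time grid")
    if np.allclose(Y, 0):
        raise ValueError("degenerate all-zero curves")
    u, s, vt = np.linalg.svd(Y, full_matrices=False)
    g = vt[0]
    c = s[0] * u[:, 0]
    if g.sum() < 0:  # orient the shape positively
        g, c = -g, -c
    if g[0] == 0:
        raise ValueError("shape vanishes at the anchor timepoint")
    c = c * g[0]
    g = g / g[0]
    resid = float(np.sum((Y - np.outer(c, g)) ** 2))
    return {
        "shape": g,
        "scales": {names[0]: float(c[0]), names[1]: float(c[1])},
        "residual": resid,
        "times": np.asarray(times, dtype=float),
    }
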
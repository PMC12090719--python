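"""Readers and writers for the package's interchange formats.

Tidy long-format CSV for measurements, JSON for fitted parameters.  Readers
validate and reject malformed rows (naming the offending lines) rather than
silently coercing; writers are deterministic (sorted keys, full float
precision).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .inference import FitResult, ObjectiveBreakdown
from .params import (
    BOXES,
    COHORTS,
    CONFIGS,
    PROMOTERS,
    TIME_GRID,
    BindingParams,
    ScenarioParams,
    canonical_label,
)

FIT_JSON_VERSION = "spo0areg-fit-1"
EMSA_JSON_VERSION = "spo0areg-emsa-1"

ACTIVITY_COLUMNS = ("cohort", "boxes", "time_h", "replicate", "activity")
EMSA_COLUMNS = ("box_subset", "conc_uM", "replicate", "frac_bound")


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{what} is missing columns {sorted(missing)}")


def _bad_rows(mask: pd.Series) -> str:
    # +2: header line plus 1-based indexing
    return ", ".join(str(i + 2) for i in mask[mask].index[:10])


def read_activity_csv(path: str | Path) -> pd.DataFrame:
    """Read a tidy activity table (cohort, boxes, time_h, replicate, activity)."""
    df = pd.read_csv(path, dtype={"boxes": str})
    _require_columns(df, ACTIVITY_COLUMNS, f"activity table {path}")
    bad = ~df["cohort"].isin(COHORTS)
    if bad.any():
        raise ValueError(f"unknown cohort on line(s) {_bad_rows(bad)}")
    try:
        df["boxes"] = df["boxes"].map(canonical_label)
    except ValueError as exc:
        raise ValueError(f"invalid boxes label in {path}: {exc}") from exc
    for col in ("time_h", "activity"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            raise ValueError(f"non-numeric {col} on line(s) {_bad_rows(bad)}")
        df[col] = vals
    dup = df.duplicated(["cohort", "boxes", "time_h", "replicate"])
    if dup.any():
        raise ValueError(
            f"duplicate (strain, time, replicate) on line(s) {_bad_rows(dup)}"
        )
    return df


def write_activity_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(ACTIVITY_COLUMNS)].to_csv(path, index=False)


def read_emsa_csv(path: str | Path) -> pd.DataFrame:
    """Read a tidy EMSA table (box_subset, conc_uM, replicate, frac_bound)."""
    df = pd.read_csv(path, dtype={"box_subset": str})
    _require_columns(df, EMSA_COLUMNS, f"EMSA table {path}")
    try:
        df["box_subset"] = df["box_subset"].map(canonical_label)
    except ValueError as exc:
        raise ValueError(f"invalid box_subset in {path}: {exc}") from exc
    for col in ("conc_uM", "frac_bound"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            raise ValueError(f"non-numeric {col} on line(s) {_bad_rows(bad)}")
        df[col] = vals
    bad = (df["conc_uM"] < 0) | (df["frac_bound"] < 0) | (df["frac_bound"] > 1)
    if bad.any():
        raise ValueError(f"out-of-range values on line(s) {_bad_rows(bad)}")
    return df


def write_emsa_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(EMSA_COLUMNS)].to_csv(path, index=False)


def write_emsa_fit_json(
    kh_fit: Mapping, selection: tuple[int, Mapping[int, float]] | None,
    path: str | Path,
) -> None:
    """Write per-box Kh estimates (with CIs), chosen N and candidate errors."""
    payload = {
        "version": EMSA_JSON_VERSION,
        "n": kh_fit["n"],
        "boxes": kh_fit["boxes"],
        "n_augment": kh_fit.get("n_augment"),
        "seed": kh_fit.get("seed"),
        "warnings": kh_fit.get("warnings", []),
    }
    if selection is not None:
        best, errors = selection
        payload["selected_n"] = int(best)
        payload["candidate_errors"] = {str(k): float(v) for k, v in errors.items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_emsa_fit_json(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != EMSA_JSON_VERSION:
        raise ValueError(
            f"unexpected EMSA-fit JSON version {payload.get('version')!r}"
        )
    return payload


def _binding_to_json(b: BindingParams) -> dict:
    return {
        "n": b.n,
        "n0a": b.effective_n0a,
        "kh_uM": {k: float(v) for k, v in b.kh.items()},
        "eps_kT": {"-".join(p): float(v) for p, v in b.eps.items()},
    }


def _binding_from_json(d: dict) -> BindingParams:
    eps = {tuple(k.split("-")): v for k, v in d.get("eps_kT", {}).items()}
    return BindingParams(n=d["n"], kh=d["kh_uM"], eps=eps, n0a=d.get("n0a"))


def _params_to_json(p: ScenarioParams) -> dict:
    return {
        "scenario": p.scenario,
        "binding": _binding_to_json(p.binding),
        "times_h": [float(t) for t in p.times],
        "a": {k: [float(x) for x in v] for k, v in p.a.items()},
        "rho": {k: {c: float(v[c]) for c in CONFIGS} for k, v in p.rho.items()},
        "eta": {k: {b: float(v[b]) for b in BOXES} for k, v in p.eta.items()},
        "vmax_scale": {k: float(v) for k, v in p.vmax_scale.items()},
    }


def _params_from_json(d: dict) -> ScenarioParams:
    return ScenarioParams(
        scenario=d["scenario"],
        binding=_binding_from_json(d["binding"]),
        a={k: np.asarray(v, dtype=float) for k, v in d["a"].items()},
        rho=d.get("rho", {}),
        eta=d.get("eta", {}),
        vmax_scale=d.get("vmax_scale", {}),
        times=np.asarray(d.get("times_h", TIME_GRID), dtype=float),
    )


def write_fit_json(result: FitResult, path: str | Path) -> None:
    """Serialize a FitResult, including the per-restart error trace."""
    payload = {
        "version": FIT_JSON_VERSION,
        "scenario": result.scenario,
        "lambda": float(result.lam),
        "params": _params_to_json(result.params),
        "objective": {
            "ev": result.objective.ev,
            "es": result.objective.es,
            "evs": result.objective.evs,
            "e": result.objective.e,
        },
        "bic": result.bic if np.isfinite(result.bic) else None,
        "bic_degenerate": result.bic_degenerate,
        "k_params": result.k_params,
        "n_restarts": result.n_restarts,
        "restart_errors": [float(e) for e in result.restart_errors],
        "seed": result.seed,
        "bound_hits": list(result.bound_hits),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_fit_json(path: str | Path) -> FitResult:
    d = json.loads(Path(path).read_text())
    if d.get("version") != FIT_JSON_VERSION:
        raise ValueError(f"unexpected fit JSON version {d.get('version')!r}")
    obj = ObjectiveBreakdown(
        ev=d["objective"]["ev"], es=d["objective"]["es"], evs=d["objective"]["evs"]
    )
    return FitResult(
        scenario=d["scenario"],
        params=_params_from_json(d["params"]),
        lam=d["lambda"],
        objective=obj,
        bic=float("-inf") if d["bic"] is None else d["bic"],
        k_params=d["k_params"],
        n_restarts=d["n_restarts"],
        restart_errors=list(d["restart_errors"]),
        seed=d["seed"],
        bound_hits=list(d["bound_hits"]),
        bic_degenerate=d["bic_degenerate"],
    )
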
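"""Statistical-mechanical promoter model.

Box-binding configurations are weighted by

    W(s) = prod_i ([0A~P]/Kh_i)^(N0A * s_i) * prod_{i<j} exp(-eps_ij)^(s_i s_j)

relative to the all-unbound reference W("000") = 1.  The effective
transcription rate of a promoter is the occupancy-weighted sum of maximum
initiation rates over promoter-bound states:

* kinetic control — RNAP occupancy is absorbed into a per-timepoint activity
  scale A(t) and each box configuration rescales vmax by rho(s):
  veff = A(t) * sum_s P(s) rho(s);
* thermodynamic control — vmax is configuration independent but RNAP
  occupancy responds to bound 0A~P through per-box interaction energies eta:
  the RNAP state r in {0, 1} enters the joint partition function with weight
  B(s, t) = R(t) * prod_i exp(-eta_i)^(s_i), and
  veff = vmax_scale * P(RNAP bound).

Dual-promoter constructs share the box state; thermodynamically controlled
RNAPs each couple to it through their own eta terms with no RNAP-RNAP
interaction, so purely kinetic control is exactly additive across promoters.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .params import (
    BOXES,
    COHORTS,
    CONFIGS,
    LABELS,
    BindingParams,
    ScenarioParams,
    Signal0AP,
    StrainSpec,
    boxes_to_mask,
    config_array,
)

_S = config_array()  # (8, 3) box states


def _pair_factors(binding: BindingParams) -> np.ndarray:
    """exp(-sum_{i<j} eps_ij s_i s_j) per configuration, shape (8,)."""
    eps = binding.eps_matrix()
    # s_i s_j summed over i<j equals (s eps s^T)/2 since eps is symmetric.
    quad = 0.5 * np.einsum("ci,ij,cj->c", _S, eps, _S)
    return np.exp(-quad)


def config_weights(conc: np.ndarray, binding: BindingParams) -> np.ndarray:
    """Statistical weights W(s) for every configuration, shape (8, T).

    ``conc`` is a 1-D array of 0A~P concentrations (uM).  Zero concentration
    is handled exactly: any configuration with a bound box gets weight 0.
    """
    c = np.atleast_1d(np.asarray(conc, dtype=float))
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    kh = binding.kh_array()
    x = (c[None, :] / kh[:, None]) ** binding.effective_n0a  # (3, T)
    w = np.ones((len(CONFIGS), c.size))
    for i in range(len(BOXES)):
        bound = _S[:, i] == 1
        w[bound, :] *= x[i][None, :]
    return w * _pair_factors(binding)[:, None]


def admissible_mask(present: Iterable[str]) -> np.ndarray:
    """Boolean (8,) mask of configurations whose bound boxes are all present."""
    m = boxes_to_mask(present)
    return ~(_S[:, ~m] == 1).any(axis=1)


def config_weight(config: str, conc: float, binding: BindingParams) -> float:
    """Weight of a single configuration at one concentration."""
    if config not in CONFIGS:
        raise ValueError(f"invalid configuration {config!r}")
    return float(config_weights(np.array([conc]), binding)[CONFIGS.index(config), 0])


def box_occupancy(
    conc: float, binding: BindingParams, present: Iterable[str] = BOXES
) -> dict[str, float]:
    """Probability of each box configuration at one concentration.

    Boxes absent from ``present`` (mutated out of the strain) are forced
    unbound; their configurations carry probability zero.  Probabilities sum
    to one.
    """
    adm = admissible_mask(present)
    w = config_weights(np.array([float(conc)]), binding)[:, 0] * adm
    p = w / w.sum()
    return {c: float(p[i]) for i, c in enumerate(CONFIGS)}


def marginal_occupancy(
    conc: float, binding: BindingParams, present: Iterable[str] = BOXES
) -> dict[str, float]:
    """Marginal P(box bound) for each present box."""
    p = box_occupancy(conc, binding, present)
    pv = np.array([p[c] for c in CONFIGS])
    return {
        b: float(pv[_S[:, i] == 1].sum())
        for i, b in enumerate(BOXES)
        if b in set(present)
    }


def _thermo_B(
    params: ScenarioParams, promoter: str, t_idx: np.ndarray
) -> np.ndarray:
    """RNAP-state weight B(s, t) = R(t) * exp(-eta . s), shape (8, T)."""
    g = np.exp(-_S @ params.eta_vector(promoter))  # (8,)
    r = params.a[promoter][t_idx]  # (T,)
    return g[:, None] * r[None, :]


def _cohort_veff(
    cohort: str,
    mask: np.ndarray,
    params: ScenarioParams,
    conc: np.ndarray,
    t_idx: np.ndarray,
) -> np.ndarray:
    """Effective transcription rate of one strain over timepoints, shape (T,)."""
    adm = admissible_mask([b for b, m in zip(BOXES, mask) if m])
    w = config_weights(conc, params.binding) * adm[:, None]  # (8, T)
    promoters = ("Pv", "Ps") if cohort == "PvPs" else (cohort,)
    thermo = [p for p in promoters if params.control(p) == "T"]
    B = {p: _thermo_B(params, p, t_idx) for p in thermo}
    D = np.ones_like(w)
    for p in thermo:
        D = D * (1.0 + B[p])
    Z = (w * D).sum(axis=0)  # (T,)
    veff = np.zeros(conc.size)
    for p in promoters:
        if params.control(p) == "K":
            rho = params.rho_vector(p)
            veff += params.a[p][t_idx] * (w * D * rho[:, None]).sum(axis=0) / Z
        else:
            other = np.ones_like(w)
            for q in thermo:
                if q != p:
                    other = other * (1.0 + B[q])
            veff += params.vmax_scale[p] * (w * B[p] * other).sum(axis=0) / Z
    return veff


def veff_single(
    strain: StrainSpec, params: ScenarioParams, conc: float, t: float
) -> float:
    """Effective transcription rate of a single-promoter strain (Pv or Ps)."""
    if strain.cohort not in ("Pv", "Ps"):
        raise ValueError("veff_single requires a Pv or Ps strain")
    return _veff_scalar(strain, params, conc, t)


def veff_dual(
    strain: StrainSpec, params: ScenarioParams, conc: float, t: float
) -> float:
    """Effective transcription rate of a dual-promoter (PvPs) strain."""
    if strain.cohort != "PvPs":
        raise ValueError("veff_dual requires a PvPs strain")
    return _veff_scalar(strain, params, conc, t)


def _veff_scalar(
    strain: StrainSpec, params: ScenarioParams, conc: float, t: float
) -> float:
    ti = np.array([_time_index(params, t)])
    out = _cohort_veff(strain.cohort, strain.mask, params, np.array([float(conc)]), ti)
    return float(out[0])


def _time_index(params: ScenarioParams, t: float) -> int:
    hits = np.nonzero(np.isclose(params.times, t, atol=1e-9))[0]
    if hits.size == 0:
        raise ValueError(f"timepoint {t} outside the model grid {params.times}")
    return int(hits[0])


def predict_timecourse(
    strain: StrainSpec, params: ScenarioParams, sig: Signal0AP
) -> np.ndarray:
    """Predicted activity of one strain on the model's time grid."""
    if not sig.covers(params.times):
        raise ValueError("signal does not cover the model time grid")
    conc = np.array([sig.conc_at(t) for t in params.times])
    t_idx = np.arange(params.times.size)
    return _cohort_veff(strain.cohort, strain.mask, params, conc, t_idx)


def predict_panel(params: ScenarioParams, sig: Signal0AP) -> pd.DataFrame:
    """Noise-free predictions for the full 24-strain panel (tidy format)."""
    rows = []
    for cohort in COHORTS:
        for label in LABELS:
            strain = StrainSpec(cohort, label)
            v = predict_timecourse(strain, params, sig)
            for t, val in zip(params.times, v):
                rows.append(
                    {"cohort": cohort, "boxes": label, "time_h": float(t),
                     "activity": float(val)}
                )
    return pd.DataFrame(rows)
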
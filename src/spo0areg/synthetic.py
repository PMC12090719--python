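"""Synthetic reporter-panel and EMSA-titration generator.

Emulates the study design end to end: a 24-strain beta-galactosidase panel
(3 promoter cohorts x 8 intact-box subsets, hourly 2-9 h, replicated) driven
by a rising 0A~P signal, and gel-shift titrations of the 7 non-empty box
subsets over 0-2 uM 0A~P.  The ground-truth defaults reproduce the
qualitative structure of the real system: box affinity ordering
Kh(0A3) < Kh(0A1) < Kh(0A2); purely kinetic control with mostly repressive
Pv ratios and a mixed Ps pattern (0A3 activating, 0A2 repressing,
rho_s("111") = 0.284, i.e. a 71.6% repression at saturation); the 0A2-0A3
pair the most attractive interaction; and a Ps RNAP fold-rise (10.8x) far
exceeding Pv's (1.4x).

Activity noise is multiplicative log-normal (reporter noise scales with
signal); EMSA noise is additive Gaussian truncated to [0, 1].  Every output
is byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .params import (
    BOXES,
    COHORTS,
    LABELS,
    TIME_GRID,
    BindingParams,
    ScenarioParams,
    Signal0AP,
)
from .binding import fraction_bound_multi
from .promoter import predict_panel

__all__ = ["GroundTruth", "gen_0ap_signal", "gen_emsa_dataset", "gen_activity_panel"]

#: Default EMSA concentration grid (uM), spanning the assayed 0-2 uM range.
EMSA_CONC_GRID = np.array([0.0, 0.1, 0.2, 0.3, 0.5, 0.75, 1.0, 1.5, 2.0])

_DEFAULT_KH_VITRO = {"0A1": 0.4, "0A2": 0.6, "0A3": 0.2}
_DEFAULT_EPS = {("0A1", "0A2"): -1.0, ("0A1", "0A3"): -1.2, ("0A2", "0A3"): -2.5}
_DEFAULT_RHO_V = {
    "000": 1.0, "100": 0.50, "010": 0.75, "001": 0.90,
    "110": 0.45, "101": 0.50, "011": 0.70, "111": 0.40,
}
_DEFAULT_RHO_S = {
    "000": 1.0, "100": 1.15, "010": 0.60, "001": 1.30,
    "110": 0.80, "101": 1.40, "011": 0.45, "111": 0.284,
}


def gen_0ap_signal(
    c_max: float = 1.0,
    t0: float = 4.0,
    k: float = 1.0,
    times: np.ndarray = TIME_GRID,
) -> Signal0AP:
    """Logistic stand-in for the wild-type 0A~P trajectory.

    c(t) = c_max / (1 + exp(-k (t - t0))), sampled on the hourly grid;
    monotone non-decreasing for k >= 0.
    """
    if c_max <= 0:
        raise ValueError("c_max must be positive")
    t = np.asarray(times, dtype=float)
    conc = c_max / (1.0 + np.exp(-k * (t - t0)))
    return Signal0AP(times=t, conc=conc)


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for the synthetic study.

    The defaults define the reference conditions used throughout the test
    suite; see the module docstring for the structure they encode.
    """

    n: int = 4
    kh_vitro: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_KH_VITRO)
    )
    lam: float = 0.5
    eps: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_EPS)
    )
    scenario: str = "KK"
    rho_v: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_RHO_V))
    rho_s: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_RHO_S))
    a_v_start: float = 100.0
    a_v_fold: float = 1.4
    a_s_start: float = 25.0
    a_s_fold: float = 10.8
    signal_c_max: float = 1.0
    signal_t0: float = 4.0
    signal_k: float = 1.0
    noise_cv: float = 0.05
    replicates: int = 3
    emsa_sd: float = 0.02
    emsa_replicates: int = 2
    seed: int = 0

    def signal(self) -> Signal0AP:
        return gen_0ap_signal(self.signal_c_max, self.signal_t0, self.signal_k)

    def binding_vitro(self) -> BindingParams:
        """In-vitro binding model: EMSA Kh, no pair interactions."""
        return BindingParams(n=self.n, kh=dict(self.kh_vitro))

    def binding_vivo(self) -> BindingParams:
        """In-vivo binding model: reconciled Kh plus pair interactions."""
        kh = {b: self.lam * v for b, v in self.kh_vitro.items()}
        return BindingParams(n=self.n, kh=kh, eps=dict(self.eps))

    def a_curves(self) -> dict[str, np.ndarray]:
        """Geometric RNAP activity rises over 2-9 h per promoter."""
        frac = (TIME_GRID - TIME_GRID[0]) / (TIME_GRID[-1] - TIME_GRID[0])
        return {
            "Pv": self.a_v_start * self.a_v_fold ** frac,
            "Ps": self.a_s_start * self.a_s_fold ** frac,
        }

    def scenario_params(self) -> ScenarioParams:
        if self.scenario != "KK":
            raise ValueError(
                "the generator's ground truth is purely kinetic; construct "
                "ScenarioParams directly for thermodynamic scenarios"
            )
        return ScenarioParams(
            scenario="KK",
            binding=self.binding_vivo(),
            a=self.a_curves(),
            rho={"Pv": dict(self.rho_v), "Ps": dict(self.rho_s)},
        )


def gen_emsa_dataset(
    truth: GroundTruth,
    conc_grid: np.ndarray = EMSA_CONC_GRID,
    replicates: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Noisy bound-fraction titrations for all 7 non-empty box subsets.

    Model values come from the multi-box partition function of the in-vitro
    parameters (no pair interactions); noise is additive Gaussian with SD
    ``truth.emsa_sd``, truncated to [0, 1].
    """
    reps = truth.emsa_replicates if replicates is None else replicates
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    binding = truth.binding_vitro()
    conc = np.asarray(conc_grid, dtype=float)
    rows = []
    for label in LABELS[1:]:  # the 7 non-empty subsets
        boxes = tuple(f"0A{d}" for d in label)
        f = fraction_bound_multi(boxes, binding, conc)
        for rep in range(1, reps + 1):
            if truth.emsa_sd > 0:
                a = (0.0 - f) / truth.emsa_sd
                b = (1.0 - f) / truth.emsa_sd
                vals = stats.truncnorm.rvs(
                    a, b, loc=f, scale=truth.emsa_sd, size=f.size, random_state=rng
                )
            else:
                vals = f
            for c, v in zip(conc, vals):
                rows.append(
                    {"box_subset": label, "conc_uM": float(c),
                     "replicate": rep, "frac_bound": float(v)}
                )
    return pd.DataFrame(rows)


def gen_activity_panel(
    truth: GroundTruth,
    replicates: int | None = None,
    noise_cv: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Replicated activity measurements for the full 24-strain panel.

    Noise-free means are the model predictions of the ground-truth scenario;
    replicates multiply them by mean-one log-normal factors with the given
    coefficient of variation.
    """
    reps = truth.replicates if replicates is None else replicates
    cv = truth.noise_cv if noise_cv is None else noise_cv
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    mean_df = predict_panel(truth.scenario_params(), truth.signal())
    sigma = np.sqrt(np.log1p(cv**2))
    rows = []
    for _, row in mean_df.iterrows():
        for rep in range(1, reps + 1):
            factor = (
                float(np.exp(rng.normal(-0.5 * sigma**2, sigma))) if cv > 0 else 1.0
            )
            rows.append(
                {
                    "cohort": row["cohort"],
                    "boxes": row["boxes"],
                    "time_h": row["time_h"],
                    "replicate": rep,
                    "activity": row["activity"] * factor,
                }
            )
    return pd.DataFrame(rows)
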
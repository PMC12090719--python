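"""Fitting the promoter models to the 24-strain reporter panel.

The objective is the mean squared *relative* residual per cohort,

    E_i = (1 / (L_i T_i)) sum_{l,t} (veff_{l,t} - X_{l,t})^2 / X_{l,t}^2,
    E = Ev + Es + Evs,

with X the replicate-mean activity.  EMSA-derived in-vitro Kh values enter
as a constraint: in-vivo half-saturations are lambda * Kh_vitro with a
single global reconciliation scale lambda > 0, preserving the relative box
affinities.

The parameter space splits into a small nonlinear block (pair energies eps,
lambda, and for thermodynamically controlled promoters the eta energies and
RNAP occupancy ratios R(t)) and a conditionally linear block (kinetic
activity scales A(t), vmax ratios rho, thermodynamic vmax scales).  The
fitter runs a multi-restart differential-evolution search over the nonlinear
block; at every trial point the linear block is profiled out exactly by
weighted (alternating) least squares.  Restarts are independent seeded runs
and the best is reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression
from sklearn.utils.validation import check_is_fitted

from .params import (
    BOXES,
    COHORTS,
    CONFIGS,
    LABELS,
    PAIRS,
    PROMOTERS,
    SCENARIOS,
    TIME_GRID,
    BindingParams,
    ScenarioParams,
    Signal0AP,
    canonical_label,
)
from .promoter import admissible_mask, config_weights, predict_panel

__all__ = [
    "ObjectiveBreakdown",
    "FitResult",
    "objective",
    "reconcile_kh",
    "bic",
    "fit_scenario",
    "fit_constrained_interactions",
    "compare_scenarios",
    "PromoterScenarioModel",
    "activity_means",
]

N_OBS = len(COHORTS) * len(LABELS) * len(TIME_GRID)  # 192

_IDX000 = CONFIGS.index("000")
_NONREF = [i for i, c in enumerate(CONFIGS) if c != "000"]
_S_MAT = np.array([[int(d) for d in c] for c in CONFIGS], dtype=float)


def _adm_stack() -> np.ndarray:
    from .params import label_to_boxes

    return np.stack([admissible_mask(label_to_boxes(l)) for l in LABELS])


_ADM = None  # (8 labels, 8 configs), built lazily to avoid import cycles


@dataclass(frozen=True)
class ObjectiveBreakdown:
    """Per-cohort mean squared relative errors; E = ev + es + evs."""

    ev: float
    es: float
    evs: float

    @property
    def e(self) -> float:
        return self.ev + self.es + self.evs


@dataclass
class FitResult:
    """Outcome of one scenario fit (best of all restarts)."""

    scenario: str
    params: ScenarioParams
    lam: float
    objective: ObjectiveBreakdown
    bic: float
    k_params: int
    n_restarts: int
    restart_errors: list[float]
    seed: int | None
    bound_hits: list[str] = field(default_factory=list)
    bic_degenerate: bool = False


def activity_means(data: pd.DataFrame) -> dict[str, np.ndarray]:
    """Replicate-mean activities per cohort as (8 labels, T) arrays.

    The tidy input must carry columns cohort, boxes, time_h, replicate,
    activity and cover all 24 strains on the full time grid.
    """
    required = {"cohort", "boxes", "time_h", "activity"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"activity table missing columns {sorted(missing)}")
    df = data.copy()
    df["boxes"] = df["boxes"].map(canonical_label)
    out: dict[str, np.ndarray] = {}
    g = df.groupby(["cohort", "boxes", "time_h"])["activity"].mean()
    for cohort in COHORTS:
        arr = np.full((len(LABELS), len(TIME_GRID)), np.nan)
        for i, label in enumerate(LABELS):
            for j, t in enumerate(TIME_GRID):
                try:
                    arr[i, j] = g.loc[(cohort, label, t)]
                except KeyError:
                    raise ValueError(
                        f"missing data for ({cohort}, {label}, t={t})"
                    ) from None
        out[cohort] = arr
    return out


def objective(pred, data) -> ObjectiveBreakdown:
    """Mean squared relative error between predictions and replicate means.

    ``pred`` and ``data`` may each be a tidy DataFrame or a dict
    cohort -> (labels, timepoints) array.  Any zero data mean makes the
    relative residual undefined and raises.
    """
    p = pred if isinstance(pred, dict) else activity_means(pred)
    x = data if isinstance(data, dict) else activity_means(data)
    terms = {}
    for cohort in COHORTS:
        if cohort not in p or cohort not in x:
            raise ValueError(f"missing cohort {cohort!r}")
        pa, xa = np.asarray(p[cohort], float), np.asarray(x[cohort], float)
        if pa.shape != xa.shape:
            raise ValueError(f"shape mismatch for cohort {cohort!r}")
        if np.any(xa == 0):
            raise ValueError(
                f"zero mean activity in cohort {cohort!r}: relative residual undefined"
            )
        terms[cohort] = float(np.mean(((pa - xa) / xa) ** 2))
    return ObjectiveBreakdown(ev=terms["Pv"], es=terms["Ps"], evs=terms["PvPs"])


def reconcile_kh(kh_vitro: Mapping[str, float], lam: float) -> dict[str, float]:
    """In-vivo half-saturations: a single global scale on the EMSA values."""
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError(f"reconciliation scale lambda must be > 0, got {lam}")
    return {b: lam * float(v) for b, v in kh_vitro.items()}


def bic(ssr_rel: float, n_obs: int, k: int) -> float:
    """BIC under a Gaussian relative-error likelihood.

    BIC = n ln(SSR/n) + k ln(n) with SSR the summed squared relative
    residuals.  SSR = 0 returns -inf (callers flag the degenerate case).
    """
    if ssr_rel < 0:
        raise ValueError("SSR must be non-negative")
    if ssr_rel == 0:
        return -math.inf
    return n_obs * math.log(ssr_rel / n_obs) + k * math.log(n_obs)


# ---------------------------------------------------------------------------
# Scenario fitter
# ---------------------------------------------------------------------------

_DEFAULT_BOUNDS = {
    "eps": (-10.0, 5.0),
    "log10_lambda": (-2.0, 2.0),  # lambda in [0.01, 100]
    "eta": (-10.0, 5.0),
    "log10_r": (-3.0, 3.0),
    "rho_max": 5.0,
}


class PromoterScenarioModel(BaseEstimator):
    """Global fit of one regulatory scenario to an activity panel.

    Parameters
    ----------
    scenario : {"KK", "KT", "TK", "TT"}
        Control mode per promoter (first letter Pv, second Ps; K kinetic,
        T thermodynamic).
    kh_vitro : mapping box -> uM
        EMSA-constrained in-vitro half-saturations.
    n : int
        Cooperativity from the EMSA fit; also used as the in-vivo exponent
        unless ``n0a`` overrides it.
    restarts : int
        Number of independent seeded global-search runs (>= 20 by default).
    zero_eps : iterable of box pairs
        Interaction energies pinned to zero (nested-model tests).
    monotone_a : bool
        If true, project each fitted A(t) onto non-decreasing curves.
    de_maxiter, de_popsize : int
        Differential-evolution budget per restart.
    als_iters : int
        Alternating-least-squares sweeps for the conditionally linear block.
    random_state : int or None
        Seed controlling every restart; fits are reproducible given it.
    """

    def __init__(
        self,
        scenario: str = "KK",
        kh_vitro: Mapping[str, float] | None = None,
        n: int = 4,
        n0a: int | None = None,
        restarts: int = 20,
        zero_eps: Sequence[tuple[str, str]] = (),
        monotone_a: bool = False,
        de_maxiter: int = 150,
        de_popsize: int = 15,
        als_iters: int = 30,
        als_tol: float = 1e-12,
        random_state: int | None = None,
    ):
        self.scenario = scenario
        self.kh_vitro = kh_vitro
        self.n = n
        self.n0a = n0a
        self.restarts = restarts
        self.zero_eps = zero_eps
        self.monotone_a = monotone_a
        self.de_maxiter = de_maxiter
        self.de_popsize = de_popsize
        self.als_iters = als_iters
        self.als_tol = als_tol
        self.random_state = random_state

    # -- theta layout -------------------------------------------------------

    def _layout(self) -> dict:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        control = {"Pv": self.scenario[0], "Ps": self.scenario[1]}
        kin = [p for p in PROMOTERS if control[p] == "K"]
        th = [p for p in PROMOTERS if control[p] == "T"]
        pinned = {tuple(sorted(p)) for p in self.zero_eps}
        free_pairs = [p for p in PAIRS if p not in pinned]
        names: list[str] = [f"eps_{a[-1]}{b[-1]}" for a, b in free_pairs]
        bounds: list[tuple[float, float]] = [_DEFAULT_BOUNDS["eps"]] * len(free_pairs)
        names.append("log10_lambda")
        bounds.append(_DEFAULT_BOUNDS["log10_lambda"])
        for p in th:
            for b in BOXES:
                names.append(f"eta_{p}_{b}")
                bounds.append(_DEFAULT_BOUNDS["eta"])
            for t in TIME_GRID:
                names.append(f"log10R_{p}_{t:g}")
                bounds.append(_DEFAULT_BOUNDS["log10_r"])
        return {
            "kin": kin,
            "th": th,
            "free_pairs": free_pairs,
            "names": names,
            "bounds": bounds,
        }

    def _decode(self, theta: np.ndarray, lay: dict) -> dict:
        npair = len(lay["free_pairs"])
        eps = {pair: float(v) for pair, v in zip(lay["free_pairs"], theta[:npair])}
        lam = float(10.0 ** theta[npair])
        pos = npair + 1
        eta: dict[str, np.ndarray] = {}
        rr: dict[str, np.ndarray] = {}
        for p in lay["th"]:
            eta[p] = np.asarray(theta[pos : pos + 3], float)
            pos += 3
            rr[p] = 10.0 ** np.asarray(theta[pos : pos + len(TIME_GRID)], float)
            pos += len(TIME_GRID)
        return {"eps": eps, "lam": lam, "eta": eta, "R": rr}

    # -- conditional (profiled) linear solve --------------------------------

    def _structures(self, dec: dict, conc: np.ndarray, lay: dict) -> dict:
        """Occupancy tensors fixed by the nonlinear block.

        Returns per-cohort RNAP-tilted configuration probabilities
        Ptil (8 labels, 8 configs, T) and, for thermodynamic promoters,
        their RNAP-bound fractions q_p (8 labels, T).
        """
        global _ADM
        if _ADM is None:
            _ADM = _adm_stack()
        kh_vivo = {b: dec["lam"] * self.kh_vitro[b] for b in BOXES}
        binding = BindingParams(n=self.n, kh=kh_vivo, eps=dec["eps"], n0a=self.n0a)
        w = config_weights(conc, binding)  # (8 configs, T)
        wl = _ADM[:, :, None] * w[None, :, :]  # (L, 8, T)
        B = {}
        for p in lay["th"]:
            g = np.exp(-_S_MAT @ dec["eta"][p])  # (8,)
            B[p] = g[:, None] * dec["R"][p][None, :]  # (8, T)
        out = {"binding": binding}
        for cohort in COHORTS:
            proms = PROMOTERS if cohort == "PvPs" else (cohort,)
            th_here = [p for p in lay["th"] if p in proms]
            D = np.ones_like(w)
            for p in th_here:
                D = D * (1.0 + B[p])
            wd = wl * D[None, :, :]
            Z = wd.sum(axis=1)  # (L, T)
            ptil = wd / Z[:, None, :]
            q = {}
            for p in th_here:
                other = np.ones_like(w)
                for qq in th_here:
                    if qq != p:
                        other = other * (1.0 + B[qq])
                q[p] = (wl * (B[p] * other)[None, :, :]).sum(axis=1) / Z
            out[cohort] = {"ptil": ptil, "q": q, "proms": proms}
        return out

    def _inner(
        self,
        dec: dict,
        conc: np.ndarray,
        x: dict[str, np.ndarray],
        lay: dict,
        als_iters: int | None = None,
    ) -> tuple[ObjectiveBreakdown, dict]:
        """Exact/ALS solve of the linear block given the nonlinear block."""
        st = self._structures(dec, conc, lay)
        kin, th = lay["kin"], lay["th"]
        T = len(TIME_GRID)
        nL = len(LABELS)
        wgt = {c: 1.0 / x[c] for c in COHORTS}
        eye_t = np.eye(T)

        rho = {p: np.ones(len(CONFIGS)) for p in kin}
        A = {p: np.zeros(T) for p in kin}
        v = {p: 1.0 for p in th}

        prev_e = np.inf
        breakdown = None
        iters = self.als_iters if als_iters is None else als_iters
        for _ in range(max(1, iters)):
            # --- A-step: activity scales A_p(t) and vmax scales v_p --------
            # Rows are (cohort, label, timepoint); each column block is
            # either the T values of one kinetic promoter's A(t) (diagonal
            # in t) or one thermodynamic promoter's vmax scale.
            blocks = []
            targets = []
            for cohort in COHORTS:
                sc = st[cohort]
                wt = wgt[cohort]  # (L, T)
                cols = []
                for p in kin:
                    if p in sc["proms"]:
                        kf = np.einsum("lst,s->lt", sc["ptil"], rho[p]) * wt
                    else:
                        kf = np.zeros((nL, T))
                    # (L, T, T) with kf on the time diagonal -> (L*T, T)
                    cols.append((kf[:, :, None] * eye_t[None, :, :]).reshape(-1, T))
                for p in th:
                    qv = sc["q"].get(p)
                    col = (qv * wt if qv is not None else np.zeros((nL, T)))
                    cols.append(col.reshape(-1, 1))
                blocks.append(np.hstack(cols))
                targets.append((x[cohort] * wt).reshape(-1))
            G = np.vstack(blocks)
            y = np.concatenate(targets)
            z, *_ = np.linalg.lstsq(G, y, rcond=None)
            z = np.clip(z, 0.0, None)
            pos = 0
            for p in kin:
                A[p] = z[pos : pos + T].copy()
                if self.monotone_a:
                    iso = IsotonicRegression(increasing=True)
                    A[p] = iso.fit_transform(TIME_GRID, A[p])
                pos += T
            for p in th:
                v[p] = float(z[pos])
                pos += 1

            # --- rho-step: vmax ratios per non-reference configuration ----
            if kin:
                blocks = []
                targets = []
                for cohort in COHORTS:
                    sc = st[cohort]
                    wt = wgt[cohort]
                    base = np.zeros((nL, T))
                    for p in sc["q"]:
                        base += v[p] * sc["q"][p]
                    cols = []
                    for p in kin:
                        if p in sc["proms"]:
                            base += A[p][None, :] * sc["ptil"][:, _IDX000, :]
                            # (L, 7, T) -> (L, T, 7) -> (L*T, 7)
                            m = (
                                wt[:, None, :]
                                * A[p][None, None, :]
                                * sc["ptil"][:, _NONREF, :]
                            )
                            cols.append(m.transpose(0, 2, 1).reshape(-1, len(_NONREF)))
                        else:
                            cols.append(np.zeros((nL * T, len(_NONREF))))
                    blocks.append(np.hstack(cols))
                    targets.append(((x[cohort] - base) * wt).reshape(-1))
                H = np.vstack(blocks)
                yb = np.concatenate(targets)
                r, *_ = np.linalg.lstsq(H, yb, rcond=None)
                r = np.clip(r, 0.0, _DEFAULT_BOUNDS["rho_max"])
                for i, p in enumerate(kin):
                    vec = np.ones(len(CONFIGS))
                    vec[_NONREF] = r[i * len(_NONREF) : (i + 1) * len(_NONREF)]
                    rho[p] = vec

            breakdown = self._breakdown(st, A, rho, v, x, lay)
            if abs(prev_e - breakdown.e) <= self.als_tol * max(breakdown.e, 1e-300):
                break
            prev_e = breakdown.e

        linear = {"A": A, "rho": rho, "v": v, "binding": st["binding"]}
        return breakdown, linear

    def _breakdown(self, st, A, rho, v, x, lay) -> ObjectiveBreakdown:
        terms = {}
        for cohort in COHORTS:
            sc = st[cohort]
            pred = np.zeros_like(x[cohort])
            for p in lay["kin"]:
                if p in sc["proms"]:
                    pred += A[p][None, :] * np.einsum("lst,s->lt", sc["ptil"], rho[p])
            for p in sc["q"]:
                pred += v[p] * sc["q"][p]
            terms[cohort] = float(np.mean(((pred - x[cohort]) / x[cohort]) ** 2))
        return ObjectiveBreakdown(ev=terms["Pv"], es=terms["Ps"], evs=terms["PvPs"])

    # -- public API ---------------------------------------------------------

    def conditional_fit(
        self,
        data: pd.DataFrame | dict,
        signal: Signal0AP,
        eps: Mapping[tuple[str, str], float],
        lam: float,
        eta: Mapping[str, Iterable[float]] | None = None,
        r: Mapping[str, Iterable[float]] | None = None,
    ) -> tuple[ObjectiveBreakdown, ScenarioParams]:
        """Profile the linear block at a fixed nonlinear point.

        Useful for fixed-point checks: on noise-free data generated by the
        model, evaluating at the true (eps, lambda) returns E ~ 0 and the
        generating linear parameters.
        """
        self._check_inputs()
        lay = self._layout()
        x = data if isinstance(data, dict) else activity_means(data)
        conc = np.array([signal.conc_at(t) for t in TIME_GRID])
        dec = {
            "eps": {tuple(sorted(k)): float(vv) for k, vv in dict(eps).items()},
            "lam": float(lam),
            "eta": {p: np.asarray(list(dict(eta or {}).get(p, np.zeros(3))), float)
                    for p in lay["th"]},
            "R": {p: np.asarray(list(dict(r or {}).get(p, np.ones(len(TIME_GRID)))),
                                float) for p in lay["th"]},
        }
        breakdown, linear = self._inner(dec, conc, x, lay, als_iters=2 * self.als_iters)
        return breakdown, self._to_params(dec, linear, lay)

    def fit(self, X, y=None, *, signal: Signal0AP):
        """Fit the scenario to a tidy activity table.

        ``X`` carries columns cohort, boxes, time_h, replicate, activity for
        the full 24-strain panel; ``signal`` supplies the 0A~P trajectory.
        """
        self._check_inputs()
        lay = self._layout()
        x = X if isinstance(X, dict) else activity_means(X)
        if not signal.covers(TIME_GRID):
            raise ValueError("signal does not cover the 2-9 h time grid")
        conc = np.array([signal.conc_at(t) for t in TIME_GRID])
        for cohort in COHORTS:
            if np.any(x[cohort] <= 0):
                raise ValueError("activity means must be positive for relative errors")

        def score(theta: np.ndarray) -> float:
            dec = self._decode(theta, lay)
            return self._inner(dec, conc, x, lay, als_iters=self.als_iters)[0].e

        rng = np.random.default_rng(self.random_state)
        seeds = rng.integers(0, 2**31 - 1, size=self.restarts)
        best_theta, best_e = None, np.inf
        restart_errors: list[float] = []
        failures = 0
        for s in seeds:
            try:
                res = differential_evolution(
                    score,
                    bounds=lay["bounds"],
                    seed=int(s),
                    maxiter=self.de_maxiter,
                    popsize=self.de_popsize,
                    tol=1e-10,
                    polish=True,
                )
            except Exception:  # pragma: no cover - defensive
                failures += 1
                restart_errors.append(math.inf)
                continue
            restart_errors.append(float(res.fun))
            if res.fun < best_e:
                best_e, best_theta = float(res.fun), np.asarray(res.x)
        if best_theta is None:
            raise RuntimeError("all optimizer restarts failed")
        if failures:
            warnings.warn(f"{failures} optimizer restarts failed", stacklevel=2)

        dec = self._decode(best_theta, lay)
        breakdown, linear = self._inner(
            dec, conc, x, lay, als_iters=4 * self.als_iters
        )
        params = self._to_params(dec, linear, lay)
        k = self._count_params(lay)
        ssr = len(LABELS) * len(TIME_GRID) * breakdown.e
        b = bic(ssr, N_OBS, k)
        self.result_ = FitResult(
            scenario=self.scenario,
            params=params,
            lam=dec["lam"],
            objective=breakdown,
            bic=b,
            k_params=k,
            n_restarts=self.restarts,
            restart_errors=restart_errors,
            seed=self.random_state,
            bound_hits=self._bound_hits(best_theta, lay),
            bic_degenerate=not math.isfinite(b),
        )
        self.params_ = params
        self.objective_ = breakdown
        self.lambda_ = dec["lam"]
        self.bic_ = b
        self.signal_ = signal
        return self

    def predict(self, X=None) -> pd.DataFrame:
        """Noise-free panel predictions of the fitted scenario."""
        check_is_fitted(self, "params_")
        return predict_panel(self.params_, self.signal_)

    # -- helpers ------------------------------------------------------------

    def _check_inputs(self) -> None:
        if self.kh_vitro is None:
            raise ValueError("kh_vitro (EMSA constraint) is required")
        missing = set(BOXES) - set(self.kh_vitro)
        if missing:
            raise ValueError(f"kh_vitro missing boxes {sorted(missing)}")

    def _count_params(self, lay: dict) -> int:
        k = len(lay["free_pairs"]) + 1  # eps + lambda
        k += len(lay["kin"]) * (len(TIME_GRID) + len(_NONREF))
        k += len(lay["th"]) * (len(TIME_GRID) + len(BOXES) + 1)
        return k

    def _bound_hits(self, theta: np.ndarray, lay: dict) -> list[str]:
        hits = []
        for name, val, (lo, hi) in zip(lay["names"], theta, lay["bounds"]):
            if min(val - lo, hi - val) < 1e-6 * (hi - lo):
                hits.append(name)
        return hits

    def _to_params(self, dec: dict, linear: dict, lay: dict) -> ScenarioParams:
        a = {}
        rho = {}
        eta = {}
        vms = {}
        for p in lay["kin"]:
            a[p] = linear["A"][p]
            rho[p] = {c: float(linear["rho"][p][i]) for i, c in enumerate(CONFIGS)}
            rho[p]["000"] = 1.0
        for p in lay["th"]:
            a[p] = dec["R"][p]
            eta[p] = {b: float(dec["eta"][p][i]) for i, b in enumerate(BOXES)}
            vms[p] = linear["v"][p]
        return ScenarioParams(
            scenario=self.scenario,
            binding=linear["binding"],
            a=a,
            rho=rho,
            eta=eta,
            vmax_scale=vms,
        )


def fit_scenario(
    data: pd.DataFrame,
    emsa_constraints: tuple[Mapping[str, float], int],
    scenario: str,
    signal: Signal0AP,
    seed: int | None = None,
    **options,
) -> FitResult:
    """Fit one scenario; thin wrapper over :class:`PromoterScenarioModel`."""
    kh_vitro, n = emsa_constraints
    model = PromoterScenarioModel(
        scenario=scenario, kh_vitro=dict(kh_vitro), n=n, random_state=seed, **options
    )
    model.fit(data, signal=signal)
    return model.result_


def fit_constrained_interactions(
    data: pd.DataFrame,
    emsa_constraints: tuple[Mapping[str, float], int],
    zero_set: Iterable[tuple[str, str]],
    scenario: str = "KK",
    signal: Signal0AP | None = None,
    seed: int | None = None,
    **options,
) -> FitResult:
    """Refit with the listed pair energies pinned to zero (nesting tests)."""
    return fit_scenario(
        data,
        emsa_constraints,
        scenario,
        signal=signal,
        seed=seed,
        zero_eps=tuple(zero_set),
        **options,
    )


def compare_scenarios(results: Iterable[FitResult]) -> list[FitResult]:
    """Rank fits by total error E ascending.

    Ties break toward fewer effective parameters, then the fixed scenario
    order KK, KT, TK, TT; the ranking is invariant to input order.
    """
    order = {s: i for i, s in enumerate(SCENARIOS)}
    return sorted(
        results, key=lambda r: (r.objective.e, r.k_params, order[r.scenario])
    )
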
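"""In-vitro 0A~P binding model and EMSA curve fitting.

A single 0A box binds N molecules of 0A~P as one mass-action event, giving
the Hill-type bound fraction

    f(c) = c^N / (Kh^N + c^N),

where Kh is the concentration at which the box is occupied with 50%
probability.  Gel-shift (EMSA) titrations quantify the fraction of DNA
fragments shifted at each 0A~P concentration; for fragments carrying several
boxes the observable is the probability that at least one box is bound,
computed from the box-state partition function.  Replicate uncertainty is
propagated by a parametric bootstrap: each (fragment, concentration) point
is resampled from a truncated normal law around the replicate mean, and the
Hill fit is repeated on every augmented dataset to yield percentile
confidence intervals.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .params import BOXES, BindingParams, canonical_label, label_to_boxes
from .promoter import box_occupancy

__all__ = [
    "fraction_bound_single",
    "fraction_bound_multi",
    "augment_dataset",
    "fit_kh",
    "select_cooperativity",
    "HillBindingModel",
    "EmsaKhEstimator",
    "CooperativitySelector",
]

EMSA_COLUMNS = ("box_subset", "conc_uM", "replicate", "frac_bound")


def fraction_bound_single(conc, kh: float, n: int):
    """Fraction of a single 0A box bound at 0A~P concentration ``conc``.

    Implements f = conc^n / (kh^n + conc^n); strictly increasing in conc,
    equal to 1/2 at conc = kh, and -> 1 as conc -> infinity.
    """
    if not np.isfinite(kh) or kh <= 0:
        raise ValueError(f"kh must be positive, got {kh}")
    if int(n) != n or n < 1:
        raise ValueError(f"n must be an integer >= 1, got {n}")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("conc must be non-negative")
    ratio = (c / kh) ** int(n)
    out = ratio / (1.0 + ratio)
    return float(out) if np.isscalar(conc) else out


def fraction_bound_multi(subset: Iterable[str], params: BindingParams, conc):
    """Fraction of DNA fragments with at least one box of ``subset`` bound.

    Any occupied box shifts the fragment in the gel, so the observable is
    1 - P(all boxes unbound), taken from the box-state partition function.
    With all pair energies zero this reduces to
    1 - prod_i (1 - f_single(conc, Kh_i, N)).
    """
    boxes = tuple(subset)
    if not boxes:
        raise ValueError("subset must contain at least one box")
    scalar = np.isscalar(conc)
    c = np.atleast_1d(np.asarray(conc, dtype=float))
    out = np.array(
        [1.0 - box_occupancy(ci, params, present=boxes)["000"] for ci in c]
    )
    return float(out[0]) if scalar else out


def _validate_emsa(data: pd.DataFrame) -> pd.DataFrame:
    missing = set(EMSA_COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"EMSA table missing columns {sorted(missing)}")
    df = data.copy()
    df["box_subset"] = df["box_subset"].map(canonical_label)
    if (df["box_subset"] == "none").any():
        raise ValueError("EMSA rows must reference at least one box")
    if (df["conc_uM"] < 0).any():
        raise ValueError("conc_uM must be non-negative")
    if ((df["frac_bound"] < 0) | (df["frac_bound"] > 1)).any():
        raise ValueError("frac_bound must lie in [0, 1]")
    return df


def augment_dataset(
    data: pd.DataFrame,
    n_augment: int,
    seed: int | None = None,
    fallback_rel_sd: float = 0.05,
) -> list[pd.DataFrame]:
    """Parametric bootstrap resampling of an EMSA table.

    For every (box_subset, concentration) point the replicate mean and SD
    define a normal law truncated to [0, 1]; each augmented dataset draws one
    value per point.  Points with a single replicate (undefined SD) fall back
    to ``fallback_rel_sd`` times the mean.  Deterministic given ``seed``.
    """
    if n_augment < 1:
        raise ValueError("n_augment must be >= 1")
    df = _validate_emsa(data)
    g = df.groupby(["box_subset", "conc_uM"])["frac_bound"]
    base = g.agg(["mean", "std", "count"]).reset_index()
    sd = base["std"].to_numpy()
    mean = base["mean"].to_numpy()
    sd = np.where(np.isnan(sd), fallback_rel_sd * mean, sd)

    rng = np.random.default_rng(seed)
    values = np.empty((n_augment, len(base)))
    zero = sd <= 0
    values[:, zero] = mean[zero]
    if (~zero).any():
        a = (0.0 - mean[~zero]) / sd[~zero]
        b = (1.0 - mean[~zero]) / sd[~zero]
        values[:, ~zero] = stats.truncnorm.rvs(
            a, b, loc=mean[~zero], scale=sd[~zero],
            size=(n_augment, int((~zero).sum())), random_state=rng,
        )
    out = []
    for k in range(n_augment):
        out.append(
            pd.DataFrame(
                {
                    "box_subset": base["box_subset"],
                    "conc_uM": base["conc_uM"],
                    "replicate": 1,
                    "frac_bound": values[k],
                }
            )
        )
    return out


def _initial_kh(conc: np.ndarray, frac: np.ndarray) -> float:
    """Crude Kh guess: concentration nearest half occupancy."""
    pos = conc[conc > 0]
    if pos.size == 0:
        return 1.0
    i = int(np.argmin(np.abs(frac - 0.5)))
    return float(conc[i]) if conc[i] > 0 else float(np.median(pos))


def _fit_single_kh(conc: np.ndarray, frac: np.ndarray, n: int) -> tuple[float, bool]:
    """Least-squares Hill fit of one box (log-Kh parameterization)."""

    def resid(logkh: np.ndarray) -> np.ndarray:
        return fraction_bound_single(conc, float(np.exp(logkh[0])), n) - frac

    x0 = np.log(_initial_kh(conc, frac))
    sol = optimize.least_squares(resid, np.array([x0]), method="lm")
    return float(np.exp(sol.x[0])), bool(sol.success)


def _single_box_means(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Replicate means of the single-box titrations, keyed by box name."""
    out = {}
    for label, sub in df.groupby("box_subset"):
        if len(label) == 1:
            box = label_to_boxes(label)[0]
            out[box] = (
                sub.groupby("conc_uM")["frac_bound"].mean().reset_index()
            )
    return out


def fit_kh(
    data: pd.DataFrame,
    n: int = 4,
    n_augment: int = 1000,
    seed: int | None = None,
    fallback_rel_sd: float = 0.05,
) -> dict:
    """Estimate per-box Kh with bootstrap 95% confidence intervals.

    The point estimate is a least-squares fit of the single-box Hill curve to
    the replicate means; the interval is the 2.5/97.5 percentile band over
    ``n_augment`` fits to augmented (resampled) datasets.  A warning is
    recorded if more than 10% of augmented fits fail to converge.
    """
    df = _validate_emsa(data)
    means = _single_box_means(df)
    if not means:
        raise ValueError("no single-box subsets found in the EMSA data")

    result: dict = {"n": int(n), "n_augment": int(n_augment), "seed": seed,
                    "boxes": {}, "warnings": []}
    single = df[df["box_subset"].str.len() == 1]
    augmented = augment_dataset(single, n_augment, seed=seed,
                                fallback_rel_sd=fallback_rel_sd)
    boot: dict[str, list[float]] = {b: [] for b in means}
    failures = {b: 0 for b in means}
    for aug in augmented:
        for box, tab in _single_box_means(aug).items():
            kh, ok = _fit_single_kh(
                tab["conc_uM"].to_numpy(), tab["frac_bound"].to_numpy(), n
            )
            if ok:
                boot[box].append(kh)
            else:
                failures[box] += 1
    for box, tab in means.items():
        kh, ok = _fit_single_kh(
            tab["conc_uM"].to_numpy(), tab["frac_bound"].to_numpy(), n
        )
        lo, hi = np.percentile(boot[box], [2.5, 97.5])
        result["boxes"][box] = {
            "kh_uM": kh,
            "ci95_low": float(lo),
            "ci95_high": float(hi),
        }
        fail_frac = failures[box] / n_augment
        if not ok or fail_frac > 0.10:
            msg = f"{box}: {fail_frac:.0%} of augmented fits failed to converge"
            result["warnings"].append(msg)
            warnings.warn(msg, stacklevel=2)
    return result


def select_cooperativity(
    data: pd.DataFrame, candidates: Iterable[int] = (1, 2, 3, 4, 5, 6)
) -> tuple[int, dict[int, float]]:
    """Choose the stoichiometric coefficient N by refitting each candidate.

    Returns the candidate with the lowest summed squared error on the
    single-box replicate means (ties broken toward the smaller N) together
    with the per-candidate errors.
    """
    cands = sorted(set(int(c) for c in candidates))
    if not cands:
        raise ValueError("candidates must be non-empty")
    df = _validate_emsa(data)
    means = _single_box_means(df)
    if not means:
        raise ValueError("no single-box subsets found in the EMSA data")
    errors: dict[int, float] = {}
    for n in cands:
        sse = 0.0
        for tab in means.values():
            conc = tab["conc_uM"].to_numpy()
            frac = tab["frac_bound"].to_numpy()
            kh, _ = _fit_single_kh(conc, frac, n)
            sse += float(np.sum((fraction_bound_single(conc, kh, n) - frac) ** 2))
        errors[n] = sse
    best = min(cands, key=lambda n: (errors[n], n))
    return best, errors


class HillBindingModel(RegressorMixin, BaseEstimator):
    """Single-site Hill binding curve with fixed cooperativity.

    Parameters
    ----------
    n : int, default=4
        Stoichiometric coefficient (number of ligand molecules per event).

    Attributes
    ----------
    kh_ : float
        Fitted half-saturation concentration (uM).
    """

    def __init__(self, n: int = 4):
        self.n = n

    def fit(self, X, y):
        conc = np.asarray(X, dtype=float).reshape(-1)
        frac = np.asarray(y, dtype=float).reshape(-1)
        if conc.shape != frac.shape:
            raise ValueError("X and y must have the same length")
        self.kh_, self.converged_ = _fit_single_kh(conc, frac, self.n)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "kh_")
        conc = np.asarray(X, dtype=float).reshape(-1)
        return fraction_bound_single(conc, self.kh_, self.n)


class EmsaKhEstimator(BaseEstimator):
    """Per-box Kh estimation with bootstrap confidence intervals.

    Fits the single-box Hill model to every single-box titration in a tidy
    EMSA table (columns box_subset, conc_uM, replicate, frac_bound) and
    attaches percentile intervals from fits to augmented datasets.
    """

    def __init__(
        self,
        n: int = 4,
        n_augment: int = 1000,
        fallback_rel_sd: float = 0.05,
        random_state: int | None = None,
    ):
        self.n = n
        self.n_augment = n_augment
        self.fallback_rel_sd = fallback_rel_sd
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        self.result_ = fit_kh(
            X,
            n=self.n,
            n_augment=self.n_augment,
            seed=self.random_state,
            fallback_rel_sd=self.fallback_rel_sd,
        )
        self.kh_ = {b: v["kh_uM"] for b, v in self.result_["boxes"].items()}
        self.ci_ = {
            b: (v["ci95_low"], v["ci95_high"])
            for b, v in self.result_["boxes"].items()
        }
        return self

    def binding_params(self) -> BindingParams:
        """Fitted in-vitro parameters (pair energies fixed to zero)."""
        check_is_fitted(self, "kh_")
        return BindingParams(n=self.n, kh=self.kh_)


class CooperativitySelector(BaseEstimator):
    """Model selection over candidate stoichiometric coefficients."""

    def __init__(self, candidates: Sequence[int] = (1, 2, 3, 4, 5, 6)):
        self.candidates = candidates

    def fit(self, X: pd.DataFrame, y=None):
        self.n_, self.errors_ = select_cooperativity(X, self.candidates)
        return self
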
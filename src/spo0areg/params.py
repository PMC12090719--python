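"""Shared domain types for the *spo0A* regulatory models.

The *spo0A* locus in *Bacillus subtilis* is transcribed from two promoters —
an upstream vegetative promoter Pv (sigma-A RNAP) and a downstream
sporulation promoter Ps (sigma-H RNAP) — and carries three modelled binding
sites for phosphorylated Spo0A (0A~P): the 0A1, 0A2 and 0A3 boxes.  This
module defines the containers every other module shares: binding parameters,
box configurations, strain specifications, the 0A~P input signal, and the
per-scenario promoter parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

#: Modelled 0A boxes, in locus order.  The fourth box (0A4) overlaps the Ps
#: -10 element and is outside the model's scope.
BOXES: tuple[str, ...] = ("0A1", "0A2", "0A3")

#: Unordered box pairs, canonical order.
PAIRS: tuple[tuple[str, str], ...] = (
    ("0A1", "0A2"),
    ("0A1", "0A3"),
    ("0A2", "0A3"),
)

#: Promoter cohorts of the reporter panel: both promoters intact, Pv only,
#: Ps only.
COHORTS: tuple[str, ...] = ("PvPs", "Pv", "Ps")

PROMOTERS: tuple[str, ...] = ("Pv", "Ps")

#: Canonical intact-box labels; "none" means every box mutated away.
LABELS: tuple[str, ...] = ("none", "1", "2", "3", "12", "13", "23", "123")

#: The eight box-binding configurations.  Digits left to right correspond to
#: (0A1, 0A2, 0A3); "1" marks a bound box.
CONFIGS: tuple[str, ...] = tuple(format(i, "03b") for i in range(8))

#: Measurement grid: hourly from 2 h (onset of starvation) to 9 h.
TIME_GRID: np.ndarray = np.arange(2.0, 10.0)

#: Regulatory scenarios.  First letter = Pv control, second = Ps control;
#: K = kinetic (configuration-dependent vmax), T = thermodynamic
#: (TF-RNAP interaction energies acting on RNAP occupancy).
SCENARIOS: tuple[str, ...] = ("KK", "KT", "TK", "TT")

_CONFIG_ARRAY = np.array([[int(d) for d in c] for c in CONFIGS], dtype=float)


def config_array() -> np.ndarray:
    """(8, 3) matrix of box states; row i is ``CONFIGS[i]``."""
    return _CONFIG_ARRAY.copy()


def canonical_label(label: object) -> str:
    """Normalize an intact-box label ("31" -> "13", "" -> "none")."""
    s = str(label).strip()
    if s.lower() in ("", "none"):
        return "none"
    digits = sorted(set(s))
    if not all(d in "123" for d in digits) or len(digits) != len(s):
        raise ValueError(f"invalid box label: {label!r}")
    return "".join(digits)


def label_to_boxes(label: str) -> tuple[str, ...]:
    """Map a label such as "13" to the box names ("0A1", "0A3")."""
    lab = canonical_label(label)
    if lab == "none":
        return ()
    return tuple(f"0A{d}" for d in lab)


def boxes_to_label(boxes: Iterable[str]) -> str:
    digits = sorted(b[-1] for b in boxes)
    return "".join(digits) if digits else "none"


def boxes_to_mask(boxes: Iterable[str]) -> np.ndarray:
    """Boolean (3,) mask over BOXES marking which boxes are present."""
    present = set(boxes)
    unknown = present - set(BOXES)
    if unknown:
        raise ValueError(f"unknown boxes: {sorted(unknown)}")
    return np.array([b in present for b in BOXES], dtype=bool)


def _norm_pair(pair: Iterable[str]) -> tuple[str, str]:
    a, b = sorted(pair)
    if (a, b) not in PAIRS:
        raise ValueError(f"invalid box pair: {(a, b)}")
    return (a, b)


@dataclass(frozen=True)
class BindingParams:
    """Equilibrium binding parameters of 0A~P to the 0A boxes.

    Parameters
    ----------
    n
        Stoichiometric (cooperativity) coefficient: number of 0A~P molecules
        binding a box as a single event.  The in-vitro fits infer a tetramer
        (n = 4).
    kh
        Half-saturation concentration per box, in uM.  Lower Kh means higher
        affinity.
    eps
        Pairwise box-box interaction energies in kT units; negative values
        are attractive (statistical weight factor exp(-eps)).  Defaults to
        zero, the in-vitro assumption.
    n0a
        Cooperativity exponent used in vivo; defaults to ``n``.
    """

    n: int
    kh: Mapping[str, float]
    eps: Mapping[tuple[str, str], float] = field(default_factory=dict)
    n0a: int | None = None

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise ValueError(f"cooperativity n must be an integer >= 1, got {self.n}")
        object.__setattr__(self, "n", int(self.n))
        kh = {str(k): float(v) for k, v in dict(self.kh).items()}
        unknown = set(kh) - set(BOXES)
        if unknown:
            raise ValueError(f"unknown boxes in kh: {sorted(unknown)}")
        if any(v <= 0 or not np.isfinite(v) for v in kh.values()):
            raise ValueError("all Kh must be positive and finite")
        object.__setattr__(self, "kh", kh)
        eps = {_norm_pair(p): float(v) for p, v in dict(self.eps).items()}
        object.__setattr__(self, "eps", eps)
        if self.n0a is not None:
            if int(self.n0a) != self.n0a or self.n0a < 1:
                raise ValueError("n0a must be an integer >= 1")
            object.__setattr__(self, "n0a", int(self.n0a))

    @property
    def effective_n0a(self) -> int:
        return self.n if self.n0a is None else self.n0a

    def kh_array(self) -> np.ndarray:
        try:
            return np.array([self.kh[b] for b in BOXES], dtype=float)
        except KeyError as exc:  # pragma: no cover - guarded upstream
            raise KeyError(f"missing Kh for box {exc}") from exc

    def eps_matrix(self) -> np.ndarray:
        """(3, 3) symmetric matrix of pair energies (zero diagonal)."""
        m = np.zeros((3, 3))
        idx = {b: i for i, b in enumerate(BOXES)}
        for (a, b), v in self.eps.items():
            m[idx[a], idx[b]] = v
            m[idx[b], idx[a]] = v
        return m

    def with_kh(self, kh: Mapping[str, float]) -> "BindingParams":
        return BindingParams(n=self.n, kh=kh, eps=self.eps, n0a=self.n0a)


@dataclass(frozen=True)
class StrainSpec:
    """One reporter strain: promoter cohort x subset of intact boxes."""

    cohort: str
    label: str

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")
        object.__setattr__(self, "label", canonical_label(self.label))

    @property
    def boxes(self) -> tuple[str, ...]:
        return label_to_boxes(self.label)

    @property
    def mask(self) -> np.ndarray:
        return boxes_to_mask(self.boxes)

    @property
    def promoters(self) -> tuple[str, ...]:
        return PROMOTERS if self.cohort == "PvPs" else (self.cohort,)


def all_strains() -> tuple[StrainSpec, ...]:
    """The full 24-strain panel (3 cohorts x 8 box subsets)."""
    return tuple(StrainSpec(c, l) for c in COHORTS for l in LABELS)


@dataclass(frozen=True)
class Signal0AP:
    """A 0A~P concentration time series on the measurement grid (uM)."""

    times: np.ndarray
    conc: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.ndim != 1 or c.shape != t.shape:
            raise ValueError("times and conc must be 1-D arrays of equal length")
        if np.any(c < 0):
            raise ValueError("0A~P concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)

    def index_of(self, t: float) -> int:
        hits = np.nonzero(np.isclose(self.times, t, atol=1e-9))[0]
        if hits.size == 0:
            raise ValueError(f"timepoint {t} not on the signal grid {self.times}")
        return int(hits[0])

    def conc_at(self, t: float) -> float:
        return float(self.conc[self.index_of(t)])

    def covers(self, times: np.ndarray) -> bool:
        return all(np.any(np.isclose(self.times, t, atol=1e-9)) for t in times)


@dataclass(frozen=True)
class ScenarioParams:
    """Full parameter set of one regulatory scenario.

    For a kinetically controlled promoter ``p`` the entries are

    * ``a[p]`` — effective promoter activity scale per timepoint,
      P(RNAP bound) * vmax("000"), in reporter units / h (only this product
      is identifiable from reporter data);
    * ``rho[p]`` — per-configuration maximum-initiation-rate ratio
      vmax(config)/vmax("000"), with rho["000"] = 1.

    For a thermodynamically controlled promoter the entries are

    * ``a[p]`` — the RNAP occupancy ratio R(t) = [RNAP]/K_P per timepoint;
    * ``eta[p]`` — TF-RNAP interaction energy per box (kT);
    * ``vmax_scale[p]`` — the single configuration-independent vmax.
    """

    scenario: str
    binding: BindingParams
    a: Mapping[str, np.ndarray]
    rho: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    eta: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    vmax_scale: Mapping[str, float] = field(default_factory=dict)
    times: np.ndarray = field(default_factory=lambda: TIME_GRID.copy())

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        a = {p: np.asarray(v, dtype=float) for p, v in dict(self.a).items()}
        for p in PROMOTERS:
            if p not in a:
                raise ValueError(f"missing a[{p!r}]")
            if a[p].shape != times.shape:
                raise ValueError(f"a[{p!r}] must match the time grid")
            if np.any(a[p] < 0):
                raise ValueError(f"a[{p!r}] must be non-negative")
        object.__setattr__(self, "a", a)

        rho = {p: {str(c): float(x) for c, x in dict(m).items()}
               for p, m in dict(self.rho).items()}
        eta = {p: {str(b): float(x) for b, x in dict(m).items()}
               for p, m in dict(self.eta).items()}
        vms = {p: float(v) for p, v in dict(self.vmax_scale).items()}
        for p in PROMOTERS:
            if self.control(p) == "K":
                r = rho.get(p)
                if r is None:
                    raise ValueError(f"kinetic promoter {p} requires rho[{p!r}]")
                missing = set(CONFIGS) - set(r)
                if missing:
                    raise ValueError(f"rho[{p!r}] missing configs {sorted(missing)}")
                if not np.isclose(r["000"], 1.0):
                    raise ValueError(f'rho[{p!r}]["000"] must be 1')
                if any(v < 0 for v in r.values()):
                    raise ValueError(f"rho[{p!r}] must be non-negative")
                if p in eta and any(v != 0 for v in eta[p].values()):
                    raise ValueError(f"kinetic promoter {p} must have eta == 0")
            else:
                if p in rho and any(not np.isclose(v, 1.0) for v in rho[p].values()):
                    raise ValueError(f"thermodynamic promoter {p} must have rho == 1")
                e = eta.get(p)
                if e is None or set(e) != set(BOXES):
                    raise ValueError(f"thermodynamic promoter {p} requires eta per box")
                if p not in vms or vms[p] < 0:
                    raise ValueError(f"thermodynamic promoter {p} requires vmax_scale >= 0")
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "eta", eta)
        object.__setattr__(self, "vmax_scale", vms)

    def control(self, promoter: str) -> str:
        """Control mode of a promoter: "K" (kinetic) or "T" (thermodynamic)."""
        if promoter == "Pv":
            return self.scenario[0]
        if promoter == "Ps":
            return self.scenario[1]
        raise ValueError(f"unknown promoter {promoter!r}")

    def rho_vector(self, promoter: str) -> np.ndarray:
        """(8,) vector of vmax ratios over CONFIGS (all ones if thermodynamic)."""
        if self.control(promoter) == "T":
            return np.ones(len(CONFIGS))
        r = self.rho[promoter]
        return np.array([r[c] for c in CONFIGS], dtype=float)

    def eta_vector(self, promoter: str) -> np.ndarray:
        """(3,) vector of TF-RNAP energies over BOXES (zeros if kinetic)."""
        if self.control(promoter) == "K":
            return np.zeros(len(BOXES))
        e = self.eta[promoter]
        return np.array([e[b] for b in BOXES], dtype=float)
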
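"""Brute-force enumeration reference for the promoter model.

Computes the effective transcription rate by explicit iteration over every
joint (box configuration, RNAP occupancy) microstate with plain Python
arithmetic and no algebraic shortcuts.  Serves as the independent check that
the vectorized partition-function code in :mod:`spo0areg.promoter` sums the
same states.
"""

from __future__ import annotations

import itertools
import math

from .params import BOXES, CONFIGS, PAIRS, ScenarioParams, StrainSpec


def _config_weight_loop(state: tuple[int, ...], conc: float, params: ScenarioParams) -> float:
    b = params.binding
    w = 1.0
    for i, box in enumerate(BOXES):
        if state[i]:
            w *= (conc / b.kh[box]) ** b.effective_n0a
    for (x, y) in PAIRS:
        i, j = BOXES.index(x), BOXES.index(y)
        if state[i] and state[j]:
            w *= math.exp(-b.eps.get((x, y), 0.0))
    return w


def enumeration_oracle(
    strain: StrainSpec, params: ScenarioParams, conc: float, t: float
) -> float:
    """veff by exhaustive joint-state enumeration (reference implementation)."""
    t_idx = None
    for i, tt in enumerate(params.times):
        if abs(tt - t) < 1e-9:
            t_idx = i
            break
    if t_idx is None:
        raise ValueError(f"timepoint {t} outside the model grid")

    present = set(strain.boxes)
    promoters = list(strain.promoters)
    thermo = [p for p in promoters if params.control(p) == "T"]

    num = 0.0
    den = 0.0
    for state in itertools.product((0, 1), repeat=len(BOXES)):
        # mutated boxes cannot be bound
        if any(s and BOXES[i] not in present for i, s in enumerate(state)):
            continue
        w_box = _config_weight_loop(state, conc, params)
        config = "".join(str(s) for s in state)
        for rnap in itertools.product((0, 1), repeat=len(thermo)):
            w = w_box
            rate = 0.0
            for p, r in zip(thermo, rnap):
                if r:
                    b = params.a[p][t_idx]
                    for i, box in enumerate(BOXES):
                        if state[i]:
                            b *= math.exp(-params.eta[p][box])
                    w *= b
                    rate += params.vmax_scale[p]
            for p in promoters:
                if params.control(p) == "K":
                    rate += params.a[p][t_idx] * params.rho[p][config]
            num += w * rate
            den += w
    return num / den
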
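# spo0areg

Statistical-thermodynamic models of *spo0A* dual-promoter autoregulation in
starving *Bacillus subtilis*.

Spo0A is the master regulator of sporulation and biofilm formation. Its
gene is transcribed from two promoters — the vegetative Pv (σ^A^-RNAP) and
the sporulation promoter Ps (σ^H^-RNAP) — and carries three binding sites
(0A boxes 0A1–0A3) for the active phosphorylated form, 0A~P, forming a
transcriptional feedback loop. This package is for quantitative
microbiologists and modellers who want to dissect such multi-site,
multi-promoter loops from reporter panels: it infers *which transcription
step* 0A~P binding regulates (RNAP recruitment vs post-recruitment
initiation) and *how strongly* each box and box combination acts.

## The models

**Binding (in vitro).** A box binds N molecules of 0A~P as one event; the
bound fraction is the Hill form f(c) = c^N / (Kh^N + c^N), with Kh the
half-saturation concentration. Multi-box fragments are predicted without
extra parameters from the box-state partition function with weights
W(s) = Π_i (c/Kh_i)^(N·s_i) · Π_{i<j} e^(−ε_ij s_i s_j). Kh confidence
intervals come from 1000 fits to bootstrap-augmented titrations; N is
selected by refitting candidate stoichiometries.

**Transcription.** The effective rate is the occupancy-weighted sum of
maximum initiation rates over promoter-bound states,
veff = Σ_α vmax_α · P_α. Each promoter is either *kinetically* controlled
(bound 0A~P rescales vmax by a per-configuration ratio ρ(s); RNAP occupancy
enters as a free per-timepoint activity A(t)) or *thermodynamically*
controlled (vmax constant; bound 0A~P shifts RNAP occupancy through per-box
interaction energies η). Four scenarios (KK, KT, TK, TT) are fitted to all
24 strains (3 cohorts × 8 box subsets × 8 hourly timepoints) by minimizing
the summed mean squared relative error E = Ev + Es + Evs, with in-vivo Kh
constrained to λ·Kh_vitro through one global scale λ. Purely kinetic
control makes dual-promoter activity exactly additive — the property the
experimental data display — and the fits select it.

See `docs/methods.md` for the full model, fitting scheme and assumptions.

## Worked example

```python
import spo0areg as s
from spo0areg.inference import PromoterScenarioModel

truth = s.GroundTruth(seed=0)              # synthetic study conditions
emsa = s.gen_emsa_dataset(truth, seed=5)   # 7 box-subset titrations, 0-2 uM
panel = s.gen_activity_panel(truth)        # 24-strain reporter panel, 5% CV

# 1. cooperativity and per-box affinities from the titrations
n, errors = s.select_cooperativity(emsa, candidates=range(1, 7))
kh = s.fit_kh(emsa, n=n, n_augment=100, seed=1)

# 2. fit the purely kinetic scenario under the EMSA constraint
model = PromoterScenarioModel(
    scenario="KK", kh_vitro={b: v["kh_uM"] for b, v in kh["boxes"].items()},
    n=n, restarts=2, de_maxiter=25, de_popsize=5, random_state=100,
)
model.fit(panel, signal=truth.signal())
print(model.objective_.e, model.lambda_, model.params_.binding.eps)
```

This prints (abridged):

```
selected N = 4, candidate errors {2: 0.229, 4: 0.0068, ...}
0A1: Kh=0.400 uM [0.382, 0.425]   0A2: 0.610 [0.570, 0.645]   0A3: 0.204 [0.199, 0.211]
E = 0.00233 (Ev 0.00086, Es 0.00058, Evs 0.00090), lambda = 0.515
eps = {0A1-0A2: -0.85, 0A1-0A3: -1.91, 0A2-0A3: -2.79}
```

A tetramer (N = 4) fits the titration steepness ~34-fold better than a
dimer here; the affinity ordering 0A3 > 0A1 > 0A2 (lower Kh = higher
affinity) is recovered with tight intervals; the scenario fit lands at a
few-percent relative error with all three box-box interactions attractive
and 0A2–0A3 the strongest, matching the generating truth. Downstream,
`regulation_strength` reports, e.g., the fully bound Ps strain 70.8% below
its box-free control (generating value −71.6%), and `saturation_time` shows
every box of the intact strain saturated by 4 h. `compare_scenarios` on all
four fitted scenarios ranks KK (purely kinetic) first on error.

The same pipeline runs from the shell:

```bash
spo0areg simulate --seed 1 --out sim/
spo0areg fit-emsa --data sim/emsa.csv --seed 1 --out emsa_fit.json
spo0areg fit-promoters --data sim/activities.csv --emsa emsa_fit.json \
    --scenario all --restarts 20 --seed 1 --out fits/
spo0areg compare-models --fits fits/fit_KK.json --fits fits/fit_TT.json \
    --fits fits/fit_KT.json --fits fits/fit_TK.json
spo0areg analyze --fit fits/fit_KK.json --out tables/
spo0areg collapse --data sim/activities.csv --out collapse.csv
```

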
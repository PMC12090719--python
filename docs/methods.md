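# Methods

## The system

The *Bacillus subtilis* sporulation master regulator Spo0A autoregulates its
own transcription. The *spo0A* locus is transcribed from two promoters — an
upstream vegetative promoter Pv read by σ^A^-RNAP and a downstream promoter
Ps read by σ^H^-RNAP — and carries three modelled binding sites (0A boxes:
0A1, 0A2, 0A3) for the active, phosphorylated form 0A~P. A fourth box (0A4)
overlaps the Ps −10 element and is outside scope: it cannot be mutated
without destroying the promoter, and the dual-promoter additivity of the
data argues its regulatory effect is negligible. The package models the
reporter panel built around this locus: three promoter cohorts (both
promoters, Pv only, Ps only) crossed with all eight subsets of intact boxes
— 24 strains, each measured hourly from 2 h (onset of starvation) to 9 h.

## In-vitro binding model

A box binds N molecules of 0A~P as one mass-action event, giving the bound
fraction f(c) = c^N / (Kh^N + c^N), where Kh is the half-saturation
concentration (µM); lower Kh means higher affinity. Gel-shift titrations of
fragments carrying one box identify Kh per box; fragments with several boxes
are predicted with no extra parameters by the box-state partition function,
with the observable taken as P(at least one box bound) — any occupied state
shifts the band. In-vitro pair interactions are fixed to zero; the
multi-box curves are then pure predictions from the single-box fits.

Replicate uncertainty is propagated by a parametric bootstrap: each
(fragment, concentration) point is resampled from a normal law with the
replicate mean and SD, truncated to [0, 1] (points with a single replicate
fall back to a configurable relative SD, default 5%). Kh is refit to each
of n_augment (default 1000) augmented datasets and the 2.5/97.5 percentiles
give the 95% interval. Fits are least squares on untransformed fractions in
a log-Kh parameterization (fractions are bounded and the noise roughly
homoscedastic over the assayed range); the measured concentration grid is
used as given, with no interpolation. Cooperativity is selected by
refitting every candidate N (default 1–6) and taking the lowest summed
squared error, ties toward the smaller N.

## Promoter model

Box configurations s ∈ {0,1}³ carry statistical weights

    W(s) = Π_i (c / Kh_i)^(N0A·s_i) · Π_{i<j} exp(−eps_ij)^(s_i s_j),

with W(000) = 1, energies in kT units and negative eps attractive. N0A, the
in-vivo cooperativity exponent, defaults to the EMSA N. Boxes mutated out
of a strain are forced unbound. The effective transcription rate is the
occupancy-weighted sum of maximum initiation rates over promoter-bound
states, with two control modes per promoter:

* **Kinetic (K)** — RNAP occupancy is not affected by 0A~P. Only the
  product P(RNAP bound)·vmax(000) is identifiable from reporter data, so it
  is fitted as one activity scale A(t) per promoter per timepoint, and each
  configuration rescales vmax by a ratio rho(s) (rho(000) = 1):
  veff = A(t) Σ_s P(s) rho(s).
* **Thermodynamic (T)** — vmax is configuration independent; bound 0A~P
  interacts with RNAP through one energy eta per box. The RNAP state
  r ∈ {0,1} enters the joint partition function with weight
  B(s,t) = R(t)·Π_i exp(−eta_i)^(s_i), where R(t) = [RNAP]/K_P, and
  veff = vmax_scale · P(r = 1).

Dual-promoter strains share the box state; each thermodynamically
controlled RNAP couples to it through its own eta terms and there is no
RNAP–RNAP interaction term (the data's additivity argues against
interference between the two polymerases). Purely kinetic control is then
*exactly* additive across promoters; thermodynamic control with nonzero eta
is not. Four scenarios arise from the two modes per promoter: KK, KT, TK,
TT (first letter Pv, second Ps). In every scenario the time dependence of
the RNAP term is carried by the per-timepoint values (A(t) or R(t)); the
thermodynamic vmax scale is constant.

All rate evaluations are closed-form partition-function sums over at most
8 × 2 × 2 joint states; an independent pure-Python enumeration oracle
recomputes them state by state and agrees to 1e−12 in the tests.

## Fitting

The objective is the mean squared relative residual per cohort,
E_i = (1/(L_i·T_i)) Σ (veff − X)²/X² with L_i = 8 strains, T_i = 8
timepoints and X the replicate-mean activity, summed as E = Ev + Es + Evs
(192 observations total). EMSA constraints enter through a single global
reconciliation scale λ: Kh_vivo,i = λ·Kh_vitro,i, preserving relative
affinities.

The parameter space splits into a nonlinear block — the three pair energies
eps, λ, and for thermodynamic promoters the three eta and eight R(t) values
— and a conditionally linear block — kinetic A(t) and rho, thermodynamic
vmax scales. The fitter is a variable-projection scheme: a seeded
differential-evolution search over the nonlinear block (λ and R in log10
space; bounds eps ∈ [−10, 5], λ ∈ [0.01, 100], eta ∈ [−10, 5],
R ∈ [10⁻³, 10³], rho ∈ [0, 5]) where every trial point profiles out the
linear block by weighted alternating least squares (the A/vmax step and the
rho step are each exact linear solves; a handful of sweeps converge because
the problem is bilinear). Restarts are independent seeded runs (default
20) and the best is reported together with the full per-restart error
trace, the seed, and flags for parameters at their bounds. An optional
monotonicity projection on A(t) exists but is off by default: the rising
RNAP dynamics are a result, not a constraint.

Nested interaction models are fit by pinning chosen eps pairs to zero and
compared by BIC = n·ln(SSR/n) + k·ln(n) under a Gaussian relative-error
likelihood, with k the count of unpinned parameters. The four scenarios
carry their natural parameter counts (KK 34, mixed 31, TT 28); scenario
ranking is by E ascending with ties broken by fewer parameters, then the
fixed tag order KK, KT, TK, TT.

## Synthetic study

The generator emulates the study conditions end to end and is the basis of
every recovery test. Defaults: N = 4 (tetramer); Kh_vitro = 0.4/0.6/0.2 µM
for 0A1/0A2/0A3 (affinity ordering 0A3 > 0A1 > 0A2); pair energies
−1.0/−1.2/−2.5 kT for 12/13/23 (0A2–0A3 most attractive); purely kinetic
control with mostly repressive Pv ratios (0A1 strongest) and a mixed Ps
pattern (0A3 and 0A1 activating alone, 0A2 repressing, the 23 combination
overriding 0A3's activation, rho_s(111) = 0.284 so the fully bound Ps
strain sits 71.6% below its box-free control at saturation); RNAP activity
rising 1.4-fold (Pv, from 100 units/h) and 10.8-fold (Ps, from 25 units/h)
over 2–9 h; 3 replicates at 5% CV multiplicative log-normal noise on
activities; 2 replicates with additive truncated-Gaussian SD 0.02 on EMSA
fractions over a 9-point 0–2 µM grid.

The 0A~P input is a logistic stand-in c(t) = c_max/(1+exp(−k(t−t0))) with
c_max = 1 µM, t0 = 4 h, k = 1/h. The reconciliation scale used by the
ground truth is λ = 0.5, chosen once so that, under this signal, every
box's marginal occupancy saturates by 9 h (the fully intact strain
saturates early through the attractive interactions) — the qualitative
regime the real system operates in.

What the generator does not emulate: growth-stage artifacts, non-stationary
replicate noise, day effects, partial gel shifts, any 0A4 contribution, or
feedback of expression onto the 0A~P input (the signal is exogenous).
Passing recovery tests therefore show the estimator is consistent under the
model's own assumptions with realistic noise, not that the biological
system satisfies them.

## Numerical choices and problem sizes

Zero concentration is handled by direct products (no logs), so W is exact
at c = 0. Occupancy normalization is safe because W(000) = 1 always.
Least-squares solves use LAPACK lstsq; solutions are clipped to their
physical boxes (A, vmax ≥ 0; rho ∈ [0, 5]). ALS stops on a 1e−12 relative
change in E. Fit determinism: all randomness flows from a single
integer seed through numpy Generators; the same seed reproduces a fit
bit for bit.

Test and acceptance runs use reduced optimizer budgets (2 restarts,
differential-evolution popsize 5, 25 generations, 8 ALS sweeps) — chosen as
the package's own fast profile after checking that recovery quality matches
the default budget on the reference conditions; production fits default to
20 restarts with a larger search. Recovery and model-selection checks use
10 independent seeds at the study conditions above.

## Known limitations

* The thermodynamic scenarios' R(t) and eta are only weakly identified from
  reporter data when occupancy saturates early; their fitted values should
  be read as effective, not structural.
* λ trades off against the signal's concentration scale; with a stand-in
  signal only the product is meaningful.
* The per-scenario parameter counts are a reconstruction (the modes differ
  in how many parameters they need); BIC comparisons across scenarios
  inherit that choice.
* Strength tables and saturation times are computed from the single best
  fit, not averaged over restarts or bootstrap replicates.
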
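# Methods

## The kinetic scheme

Macroscopic NMDAR currents are simulated from a five-state continuous-time
Markov scheme per channel, integrated as a master equation
dP/dt = Qᵀ(t)·P over the protocol:

```
          β·f([NMDA])            k_des
      C ──────────────► O ──────────────► D
      C ◄────────────── O ◄────────────── D
           α_close              k_rec

          k_on(Vm)·[ATL]         α_close
      O ──────────────► OB ──────────────► CB
      O ◄────────────── OB ◄────────────── CB
            k_off                β·f([NMDA])
                                          CB ──k_escape──► C
```

- **Activation** is lumped into a single concentration-dependent opening
  step, C→O at `beta_open_max·[NMDA]/([NMDA]+ec50_nmda)`, opposed by
  `alpha_close`. AP5 (competitive antagonist) sets the opening rate to zero
  whenever its effective concentration exceeds 0.5 µM — 1% of the applied
  50 µM. A strict "any AP5 > 0" rule would interact pathologically with the
  exchange lag (an exponential washout tail never reaches exactly zero).
- **Ca²⁺-dependent desensitization**, O→D, is proportional to a
  driving-force-scaled Ca²⁺-influx surrogate
  `Ca_out·max(0, E_rev − Vm)/(E_rev + 70)`, normalized to 1·Ca_out at
  −70 mV. ATL enhances the rate by the saturable factor
  `1 + ε·[ATL]/([ATL] + K_ATL)`. BAPTA-loaded cells multiply the whole rate
  by `bapta_factor` (Ca²⁺ acts from the cytosol; chelation suppresses the
  pathway).
- **Open-channel block**, O⇌OB, carries all of its voltage dependence on the
  on-rate, `k_on(Vm) = k_on0·exp(−δ·z·Vm/(RT/F))`, with a
  voltage-independent `k_off0`. The equilibrium constant therefore follows
  the Woodhull form K_d(Vm) = (k_off0/k_on0)·exp(δ·z·Vm·F/RT) exactly.
- **Trapping**: the blocked channel closes at the gating rate
  (OB→CB at `alpha_blocked`, default = `alpha_close`) and reopens at the
  agonist-dependent opening rate; the trapped blocker escapes the closed
  channel at `k_escape` (partial trapping; 0 = full trapping). Setting
  `alpha_blocked = 0` forbids closure while blocked — the sequential
  ("foot-in-the-door") scheme, whose macroscopic signature is a tail
  current on simultaneous agonist + blocker removal.

Current is `n_channels_gamma·(Vm − e_rev)·P(O)` (pA), optionally plus white
Gaussian noise of standard deviation `noise_sd` drawn from the given seed.

## Default parameters and calibration

| parameter | default | units | rationale |
|---|---|---|---|
| k_on0 | 0.0016/exp(0.51·70/25.7) ≈ 3.99e−4 | 1/(s·µM) | anchors k_on(−70 mV) to the measured 0.0016 |
| k_off0 | 0.204 | 1/s | measured unblock rate |
| delta_block, z_block | 0.51, 1 | — | measured electrical depth; monovalent cation |
| rt_over_f | 25.7 | mV | RT/F at room temperature |
| alpha_close | 10 | 1/s | deactivation ~100 ms after agonist removal; fast enough to trap the blocker without a tail |
| beta_open_max | 2400 | 1/s | open-biased gating (P_open ≈ 0.995 at 100 µM NMDA) so macroscopic block relaxations report the binding step to ≪1% |
| ec50_nmda | 20 | µM | NMDA potency |
| k_des0·ca_coupling | 1.0 | 1/(s·mM) | with k_rec = 0.5 1/s gives a desensitized/open ratio of 2·[Ca²⁺] at −70 mV |
| atl_des_gain (ε), atl_des_k | 2.0, 0.5 µM | — | calibrated so the stationary IC₅₀ at −70 mV spans ≈65 µM (0.25 mM Ca²⁺) to ≈0.6 µM (4 mM) |
| bapta_factor | 0.1 | — | BAPTA leaves ~10% residual desensitization; shifts IC₅₀(1 mM Ca²⁺) to ≈100 µM |
| k_escape | 0.25 | 1/s | escape visible over 0.5–4 s washouts |
| tau_exchange | 10 | ms | fast solution-exchange lag (first-order) |
| n_channels_gamma | 20 | pA/mV | ≈1.4 nA maximal inward current at −70 mV |

The gating numbers are *effective* macroscopic rates, not single-channel
estimates: the model's purpose is to reproduce the slow (blocker- and
desensitization-limited) relaxations that the analysis consumes, with
gating relegated to a fast, strongly open-biased equilibrium.

## What the generator emulates — and what it does not

The fixture generator (`fixtures.make_study_fixtures`) emulates per-cell
recordings for the study's condition families: ATL staircases at −70 mV
across bath Ca²⁺ (0.25–4 mM), staircases across holding voltage in low
Ca²⁺, two-concentration block/unblock steps, the trapping protocol across
washout durations, and BAPTA-loaded staircases. Cell-to-cell variability is
lognormal jitter on conductance (σ = 0.2) and on the kinetic rates
(σ = 0.05); recording noise is plain white Gaussian at the output sample
rate. Not modelled: the 8th-order 200 Hz low-pass of the acquisition chain,
capacitive transients, rundown, liquid-junction corrections, Mg²⁺ block,
and receptor-subtype heterogeneity. Passing tests therefore demonstrate
that the *estimators* recover known generating parameters under realistic
protocol structure and noise — not that the scheme is a complete model of
neuronal recordings.

Two fixture families deliberately run with desensitization disabled
(`k_des0 = 0`): relaxation kinetics and the trapping protocol. The
experiments they emulate were done in 0.25 mM Ca²⁺ precisely to isolate
block from desensitization; in the lumped scheme, recovery from D at
`k_rec` would otherwise contaminate the block relaxations and masquerade as
blocker escape in the test-pulse rise. For the same reason the trapping
fixtures use 1000 µM ATL (≈8×K_d(−70 mV)) so the trapped pool dominates the
test pulse; the protocol builder's default remains the nominal 200 µM.

## Numerical choices

- Integration: scipy `solve_ivp` (LSODA, analytic Jacobian) segment-by-
  segment between solution-change boundaries; rtol 1e−8, atol 1e−10 on
  occupancies. Effective concentrations follow the closed-form first-order
  lag toward each epoch's targets. Output occupancies are clipped of
  solver-tolerance-level negatives and renormalized per sample.
- Mono- and bi-exponential fits: unweighted least squares over the full
  relaxation (no robust loss), initial guesses from segment endpoints and
  the 1/e crossing; τ landing on a bound flags the fit. Bi-exponential
  components closer than 3× in τ are flagged degenerate (a single
  exponential describes the rise) and excluded from trapping-depth
  judgements.
- Hill fits are parameterized in log10(IC₅₀) with h ∈ [0.3, 4]; per-cell
  fits are averaged into condition means ± SEM (no pooled fit).
- The Woodhull fit is a straight line in log(IC₅₀) (the model is exactly
  linear there); the Ca²⁺-exponential is fit on the *linear* IC₅₀ scale —
  deliberately different, because that convention reproduces the published
  amplitude/e-fold pair from the published condition means. A clearly
  negative Woodhull slope (block weakening with hyperpolarization of a
  cationic blocker) raises a sign-convention error; |δ| < 0.05 is flagged
  voltage-independent rather than rejected.
- Steady-state windows: the final 20% of an epoch, excluding 3·τ_exchange
  guards at both edges, with a slope-based steadiness criterion.
- Trapping test-pulse fits start where the rising current magnitude first
  crosses the residual blocked level I_b, which makes the amplitude
  constraint C = I₁ + I₂ + I_b consistent with the first fitted sample.
- Tail detection: post-removal current exceeding the pre-removal steady
  state by 5% for ≥50 ms.
- Escape-rate model: f(t_AP5) = f∞ − (f∞ − f₀)·e^(−k·t_AP5) with f∞ ≤ 1;
  the monotone trend itself is judged by the 95% CI of a linear slope.

## Design decisions that were genuinely open

- Whether dose–response fits are pooled or per-cell is not dictated by the
  estimators; per-cell fits with condition means were chosen to mirror the
  per-cell scatter convention of the experimental summaries.
- Desensitized-blocked states are omitted: five states are the minimum that
  express the three mechanisms, and nothing in the analysis chain
  identifies a D·B state.
- The composite IC₅₀ surface at the low-ATL end is governed by the
  saturable desensitization-enhancement term; with a single half-max
  constant the simulated dose–response curves are shallower (effective
  h < 1) and the intermediate-Ca²⁺ IC₅₀s fall more steeply with Ca²⁺ than
  the published means. The surface's separable exponential form is still
  reproduced, and the published-mean refits are run on the published
  numbers themselves.
- The simulated slow test-pulse component is unblock-limited
  (τ_s ≈ 1/k_off ≈ 4.9 s); its invariance across washout durations — the
  scientifically meaningful property — holds, while its absolute value is
  smaller than the measured 11–15 s (which likely reflects slower agonist
  re-equilibration than the lumped activation step).

## Problem sizes

The test suite and analysis drivers use 2–5 simulated cells per condition,
5 staircase levels per cell, 20-seed replicate sets for recovery and
classification checks, and 10–100 seeds for null-calibration checks; the
full suite completes in a few minutes on one CPU. These sizes were chosen
as the smallest that keep SEMs meaningful and classification unambiguous.

## Known limitations

Single-channel (stochastic) behavior, Mg²⁺ block, permeation of the
blocker, agonist lock-in energetics, and GluN2A/GluN2B differences are out
of scope. The Ca²⁺-influx surrogate is linear in driving force and bath
Ca²⁺; real flux saturates. The model's Ca²⁺-dependent component acquires a
weak voltage dependence through the influx surrogate (δ ≈ 0.2 at 4 mM
Ca²⁺), whereas block contributes δ ≈ 0.5–0.9 depending on condition mix.
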
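# Methods

This note documents the models, the learning procedure, the numerical
choices and the limitations of `fluxrl`, in the spirit of a methods
section a maintainer can audit.

## Kinetic environments

### Fatty-acid / ACC process

Batch fermentation of engineered *E. coli* producing fatty acids via
inducible acetyl-CoA carboxylase (ACC).  States (all dimensionless):
glucose `S`, biomass `X*`, ACC `E`, malonyl-CoA `M`, LacI `R`, fatty
acid `P*`.  With growth rate `μ = kX·S·(1 − TX)`:

    dS/dt  = −μ X*
    dX*/dt = (μ − μd) X*
    dE/dt  = kE · KR0^nR / (KR0^nR + R_free^nR) − (dE + μ) E
    dM/dt  = kM E − kP M − μ M
    dR/dt  = kR1 − (dR + μ) R
    dP*/dt = kP M X* · S/(KSP + S) · (1 − TP)

where `R_free = R / (1 + (u/KI)^nI)` is the LacI pool not sequestered by
the inducer `u` (µM IPTG-equivalent, bounds [0, 1000]).  ACC toxicity
enters twice: `TX = TXmax·E^nTX/(KTX^nTX + E^nTX)` reduces growth, and
`TP = (E−Etox)^nTP / (KTP^nTP + (E−Etox)^nTP)` for `E ≥ Etox` (zero
below, continuous at the threshold) halts product formation once ACC
exceeds `Etox = 1`.  Observables: `X = HX·X*` (relative OD600),
`P = HP·P*` (g/L).  The nominal initial glucose is tied to biomass,
`S0 = 1 − X0*`.  The single growth-rate function `μ` is used wherever a
dilution term appears (it is the only growth rate the model defines).

### Lactate / ATPase process

Anaerobic lactate fermentation (Δ*adhE*, Δ*ackA-pta*) with
light-inducible F1-ATPase.  States: glucose `S`, biomass `X`, lactate
`L` (g/L) and ATPase `E` (virtual units per gram biomass).  Specific
rates:

    qS = qSmax · S/(S+kS) · (1 + E^n1/(E^n1 + kSV^n1))
    μ  = YXS (qS − mS) · (1 − E^n2/(E^n2 + kXV^n2))
    qL = YLX·μ + mL · S/(S+kLS) · (1 + E^n3/(E^n3 + kLV^n3))
    qE = qE0 + qEmax · u^n4/(u^n4 + kl^n4)

with `dS = −qS·X`, `dX = μ·X`, `dL = qL·X`, `dE = qE − kd·E`; input `u`
is green-light photon flux (µmol m⁻² s⁻¹, bounds [0, 873]).  Raising
ATPase raises ATP turnover, boosting uptake and lactate flux (up to
two-fold) while suppressing growth.  `kLS = 1e-10 g/L` gates the
non-growth-associated lactate term off under substrate starvation; it is
not part of the source kinetic model and is kept in the nominal set
deliberately.

Both parameter sets ship as versioned YAML files
(`src/fluxrl/data/*.yaml`) with per-field units; they are the single
source the models are built from.

## Episodes and domain randomization

Inputs are piecewise constant on an equidistant grid (25 × 1 h for
fatty acid; 11 intervals over 9.5 h for lactate).  Interval `t` covers
`[t·Δt, (t+1)·Δt)`; inputs are indexed 0..N−1 and states 0..N.

"X% uncertainty" means: once per episode, each targeted quantity `q` is
redrawn as `q + N(0, (X%·q)²)` — a zero-mean Gaussian with *relative*
standard deviation — independently per target, with negative draws
clamped to zero (targets with nominal value zero are therefore
unperturbed).  Default targets follow the case studies: all initial
conditions plus `kE`, `kR1` (fatty acid) or `qEmax` (lactate).  The
initial glucose of the fatty-acid process is randomized around its
nominal `1 − X0*` as an initial condition in its own right; this
independent law reproduces the published static-control spread (e.g.
1.38 ± 0.30 g/L at 25%) where re-deriving `S0` from the perturbed
biomass does not (it gives σ ≈ 0.22).

## Integration

Each interval is integrated with adaptive error control at
`rtol = 1e-6`, `atol = 1e-9`; states are clamped non-negative inside the
rate laws and after each interval (the dynamics cannot cross zero except
by integration noise).  The fatty-acid system is smooth and uses an
explicit Runge–Kutta pair (RK45).  The lactate system becomes stiff at
substrate exhaustion — for `S ≪ kS` the substrate equation has a local
decay rate `~qSmax·X/kS ≈ 1e5–1e6 h⁻¹` — so it defaults to LSODA, which
switches to a BDF method there.  A whole batch of episodes is stacked
into one block-diagonal ODE system and integrated together (LSODA is
told the Jacobian is banded with bandwidth `n_states − 1`), which is
what makes 500-episode epochs take fractions of a second.

Near-zero Hill exponents (`n1 = 0.01`) use the continuous extension
`0^n = 0`.

## Policy and gradient estimator

Features: the two most recent state–input pairs and a linear time
embedding `2t/(N−1) − 1`, each component affinely mapped to [−1, 1] and
clipped; at `t = 0` the missing pair repeats the initial state with a
zero input.  State normalization ranges default to 1.5× the maximum of
a deterministic static-control rollout (configurable); the mechanism the
published setups used is unstated, so this is a package choice.

The network (4 × 20 leaky-ReLU, slope 0.01) outputs two raw values
squashed by a logistic map: `m = lb + range·s(a)` and
`σ = σ_cap·(ε + (1−ε)·s(b))` with `σ_cap = 0.25·range` and `ε = 1e-9`
(the floor keeps σ strictly positive even when the logistic underflows).
Bounds therefore hold for *any* weights, by construction.  Actions are
sampled from the unclipped Gaussian; the applied input is clipped to the
bounds but the stored log-density is evaluated at the raw sample,
keeping the score-function estimator consistent with the distribution
actually sampled.  Gradients of `Σ_t log π` are exact reverse-mode
derivatives of this computation, implemented directly in numpy (the
network is tiny) and verified against central finite differences to
better than 1e-4 relative error.

Returns are normalized within each epoch by the population standard
deviation plus `ε_mach = 1e-8` (so a fully deterministic epoch yields a
zero update, not 0/0).  One ascent step per epoch uses Adam by default;
plain gradient ascent is available for the analytic oracle tests.

Two stabilization choices matter and are deliberate (neither the weight
initialization nor the optimizer is specified by the reference setups):

* the output layer is initialized at 0.1× its He scale, so every fresh
  policy starts near the mid-range mean with σ ≈ σ_cap/2 instead of a
  randomly saturated head;
* Adam's first-moment decay is 0.5 rather than 0.9 — score-function
  gradients decorrelate quickly across epochs, and the heavier momentum
  made the policy mean overshoot through the high-return input region
  into a saturated corner of the squashed head, stalling roughly 40% of
  deterministic runs.  With both choices, training converged on every
  seed tried in all three benchmark settings.

## Training protocol

Reference setups: fatty acid — 350 epochs × 500 episodes, learning rate
0.0075; lactate — 500 epochs × 500 episodes, rate 0.001; both with
early stopping after 50 epochs without a strictly better mean return.
The test suite and the acceptance script run a reduced budget of
150 epochs × 200 episodes, which reaches mean titers within a percent
of the full-budget result (e.g. 2.29 g/L vs 2.30 at the full budget in
the deterministic fatty-acid case).  Every epoch's
parameter vector is snapshotted *before* its update, so the selected
policy is exactly the one that produced the best epoch-mean return.
All randomness descends from one master seed through a spawned seed
tree (policy init, then one stream per epoch covering disturbances and
actions), making runs bit-reproducible.

## Objectives and the golden batch

* `terminal_titer`: `J(τ) = P(t_N)` in g/L; all reward mass sits on the
  final interval (equivalent to the terminal objective, and it keeps
  the per-step reward slots well defined).
* `reference_tracking`: `J(τ) = −Σ_{t=1..N} (E_t − E_{r,t})²`.

The golden-batch ATPase reference is not tabulated anywhere, only
described as coming from open-loop optimization.  It is therefore
*constructed*: simulate the deterministic lactate model under a
bang-bang input (lower bound before a switch step, upper bound after)
and take the realized enzyme path; by default the switch step is chosen
by open-loop titer maximization over all switch positions.  On the
reference grid this lands at step 5 of 11 — midway through the batch —
with an open-loop final titer of 3.77 g/L and full substrate depletion.
Reproduction of the published dynamic-control lactate titer (3.81 g/L)
therefore carries reference-construction uncertainty of a few
hundredths of a g/L.

## Known discrepancies and limitations

* With the printed parameter tables, the deterministic lactate
  static-control baseline computes to **2.90 g/L**, not the published
  2.97 (−2.3%); the fatty-acid baseline matches (1.608 ≈ 1.61).  The
  final lactate titer is ~1% sensitive to the ratio of the ATPase
  steady state to `kLV` through the steep `n3 = 10` Hill term, so
  3–4-digit rounding of `kd`, `kLV`, `qEmax` or `kl` in the printed
  table plausibly accounts for the gap.  Randomized lactate
  static-control means inherit the same −0.07 g/L offset.
* The trained deterministic fatty-acid policy *rides* the toxicity
  threshold: product toxicity is zero at `Etox` and continuous above
  it, so the return-optimal enzyme trajectory saturates at `E ≈ 1.0`
  and transiently exceeds it by a few percent (max E ≈ 1.02–1.04 even
  at the full reference budget).  Statements that the policy keeps ACC strictly
  below the threshold should be read at plot resolution.
* Domain randomization emulates batch-to-batch parametric and inoculum
  variability only: disturbances are frozen within an episode, there is
  no intra-batch process noise, no measurement noise (full state
  observability), and no fed-batch or continuous operation.  Passing
  benchmarks therefore show robustness to *episode-level* uncertainty,
  not performance under real-time sensor noise.
* Evaluation reports the stochastic policy as trained (sampled
  actions); a converged policy is near-deterministic, so its
  deterministic (mean-action) evaluation differs only marginally.
* No value-function baseline, trust region or off-policy correction:
  the estimator is plain Monte-Carlo REINFORCE with return
  normalization, matching the reference method.
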
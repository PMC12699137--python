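# fluxrl

Policy-gradient reinforcement learning for **robust dynamic metabolic
control** of microbial bioprocesses.

Metabolic enzymes set the rates of the reactions they catalyze, so
modulating their expression in real time (with chemical or optogenetic
inducers) steers fluxes during a fermentation.  Static control — one
constant induction level — is simple but inflexible; excessive enzyme
expression can also arrest growth through cytotoxicity or ATP drain.
`fluxrl` derives *dynamic* induction policies by letting a
reinforcement-learning agent interact with a kinetic ODE model of the
process used as a surrogate environment, and makes those policies robust
to process variability by **domain randomization**: each training
episode perturbs initial conditions and key kinetic parameters with
zero-mean Gaussians whose standard deviation is a chosen fraction of the
nominal value.

The package is aimed at bioprocess and metabolic-engineering researchers
who want to prototype dynamic control strategies *in silico* before
committing to genetic-circuit and bioreactor experiments.

## Method

The process state `x_t` evolves over `N_x` control intervals,
`x_{t+1} = f(x_t, u_t, ω, d_t)`, realized by integrating a kinetic ODE
system with the scalar input `u_t` held constant on each interval.  A
feedforward network (4 hidden layers × 20 leaky-ReLU units) maps a
featurized state `s_t` — the two most recent state–input pairs plus a
time embedding, normalized to [−1, 1] — to a Gaussian over the input,

    m_t, σ_t = f_DNN(s_t, Θ),    u_t ~ N(m_t, σ_t²),

with `m_t` squashed into the input bounds and `σ_t` capped at 25% of the
input range.  Policy parameters ascend the Monte-Carlo policy gradient
(REINFORCE) with within-epoch return normalization:

    ∇_Θ E[J] ≈ (1/N_MC) Σ_k  (J(τ⁽ᵏ⁾) − J̄)/(σ_J + ε) · ∇_Θ Σ_t log π(u_t⁽ᵏ⁾ | s_t⁽ᵏ⁾, Θ).

The return `J(τ)` is either the final product titer (economic
objective) or the negative summed squared deviation of an enzyme
trajectory from a "golden-batch" reference (tracking objective).

Two fully parameterized *E. coli* case studies ship with the package:

* **fatty_acid** — fatty-acid synthesis with IPTG-inducible acetyl-CoA
  carboxylase (ACC) under LacI repression; ACC accumulation is
  cytotoxic (Hill-type toxicity of growth, and of product formation
  above a threshold `Etox`).
* **lactate** — anaerobic lactate fermentation with green-light-induced
  F1-ATPase; ATP wasting trades growth for lactate flux.

## Worked example

Simulate the static baselines and train a dynamic policy for the
fatty-acid process (a few seconds / a few minutes respectively):

```bash
$ fluxrl simulate --preset fatty_acid_paper --seed 0 --out runs/sc
final titer: 1.6079 g/L  return: 1.6079

$ fluxrl train --preset fatty_acid_paper --epochs 150 --episodes 200 \
      --seed 1 --out runs/dc
best epoch 61: mean return 2.2934 (early_stop)

$ fluxrl benchmark --preset fatty_acid_paper --levels 0,25 --episodes 500 \
      --checkpoints runs/dc/checkpoints/policy_best.json,runs/dc25/checkpoints/policy_best.json \
      --seed 1 --out runs/bench
```

The first number is the static-control (SC) baseline: constant 40 µM
IPTG-equivalent induction for 25 h yields 1.61 g/L fatty acid.  The
trained dynamic-control (DC) policy reaches a mean final titer of
2.29 g/L in the deterministic environment — roughly a 40% improvement —
by pushing induction high early and tapering it so the intracellular
ACC level rides just at the toxicity threshold instead of overshooting
it.  The same workflow with `--preset lactate_paper` trains a
golden-batch tracking policy that switches induction on midway through
the batch, reaching ≈3.7–3.8 g/L lactate versus 2.90 g/L under full
static induction.

The same functionality is available as a library:

```python
import numpy as np, fluxrl as fx

model = fx.fatty_acid_model()
grid = fx.ControlGrid(t_end=25.0, n_intervals=25)
cfg = fx.TrainingConfig(learning_rate=0.0075, epochs=150,
                        episodes_per_epoch=200, seed=1)
result = fx.train(model, grid, fx.RandomizationSpec(0.25),
                  fx.ObjectiveSpec("terminal_titer"), cfg)
summary = fx.evaluate_policy(result.policy, model, grid,
                             fx.RandomizationSpec(0.25), 500, seed=1)
print(summary.titer_mean, summary.titer_std)   # 1.945 +/- 0.411 g/L
```

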
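# Methods

## The assemblage-to-composition map and its assumptions

The package learns the map φ from a binary species assemblage z ∈ {0,1}ᴺ to
a steady-state relative-abundance composition p ∈ Δᴺ. For the map to exist
and be learnable from samples, three assumptions are required:

1. **Universal dynamics** — all samples are produced by one dynamics with
   one parameter set (e.g. communities assembled in similar environments).
2. **Steady-state samples** — compositions represent equilibria, not
   transients.
3. **No true multistability** — each assemblage has a unique steady-state
   composition, so φ is single-valued.

None holds exactly in real data, which is why the package ships generators
that violate each assumption by a controlled amount (below) so the
degradation of prediction accuracy can be measured.

## The cNODE architecture

An assemblage is embedded as the uniform composition over its support,
h(0) = z / 1ᵀz, and the state evolves by the replicator equation with a
learned fitness f_θ:

    dh/dτ = h ⊙ (f_θ(h) − 1 hᵀ f_θ(h)),   τ ∈ [0, τ_c],   p̂ = h(τ_c).

Because 1ᵀ(dh/dτ) = 0 and the right-hand side carries a factor of h, the
flow stays on the simplex and preserves the zero pattern of z for any
finite parameters: predictions are compositional and absent species stay
absent by construction. τ_c = 1 without loss of generality — rescaling τ is
equivalent to scaling f_θ by a constant (a property covered by a regression
test).

The fitness is linear by default, f_θ(h) = Θh with Θ ∈ ℝᴺˣᴺ (N² parameters).
The `CNODEModel` accepts an arbitrary fitness callable for forward
prediction, but gradient training supports the linear form, which is the
tested default throughout.

**Initialization.** Θ entries are i.i.d. Normal(0, 1/N²). Any finite Θ
satisfies the structural restrictions; the small scale keeps the initial
map close to the uniform embedding so early training is stable.

## Numerical integration and gradients

Prediction integrates the replicator ODE with a fixed-step classical RK4
scheme, 32 steps over [0, 1] by default (`SolverSettings`; explicit Euler
and midpoint are available). The dynamics are smooth and low-dimensional,
so a fixed-step scheme gives fixed cost and, crucially, an exactly
differentiable computation graph. A test compares the fixed-step prediction
against an adaptive integration at tolerance 1e-10 and requires agreement
within 1e-4 Bray-Curtis across random instances with Θ at scale 1/N.

Gradients are computed discretize-then-optimize: reverse-mode
differentiation through the unrolled solver steps. For the linear fitness
the vector-Jacobian products of the replicator right-hand side have closed
forms, so the backward sweep stores only the per-step states and recomputes
the RK stages. The continuous-adjoint alternative is deliberately not used:
at these problem sizes the unrolled gradient is exact for the loss actually
computed, simpler, and verified against central finite differences
(relative 1e-4) in the test suite.

**Negative round-off.** In continuous time the state cannot cross zero;
discrete steps can slightly. Outputs are floored at zero, forced to exact
zeros off the assemblage support, and renormalized — only at the output,
never at interior steps. The gradient path applies the matching
subgradient (zero through clipped entries).

## Training

The loss is the mean dissimilarity E(D) = (1/|D|) Σ d(p, φ̂_θ(z)) with
Bray-Curtis d(p,q) = ½Σ|pᵢ−qᵢ| by default; total-variation (identical on
the simplex) and root Jensen-Shannon are pluggable alternatives.
Updates use Adam (plain SGD by flag); mini-batches are drawn without
replacement and reshuffled each epoch from the run seed, so training is
bitwise reproducible.

**Meta mode.** The literature this design follows specifies gradient-based
meta-learning without details, so the package implements a declared
first-order episodic scheme: each mini-batch is an episode split into
support and query halves (`query_fraction`, default 0.5); `inner_steps`
(default 1) SGD steps at `inner_lr` (default 0.05) adapt a copy of the
parameters on the support split; the query-loss gradient at the adapted
parameters is the outer gradient fed to the optimizer. `inner_steps = 0`
reduces exactly to plain mini-batch descent on the query split (tested).
Plain mode is the fallback; a paired test checks meta mode stays
competitive.

**Defaults at the benchmark scale** (N = 10): learning rate 0.02, 150
epochs, mini-batch 5. These were chosen as a stable operating point for
the synthetic task family; the `hyperparameter_search` helper reproduces
the grid-selection procedure (score by LOOCV or by a single split, pick
the minimizer, ties toward smaller learning rate then smaller batch).

No early stopping by default — validation tracks the test-error *plateau*
rather than a stopping rule; optional patience-based stopping exists.

## The GLV data generator

Synthetic samples are steady states of generalized Lotka-Volterra
communities dxᵢ/dt = xᵢ(rᵢ + Σⱼ aᵢⱼxⱼ) with aᵢⱼ ~ Bernoulli(C)·Normal(0, σ)
off-diagonal, aᵢᵢ = −1, rᵢ ~ Uniform[0,1]. Connectivity C and interaction
strength σ are the two knobs that make the learning task harder.
Abundances are dimensionless (time in units of the self-limitation rate).

Assemblages are drawn with each species present independently with
probability 0.5 (duplicates redrawn — under a deterministic steady-state
map a repeated assemblage adds no information), initial abundances
Uniform(0,1] on the support, and the ODE is integrated (LSODA) in windows
until every surviving species' per-capita rate is below 1e-6 in absolute
value. Species falling below 1e-8 are extinct and pinned to zero;
additionally, a species below 1e-3 whose per-capita rate is persistently
negative is declared extinct without waiting out its exponential tail (the
reduced system then re-converges, so the final residual check still
applies). Trajectories whose total abundance exceeds 1e6 are flagged
divergent. Non-convergent or divergent draws are resampled — the (C, σ)
labels keep their meaning — and generation aborts if more than half of all
attempts fail.

The recorded assemblage is the one *drawn*: a species that went
competitively extinct keeps zᵢ = 1 with pᵢ = 0, mirroring an introduced
species that fails to establish. `strict_support=True` records the
survivor set instead.

**What the generator does not emulate:** demographic noise, time-series
structure, compositional sampling noise from finite sequencing depth
(except through the explicit ε family below), taxonomic aggregation
effects, and environmental covariates. Passing the synthetic benchmarks
therefore demonstrates that the architecture and training recover a
deterministic assemblage→composition map from few samples — not that any
particular real habitat satisfies the three assumptions.

## Robustness families

* **Interaction noise (η):** every nonzero off-diagonal aᵢⱼ gets
  independent additive Normal(0, η) — freshly per sample — so samples no
  longer share one dynamics. η = 0 is the universal case.
* **Rewiring (ρ):** round(ρ·E) of the E existing edges are moved to random
  empty off-diagonal positions, carrying their weights (edge count and
  weight multiset conserved; topology-only violation). Sweep levels
  declared here: {0, 0.1, 0.25}.
* **Measurement noise (ε):** pᵢ → max{0, pᵢ + Normal(0, ε)}, renormalized.
  Exact zeros also receive noise, so absent taxa can appear and rare taxa
  vanish; the stored assemblage is the nonzero pattern of the *measured*
  composition. Note a structural property of this noise model: at any
  ε > 0 each absent taxon is measured as present with probability 1/2
  (only the spurious abundance scales with ε), and once noise dominates an
  entry its scale cancels in the renormalization. Prediction error
  therefore degrades steeply at small ε and saturates rather than growing
  without bound — at the benchmark scale the saturation sets in below
  ε = 0.05, so sweeps resolve the degradation only on the rising part of
  the curve.
* **Multistability (μ):** a fraction μ of samples come from the
  high-biomass regime of a bistable community model, the rest from the
  low-biomass regime, making φ two-valued on a μ-fraction of the data.

**The bistable model.** Per-capita growth of species i:

    bᵢ + aᵢ xᵢ²/(kᵢ² + xᵢ²) − cᵢ xᵢ + Σ_{j≠i} Aᵢⱼ xⱼ/(1 + xⱼ/kⱼ)

— sigmoidal self-facilitation (strength aᵢ = 4, half-saturation kᵢ = 1)
against linear crowding (cᵢ = 1.5) with a small positive net baseline rate
bᵢ. A mortality offset alone cannot produce two *interior* equilibria (the
per-capita rate would be monotone in own abundance, giving at most one
positive root); the sigmoidal term yields three positive roots — stable
low, unstable middle, stable high — which is exactly the two-regime
phenomenology required. Baselines are heterogeneous, bᵢ = 0.02 + 0.08·rᵢ
from the community's GLV growth rates, kept inside the bistable window
b ∈ (0, ~0.1]; this makes the low-regime composition (≈ proportional to
bᵢ/cᵢ) differ visibly from the nearly uniform high regime, so the μ
violation has bite. Interactions enter through saturating Holling-II
responses (bounded by kⱼ), preserving both regimes for weak interactions.
The regime is selected by the initial-condition scale (0.01·k vs 3·k, with
±20% jitter); parameter draws whose two regimes collapse onto one
equilibrium are resampled, and accepted draws satisfy
biomass(high) > biomass(low).

## Evaluation

`evaluate` reports per-sample errors with quartiles by linear interpolation
on the sorted values (the convention matters for selecting the
min/q1/median/q3/max representative samples, so it is fixed here).
`null_predictor_error` is the mean error of predicting the uniform
composition over each assemblage — identical to an untrained Θ = 0 model —
and anchors all "did training help" comparisons.

The dissimilarity-overlap screening computes, for every sample pair with
nonempty shared support s: overlap = ½ Σ_{i∈s}(pᵢ + qᵢ) and dissimilarity =
root Jensen-Shannon divergence of the two compositions renormalized on s;
disjoint pairs are excluded and counted. These formulas are stated here
explicitly because the screening is only reproducible with a fixed
convention. The tool reports the point cloud and a rank-correlation
summary (optionally restricted to the high-overlap half, where a negative
trend is the universality signature); no significance test is attached.

## Benchmark scale and reproducibility

All end-to-end validation (tests and `scripts/acceptance.py`) runs at
N = 10 species, S_train = 2N, S_test = N, averaged over 3–5 seeded
replicates, with 150 training epochs — sizes chosen so the full suite runs
on a single CPU in minutes while staying in the regime where 2N samples
suffice to train the model. The plateau test error is the mean over the
final 10% of epochs. Every random choice (community parameters, sampling,
splits, initialization, shuffling) descends from explicit integer seeds;
identical seeds give bitwise-identical datasets and trained parameters.

## Known limitations

* Taxa never observed in training cannot be predicted (any zᵢ pattern is
  accepted, but the model has no information about an always-absent taxon).
* The linear fitness limits expressivity; the fitness contract admits
  richer functions, but training is implemented for the linear form.
* Compositional data make the learned Θ non-identifiable — the model
  predicts, it does not mechanistically explain.
* The multistability generator uses the declared surrogate model above;
  conclusions about multistability robustness are relative to that
  surrogate's two-regime structure.
* No GPU path and no continuous-adjoint gradients; problem sizes are
  bounded by dense N×N linear algebra per solver step (fine up to a few
  hundred taxa on one CPU).
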
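# cnode

Predicting microbiome compositions from species assemblages with
compositional neural ordinary differential equations.

## The problem

A microbial habitat hosts a pool of N taxa. Any particular community drawn
from that pool is described by a binary *assemblage* z ∈ {0,1}ᴺ (which taxa
are present) and settles into a *composition* p ∈ Δᴺ — the vector of
relative abundances on the probability simplex. Managing such communities
(probiotics, decolonization, community design) requires predicting the map

    φ : z ∈ {0,1}ᴺ  ⟼  p ∈ Δᴺ

without knowing the physical, chemical and ecological processes behind it.
This package learns φ directly from (z, p) sample pairs, the form in which
standard metagenomic surveys deliver data. It is aimed at microbial
ecologists and quantitative biologists who have a table of relative
abundances and want out-of-sample composition predictions, plus the
machinery to validate the approach end to end on synthetic communities.

## The model

A cNODE (compositional neural ODE) embeds an assemblage as the uniform
composition over its support, h(0) = z / 1ᵀz, and integrates the replicator
equation over a virtual time τ ∈ [0, 1]:

    dh/dτ = h ⊙ ( f_θ(h) − 1 hᵀ f_θ(h) ),        p̂ = h(1),

with a learned fitness function f_θ (linear by default, f_θ(h) = Θh with
Θ ∈ ℝᴺˣᴺ). The right-hand side sums to zero and vanishes entrywise with h,
so for *any* parameters the prediction is compositional (p̂ ∈ Δᴺ) and absent
taxa stay at exactly zero (zᵢ = 0 ⇒ p̂ᵢ = 0) — the two structural
restrictions of the problem hold by construction rather than by penalty.
Although f_θ is linear, the map z ↦ p̂ is nonlinear because it is the flow
of a nonlinear ODE.

Training minimizes the mean Bray-Curtis dissimilarity
d(p, p̂) = ½ Σᵢ |pᵢ − p̂ᵢ| over a training set, with exact gradients obtained
by reverse-mode differentiation through the unrolled fixed-step solver.
Plain mini-batch training and an episodic first-order meta-learning mode
(support/query adaptation per batch) are both available, as are
leave-one-out cross-validation and a small hyperparameter grid search.

For validation, the package generates synthetic samples as steady states of
random generalized Lotka-Volterra (GLV) communities,

    dxᵢ/dt = xᵢ ( rᵢ + Σⱼ aᵢⱼ xⱼ ),   aᵢⱼ ~ Bernoulli(C)·Normal(0, σ), aᵢᵢ = −1,

and provides four perturbation families that break the method's working
assumptions in controlled ways: per-sample interaction noise (η), network
rewiring (ρ), measurement noise on compositions (ε), and true
multistability via a bistable saturating-response community model (μ). A
dissimilarity-overlap analysis screens any dataset for the signature of
universal dynamics.

## Worked example

```python
import numpy as np
from cnode import (
    CNODEModel, TrainingConfig, sample_glv_parameters, generate_glv_dataset,
    split_dataset, train, evaluate, null_predictor_error,
)

params = sample_glv_parameters(N=10, C=0.5, sigma=0.1, seed=1)
data = generate_glv_dataset(params, S=30, seed=2)
train_set, test_set = split_dataset(data, test_fraction=0.2, seed=3)

model = CNODEModel.initialize(N=10, seed=4)
fitted, trace = train(
    model, train_set,
    TrainingConfig(learning_rate=0.02, epochs=150, minibatch_size=5, seed=4),
)

result = evaluate(fitted, test_set)
print(f"training error after {len(trace.train_errors)} epochs: "
      f"{trace.train_errors[-1]:.4f}")
print(f"test error (median over {result.S} held-out samples): "
      f"{result.median:.4f}")
print(f"untrained baseline on the same samples: "
      f"{null_predictor_error(test_set):.4f}")
```

Output:

```
training error after 150 epochs: 0.0041
test error (median over 6 held-out samples): 0.0162
untrained baseline on the same samples: 0.2034
```

The test error is the Bray-Curtis dissimilarity between held-out
compositions and their predictions (0 = identical, 1 = disjoint). Here the
trained model predicts never-seen assemblages an order of magnitude better
than the untrained baseline, which returns the uniform composition over
each assemblage's support.

## Command line

The same pipeline is exposed as a CLI:

```sh
cnode simulate --N 10 --C 0.5 --sigma 0.1 --S 30 --seed 1 --out data.tsv
cnode train    --data data.tsv --epochs 150 --seed 1 --out model.txt
cnode predict  --model model.txt --assemblages data.tsv --out predicted.tsv
cnode loocv    --data data.tsv --epochs 100 --seed 1 --out report.json
cnode perturb  --params data.tsv.params.tsv --kind measurement_noise \
               --level 0.02 --S 30 --seed 2 --out noisy.tsv
cnode doc      --data data.tsv --out doc.json
```

Every subcommand accepts `--seed`, `--out` and `--config <yaml>`, and
writes a `<out>.config.json` with the fully resolved settings of the run.
Input tables are delimited text (TSV default): first row taxon names, first
column sample IDs, one sample per row; compositions are renormalized on
load.

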
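"""Scaled-down in-silico validation experiments.

These reproduce, at reduced problem size, the qualitative validation
protocol for cNODE on GLV communities: train on steady-state samples of a
random community and measure the out-of-sample (test) prediction error,
optionally under one of the robustness perturbations.  The default sizes
(N = 10 species, S_train = 2N, S_test = N) keep a full sweep affordable on
a single CPU while preserving the regime where 2N training samples
adequately train the model.

The *plateau* test error is the mean test error over the final 10% of
training epochs — the quantity whose dependence on connectivity,
interaction strength and perturbation level the validation sweeps track.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import CNODEModel
from .datamodel import MicrobiomeDataset
from .evaluation import null_predictor_error
from .glv import SteadyStateSettings, generate_glv_dataset, sample_glv_parameters
from .perturb import PerturbationSpec, generate_robustness_suite
from .training import TrainingConfig, prediction_error, train

__all__ = ["BenchmarkResult", "run_glv_benchmark", "plateau_error", "sweep"]

#: training defaults for the N=10 benchmark scale
DEFAULT_CONFIG = TrainingConfig(
    learning_rate=0.02, epochs=150, minibatch_size=5, seed=0
)


@dataclass
class BenchmarkResult:
    test_error: float  # plateau mean
    final_test_error: float
    train_error: float
    null_error: float
    test_trace: list[float]
    train_trace: list[float]


def plateau_error(test_trace: list[float], fraction: float = 0.1) -> float:
    """Mean test error over the final ``fraction`` of epochs."""
    n = max(1, round(len(test_trace) * fraction))
    return float(np.mean(test_trace[-n:]))


def run_glv_benchmark(
    seed: int,
    N: int = 10,
    C: float = 0.5,
    sigma: float = 0.1,
    S_train: int | None = None,
    S_test: int | None = None,
    config: TrainingConfig | None = None,
    perturbation: PerturbationSpec | None = None,
    settings: SteadyStateSettings | None = None,
) -> BenchmarkResult:
    """One train/test run on a freshly generated GLV community.

    ``seed`` drives everything: community parameters, sample generation,
    the train/test split, parameter initialization and the training
    shuffle.  ``perturbation`` generates the data through the matching
    robustness family instead of the clean simulator.
    """
    S_train = 2 * N if S_train is None else S_train
    S_test = N if S_test is None else S_test
    config = config if config is not None else DEFAULT_CONFIG
    ss = np.random.SeedSequence([seed, 0x5EED])
    param_seed, data_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))

    params = sample_glv_parameters(N, C, sigma, param_seed)
    S = S_train + S_test
    if perturbation is None:
        data = generate_glv_dataset(params, S, settings, seed=data_seed)
    else:
        data = generate_robustness_suite(
            params, replace(perturbation, seed=data_seed), S, settings
        )
    train_set = data.subset(range(S_train))
    test_set = data.subset(range(S_train, S))

    model = CNODEModel.initialize(N, seed=seed)
    cfg = replace(config, seed=seed, minibatch_size=min(config.minibatch_size, S_train))
    fitted, trace = train(model, train_set, cfg, test_set=test_set)
    return BenchmarkResult(
        test_error=plateau_error(trace.test_errors),
        final_test_error=trace.test_errors[-1],
        train_error=trace.train_errors[-1],
        null_error=null_predictor_error(test_set, cfg.dissimilarity),
        test_trace=list(trace.test_errors),
        train_trace=list(trace.train_errors),
    )


def sweep(
    seeds,
    **conditions,
) -> dict[str, float]:
    """Mean plateau/null errors of :func:`run_glv_benchmark` over seeds."""
    results = [run_glv_benchmark(seed, **conditions) for seed in seeds]
    return {
        "mean_test_error": float(np.mean([r.test_error for r in results])),
        "mean_null_error": float(np.mean([r.null_error for r in results])),
        "mean_train_error": float(np.mean([r.train_error for r in results])),
    }
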
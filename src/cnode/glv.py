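"""Generalized Lotka-Volterra simulation of in-silico microbiome samples.

Training and validation data are steady-state compositions of random GLV
communities,

    dx_i/dt = x_i (r_i + sum_j a_ij x_j),

with random parameters a_ij ~ Bernoulli(C) * Normal(0, sigma) off the
diagonal, a_ii = -1, and r_i ~ Uniform[0, 1].  The connectivity C sets how
likely two species interact; sigma sets the typical interaction strength.
A sample is produced by drawing a random species assemblage, integrating
the sub-community to equilibrium from a random positive initial condition,
and normalizing the surviving abundances to a composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
from scipy.integrate import solve_ivp

from .datamodel import MicrobiomeDataset, TaxonSet

__all__ = [
    "GLVParameters",
    "SteadyStateSettings",
    "SteadyStateResult",
    "sample_glv_parameters",
    "glv_trajectory",
    "glv_steady_state",
    "steady_composition",
    "generate_glv_dataset",
    "save_glv_parameters",
    "load_glv_parameters",
]


@dataclass
class GLVParameters:
    """Interaction matrix, growth rates and their generating hyperparameters."""

    A: np.ndarray
    r: np.ndarray
    C: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError(f"A must be square, got {self.A.shape}")
        if self.r.shape != (self.A.shape[0],):
            raise ValueError("r must have length N")

    @property
    def N(self) -> int:
        return self.A.shape[0]

    def copy(self) -> "GLVParameters":
        return GLVParameters(self.A.copy(), self.r.copy(), self.C, self.sigma)


@dataclass(frozen=True)
class SteadyStateSettings:
    """Convergence and integration controls for steady-state runs.

    ``convergence_tol`` bounds the max per-capita growth rate |r + A x|_i
    over surviving species at acceptance; ``extinction_threshold`` is the
    abundance below which a species is declared extinct and pinned to zero.
    """

    horizon: float = 1000.0
    convergence_tol: float = 1e-6
    extinction_threshold: float = 1e-8
    x0_scale: float = 1.0
    divergence_bound: float = 1e6
    window: float = 50.0
    #: a species this rare with a persistently negative per-capita rate is
    #: declared extinct without waiting out its exponential decay
    dying_threshold: float = 1e-3

    def __post_init__(self) -> None:
        for name in (
            "horizon",
            "convergence_tol",
            "extinction_threshold",
            "x0_scale",
            "divergence_bound",
            "window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class SteadyStateResult(NamedTuple):
    x: np.ndarray
    converged: bool
    diverged: bool
    t: float


def sample_glv_parameters(
    N: int, C: float, sigma: float, seed: int | np.random.Generator
) -> GLVParameters:
    """Random GLV parameters: a_ij ~ Bernoulli(C) Normal(0, sigma) for i != j,
    a_ii = -1, r_i ~ Uniform[0, 1]."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 <= C <= 1.0:
        raise ValueError("C must lie in [0, 1]")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    present = rng.random((N, N)) < C
    strengths = rng.normal(0.0, sigma, size=(N, N))
    A = np.where(present, strengths, 0.0)
    np.fill_diagonal(A, -1.0)
    r = rng.uniform(0.0, 1.0, size=N)
    return GLVParameters(A, r, C=C, sigma=sigma)


def _glv_rhs_factory(params: GLVParameters) -> Callable[[float, np.ndarray], np.ndarray]:
    A, r = params.A, params.r

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        growth = r + A @ x
        out = x * growth
        # absent species stay exactly zero even if present ones overflow
        # (avoids 0 * inf = nan near finite-time blow-up)
        out[x == 0] = 0.0
        return out

    return rhs


def glv_trajectory(
    params: GLVParameters,
    x0: np.ndarray,
    settings: SteadyStateSettings | None = None,
    t_span: tuple[float, float] | None = None,
    t_eval: np.ndarray | None = None,
):
    """Integrate the GLV dynamics with an adaptive stiff-capable scheme.

    Returns the ``scipy`` solution object; absent species (x0 = 0) remain
    exactly zero because the right-hand side carries a factor of x.  A
    trajectory whose total abundance exceeds the divergence bound is
    terminated and flagged via ``sol.status == 1`` (event termination).
    """
    settings = settings or SteadyStateSettings()
    x0 = np.asarray(x0, dtype=float)
    if (x0 < 0).any():
        raise ValueError("initial abundances must be nonnegative")
    if t_span is None:
        t_span = (0.0, settings.horizon)

    def blowup(t: float, x: np.ndarray) -> float:
        return settings.divergence_bound - x.sum()

    blowup.terminal = True  # type: ignore[attr-defined]
    # near finite-time blow-up the rhs legitimately overflows; the event
    # and the non-finite checks downstream handle it
    with np.errstate(over="ignore", invalid="ignore"):
        sol = solve_ivp(
            _glv_rhs_factory(params),
            t_span,
            x0,
            method="LSODA",
            t_eval=t_eval,
            events=blowup,
            rtol=1e-8,
            atol=1e-10,
        )
    return sol


def glv_steady_state(
    params: GLVParameters,
    z: np.ndarray,
    settings: SteadyStateSettings | None = None,
    seed: int | np.random.Generator = 0,
) -> SteadyStateResult:
    """Equilibrium abundances of the sub-community selected by ``z``.

    Integrates from a random positive initial condition on the support of
    ``z`` in windows; species dipping below the extinction threshold are set
    to zero and the reduced system continues.  Convergence is declared when
    the per-capita rate of every surviving species is below
    ``convergence_tol`` in absolute value.
    """
    settings = settings or SteadyStateSettings()
    z = np.asarray(z)
    rng = np.random.default_rng(seed)
    N = params.N
    x = np.zeros(N)
    support = z > 0
    if not support.any():
        raise ValueError("empty assemblage")
    # Uniform(0, 1] scaled: avoids exact zeros on the support
    x[support] = (1.0 - rng.random(support.sum())) * settings.x0_scale

    t = 0.0
    while t < settings.horizon:
        t_end = min(t + settings.window, settings.horizon)
        sol = glv_trajectory(params, x, settings, t_span=(t, t_end))
        if sol.status != 0 or not np.isfinite(sol.y[:, -1]).all():
            return SteadyStateResult(sol.y[:, -1], False, True, float(sol.t[-1]))
        x = np.maximum(sol.y[:, -1], 0.0)
        x[~support] = 0.0  # solver round-off must not resurrect absent species
        x[x < settings.extinction_threshold] = 0.0
        percap = params.r + params.A @ x
        dying = (
            (x > 0)
            & (x < settings.dying_threshold)
            & (percap < -settings.convergence_tol)
        )
        x[dying] = 0.0  # exponentially vanishing; cut the slow tail short
        support = x > 0  # extinctions are permanent
        t = float(sol.t[-1])
        alive = x > 0
        if not alive.any():
            return SteadyStateResult(x, False, False, t)
        if not dying.any() and np.abs(percap[alive]).max() < settings.convergence_tol:
            return SteadyStateResult(x, True, False, t)
    return SteadyStateResult(x, False, False, t)


def steady_composition(x: np.ndarray) -> np.ndarray:
    """Relative abundances p = x / sum(x)."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("community collapsed (all-zero abundances)")
    return x / total


def _draw_assemblage(
    rng: np.random.Generator, N: int, presence_prob: float
) -> np.ndarray:
    while True:
        z = (rng.random(N) < presence_prob).astype(np.int8)
        if z.any():
            return z


def generate_glv_dataset(
    params: GLVParameters,
    S: int,
    settings: SteadyStateSettings | None = None,
    seed: int = 0,
    presence_prob: float = 0.5,
    strict_support: bool = False,
    taxa: TaxonSet | None = None,
    params_for_sample: Callable[[int, np.random.Generator], GLVParameters] | None = None,
    max_attempt_factor: int = 20,
) -> MicrobiomeDataset:
    """Draw S samples: random assemblage -> GLV equilibrium -> composition.

    Assemblages are distinct within the dataset (a repeated assemblage would
    duplicate its composition under a deterministic steady-state map, so
    duplicates are redrawn); non-convergent or divergent draws are
    resampled, and generation aborts if more than half of all attempts fail.

    ``params_for_sample(k, rng)``, when given, supplies per-sample dynamics
    (used for the universality-loss robustness suites).  The assemblage and
    initial-condition random stream is independent of the perturbation
    stream, so a zero-level perturbation reproduces the unperturbed dataset
    bit for bit.

    By default the stored ``z`` is the assemblage as *drawn* — species that
    went competitively extinct keep z=1 with p=0, mirroring an introduced
    species that fails to establish.  ``strict_support`` records
    z = support(p) instead.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if not 0.0 < presence_prob <= 1.0:
        raise ValueError("presence_prob must lie in (0, 1]")
    settings = settings or SteadyStateSettings()
    N = params.N
    taxa = taxa or TaxonSet.generic(N)
    ss = np.random.SeedSequence(seed)
    asm_rng = np.random.default_rng(ss.spawn(3)[0])
    ic_seed_rng = np.random.default_rng(ss.spawn(3)[1])
    pert_rng = np.random.default_rng(ss.spawn(3)[2])

    P_rows: list[np.ndarray] = []
    Z_rows: list[np.ndarray] = []
    seen: set[bytes] = set()
    attempts = 0
    failures = 0
    max_attempts = max(max_attempt_factor * S, 100)
    while len(P_rows) < S:
        if attempts >= max_attempts or (
            attempts >= 2 * S and failures > 0.5 * attempts
        ):
            raise RuntimeError(
                f"generated only {len(P_rows)}/{S} samples after {attempts} "
                f"attempts ({failures} non-convergent/divergent); try a "
                "smaller sigma or a longer horizon"
            )
        attempts += 1
        z = _draw_assemblage(asm_rng, N, presence_prob)
        ic_seed = int(ic_seed_rng.integers(2**31))
        if z.tobytes() in seen:
            continue
        k = len(P_rows)
        p_run = params_for_sample(k, pert_rng) if params_for_sample else params
        res = glv_steady_state(p_run, z, settings, seed=ic_seed)
        if not res.converged:
            failures += 1
            continue
        p = steady_composition(res.x)
        seen.add(z.tobytes())
        Z_rows.append(p > 0 if strict_support else z)
        P_rows.append(p)

    return MicrobiomeDataset.from_matrices(
        taxa, np.stack(P_rows), Z=np.stack(Z_rows).astype(np.int8)
    )


def save_glv_parameters(params: GLVParameters, path) -> None:
    """Sidecar text format for exact replay of a simulation."""
    from pathlib import Path

    path = Path(path)
    lines = ["glv-params-v1", f"N\t{params.N}"]
    lines.append(f"C\t{'' if params.C is None else repr(float(params.C))}")
    lines.append(
        f"sigma\t{'' if params.sigma is None else repr(float(params.sigma))}"
    )
    lines.append("r\t" + "\t".join(repr(float(v)) for v in params.r))
    for row in params.A:
        lines.append("\t".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


def load_glv_parameters(path) -> GLVParameters:
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != "glv-params-v1":
        raise ValueError(f"{path}: not a glv-params-v1 file")
    N = int(lines[1].split("\t")[1])
    c_field = lines[2].split("\t")
    s_field = lines[3].split("\t")
    C = float(c_field[1]) if len(c_field) > 1 and c_field[1] else None
    sigma = float(s_field[1]) if len(s_field) > 1 and s_field[1] else None
    r = np.array([float(v) for v in lines[4].split("\t")[1:]])
    A = np.array([[float(v) for v in line.split("\t")] for line in lines[5 : 5 + N]])
    return GLVParameters(A, r, C=C, sigma=sigma)
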
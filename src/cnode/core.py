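"""The cNODE architecture: replicator dynamics on the probability simplex.

A compositional neural ODE maps a binary assemblage ``z`` to a predicted
composition by (i) embedding ``z`` as the uniform composition over its
support, h(0) = z / sum(z), and (ii) integrating the replicator equation

    dh/dtau = h * (f(h) - <h, f(h)> 1),        tau in [0, tau_c],

where the fitness ``f`` is a learned function of the current state — by
default the linear map f(h) = Theta h.  The right-hand side sums to zero,
so the state stays on the simplex, and it carries a factor of ``h``, so
absent species stay at exactly zero: the two structural restrictions of the
assemblage-to-composition map hold by construction for any parameters.

Integration uses a fixed-step scheme (classical RK4 by default) so that the
training code can differentiate exactly through the unrolled solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .datamodel import TaxonSet

__all__ = [
    "SolverSettings",
    "CNODEModel",
    "embed_assemblage",
    "replicator_rhs",
    "predict",
    "predict_batch",
    "save_model",
    "load_model",
]

#: fitness contract — maps an (B, N) simplex batch to an (B, N) fitness batch
FitnessFunction = Callable[[np.ndarray], np.ndarray]

_FIXED_STEP_METHODS = ("rk4", "euler", "midpoint")


@dataclass(frozen=True)
class SolverSettings:
    """Fixed-step integrator configuration over the virtual time [0, tau_c].

    tau_c = 1 by default: rescaling tau is equivalent to rescaling the
    fitness by a constant, so the final time carries no extra freedom.
    """

    method: str = "rk4"
    steps: int = 32
    tau_c: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in _FIXED_STEP_METHODS:
            raise ValueError(
                f"unknown solver method {self.method!r}; "
                f"choose from {_FIXED_STEP_METHODS}"
            )
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.tau_c <= 0:
            raise ValueError("tau_c must be > 0")


class CNODEModel:
    """A parametrized assemblage-to-composition map.

    Parameters
    ----------
    theta:
        N x N fitness parameter matrix (finite).  ``fitness(h)`` is
        ``theta @ h`` unless a custom fitness callable is supplied
        (custom fitness supports prediction only, not gradient training).
    solver:
        Fixed-step integrator settings.
    taxa:
        Optional taxon names carried through serialization.
    """

    def __init__(
        self,
        theta: np.ndarray,
        solver: SolverSettings | None = None,
        taxa: TaxonSet | None = None,
        fitness: FitnessFunction | None = None,
    ) -> None:
        theta = np.asarray(theta, dtype=float)
        if theta.ndim != 2 or theta.shape[0] != theta.shape[1]:
            raise ValueError(f"theta must be square, got shape {theta.shape}")
        if not np.isfinite(theta).all():
            raise ValueError("theta must be finite everywhere")
        if taxa is not None and taxa.N != theta.shape[0]:
            raise ValueError("taxon set dimension does not match theta")
        self.theta = theta
        self.solver = solver if solver is not None else SolverSettings()
        self.taxa = taxa
        self._fitness = fitness

    @classmethod
    def initialize(
        cls,
        N: int,
        seed: int = 0,
        scale: float | None = None,
        solver: SolverSettings | None = None,
        taxa: TaxonSet | None = None,
    ) -> "CNODEModel":
        """Fresh model with Theta ~ Normal(0, scale), scale = 1/N^2 by default.

        The small scale keeps the initial dynamics near the identity so the
        untrained map is close to the uniform-over-support embedding.
        """
        if N < 1:
            raise ValueError("N must be >= 1")
        if scale is None:
            scale = 1.0 / N**2
        rng = np.random.default_rng(seed)
        return cls(rng.normal(0.0, scale, size=(N, N)), solver=solver, taxa=taxa)

    @property
    def N(self) -> int:
        return self.theta.shape[0]

    @property
    def is_linear(self) -> bool:
        return self._fitness is None

    def fitness(self, h: np.ndarray) -> np.ndarray:
        """Fitness of a state batch (rows are simplex vectors)."""
        if self._fitness is not None:
            f = np.asarray(self._fitness(h), dtype=float)
            if f.shape != h.shape:
                raise ValueError("fitness output shape must match its input")
            return f
        return h @ self.theta.T

    def copy(self) -> "CNODEModel":
        return CNODEModel(
            self.theta.copy(), self.solver, self.taxa, self._fitness
        )

    def __repr__(self) -> str:
        return f"CNODEModel(N={self.N}, solver={self.solver})"


def embed_assemblage(z: Sequence[float] | np.ndarray) -> np.ndarray:
    """Uniform composition over the support of ``z``: h(0) = z / sum(z)."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 1:
        raise ValueError("z must be a 1-d vector")
    if not np.isin(z, (0.0, 1.0)).all():
        raise ValueError("z must be binary")
    total = z.sum()
    if total == 0:
        raise ValueError("empty assemblage has no composition")
    return z / total


def replicator_rhs(h: np.ndarray, model: CNODEModel) -> np.ndarray:
    """dh/dtau = h * (f(h) - <h, f(h)>); entries sum to zero."""
    h = np.asarray(h, dtype=float)
    f = model.fitness(h[None, :])[0]
    if not np.isfinite(f).all():
        raise FloatingPointError("fitness returned non-finite values")
    return h * (f - h @ f)


def _rhs_batch(H: np.ndarray, model: CNODEModel) -> np.ndarray:
    F = model.fitness(H)
    mean_fit = np.einsum("bi,bi->b", H, F)
    return H * (F - mean_fit[:, None])


def integrate_batch(
    model: CNODEModel, H0: np.ndarray, return_trajectory: bool = False
) -> np.ndarray | list[np.ndarray]:
    """Fixed-step integration of the replicator ODE for a batch of states.

    Returns the final states, or the full list of per-step states when
    ``return_trajectory`` is set (used by the gradient code and the simplex
    conservation diagnostics).
    """
    s = model.solver
    dt = s.tau_c / s.steps
    H = np.array(H0, dtype=float)
    traj = [H.copy()]
    for _ in range(s.steps):
        if s.method == "euler":
            H = H + dt * _rhs_batch(H, model)
        elif s.method == "midpoint":
            K1 = _rhs_batch(H, model)
            H = H + dt * _rhs_batch(H + 0.5 * dt * K1, model)
        else:  # rk4
            K1 = _rhs_batch(H, model)
            K2 = _rhs_batch(H + 0.5 * dt * K1, model)
            K3 = _rhs_batch(H + 0.5 * dt * K2, model)
            K4 = _rhs_batch(H + dt * K3, model)
            H = H + (dt / 6.0) * (K1 + 2.0 * K2 + 2.0 * K3 + K4)
        if not np.isfinite(H).all():
            raise FloatingPointError(
                "non-finite state during integration; increase solver steps "
                "or reduce the scale of theta"
            )
        if return_trajectory:
            traj.append(H.copy())
    return traj if return_trajectory else H


def _clip_renorm(H: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Floor negative round-off at 0, zero the complement of z, renormalize."""
    P = np.where(np.asarray(Z) > 0, np.maximum(H, 0.0), 0.0)
    totals = P.sum(axis=1)
    if (totals <= 0).any():
        raise FloatingPointError("prediction collapsed to the zero vector")
    return P / totals[:, None]


def predict(model: CNODEModel, z: Sequence[float] | np.ndarray) -> np.ndarray:
    """Predicted composition for one assemblage.

    Integrates the replicator ODE from the uniform embedding of ``z`` over
    [0, tau_c]; the output is floored at zero (discrete steps can produce
    tiny negative round-off), forced to exact zeros off the support of
    ``z``, and renormalized to the simplex.
    """
    z = np.asarray(z)
    h0 = embed_assemblage(z)
    if model.N != h0.shape[0]:
        raise ValueError(
            f"assemblage dimension {h0.shape[0]} does not match model N={model.N}"
        )
    H = integrate_batch(model, h0[None, :])
    return _clip_renorm(H, z[None, :])[0]


def predict_batch(
    model: CNODEModel, assemblages: Sequence[Sequence[float]] | np.ndarray
) -> np.ndarray:
    """Vectorised :func:`predict` over a list of assemblages (order kept)."""
    assemblages = list(assemblages)
    if not assemblages:
        return np.zeros((0, model.N))
    H0 = np.empty((len(assemblages), model.N))
    Z = np.empty((len(assemblages), model.N), dtype=np.int8)
    for k, z in enumerate(assemblages):
        try:
            H0[k] = embed_assemblage(z)
        except ValueError as exc:
            raise ValueError(f"invalid assemblage at index {k}: {exc}") from exc
        Z[k] = np.asarray(z, dtype=np.int8)
    H = integrate_batch(model, H0)
    return _clip_renorm(H, Z)


_MODEL_FORMAT = "cnode-model-v1"


def save_model(model: CNODEModel, path: str | Path) -> None:
    """Serialize a linear-fitness model to versioned plain text."""
    if not model.is_linear:
        raise ValueError("only linear-fitness models can be serialized")
    path = Path(path)
    s = model.solver
    lines = [
        _MODEL_FORMAT,
        f"N\t{model.N}",
        "taxa\t" + "\t".join(model.taxa.names if model.taxa else []),
        f"solver\t{s.method}\t{s.steps}\t{float(s.tau_c)!r}",
    ]
    for row in model.theta:
        lines.append("\t".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


def load_model(path: str | Path) -> CNODEModel:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0] != _MODEL_FORMAT:
        raise ValueError(f"{path}: not a {_MODEL_FORMAT} file")
    N = int(lines[1].split("\t")[1])
    taxa_fields = lines[2].split("\t")[1:]
    taxa = TaxonSet(tuple(taxa_fields)) if taxa_fields else None
    _, method, steps, tau_c = lines[3].split("\t")
    solver = SolverSettings(method=method, steps=int(steps), tau_c=float(tau_c))
    theta = np.array(
        [[float(v) for v in line.split("\t")] for line in lines[4 : 4 + N]]
    )
    return CNODEModel(theta, solver=solver, taxa=taxa)
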
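"""Robustness-test dataset families: the four ways real data break the
idealized assemblage-to-composition map.

* ``interaction_noise`` (eta): each sample is generated by a GLV whose
  nonzero interaction strengths are independently jittered by
  Normal(0, eta) — a per-sample loss of universal dynamics.  eta = 0 is
  the universal case.
* ``rewiring`` (rho): each sample's GLV has a fraction rho of its
  interaction edges moved to random empty positions (weights preserved) —
  universality loss through sample-specific network topology.
* ``measurement_noise`` (eps): compositions of a single clean GLV dataset
  are corrupted entrywise by truncated Gaussian noise and renormalized;
  absent taxa can be measured as present and vice versa.
* ``multistability`` (mu): samples come from a community model with
  nonlinear (saturating) functional responses admitting two interior
  equilibria per assemblage — a low-biomass and a high-biomass regime —
  with a fraction mu of samples drawn from the high regime, so the
  assemblage-to-composition map is no longer single-valued.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .datamodel import MicrobiomeDataset, TaxonSet
from .glv import (
    GLVParameters,
    SteadyStateSettings,
    SteadyStateResult,
    _draw_assemblage,
    generate_glv_dataset,
    steady_composition,
)

__all__ = [
    "PerturbationSpec",
    "BistableGLVParameters",
    "perturb_interactions",
    "rewire_network",
    "add_measurement_noise",
    "bistable_steady_state",
    "generate_multistable_dataset",
    "generate_robustness_suite",
]

_KINDS = ("interaction_noise", "rewiring", "measurement_noise", "multistability")


@dataclass(frozen=True)
class PerturbationSpec:
    """One robustness condition: which family, at what level, which seed."""

    kind: str
    level: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.level < 0:
            raise ValueError("level must be >= 0")
        if self.kind in ("rewiring", "multistability") and self.level > 1:
            raise ValueError(f"{self.kind} level must lie in [0, 1]")


def perturb_interactions(
    params: GLVParameters, eta: float, seed: int | np.random.Generator
) -> GLVParameters:
    """Additive Normal(0, eta) noise on every *nonzero* off-diagonal a_ij.

    The ecological network G(A) is preserved: zeros and the diagonal are
    untouched.  Each call draws fresh noise, so calling once per sample
    yields sample-specific dynamics on a common network.
    """
    if eta < 0:
        raise ValueError("eta must be >= 0")
    rng = np.random.default_rng(seed)
    out = params.copy()
    N = params.N
    offdiag = ~np.eye(N, dtype=bool)
    mask = offdiag & (params.A != 0)
    noise = rng.normal(0.0, eta, size=N * N).reshape(N, N)
    out.A = np.where(mask, params.A + noise, params.A)
    return out


def rewire_network(
    params: GLVParameters, rho: float, seed: int | np.random.Generator
) -> GLVParameters:
    """Move round(rho * E) interaction edges to random empty positions.

    Each selected off-diagonal edge is deleted and its weight re-inserted at
    a uniformly random currently-empty off-diagonal slot (slots freed by
    earlier moves become available), so the edge count and the weight
    multiset are conserved and only the topology changes.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = params.copy()
    A = out.A
    N = params.N
    offdiag = ~np.eye(N, dtype=bool)
    edges = [tuple(ij) for ij in np.argwhere(offdiag & (A != 0))]
    E = len(edges)
    n_move = round(rho * E)
    if n_move == 0:
        return out
    empty = {tuple(ij) for ij in np.argwhere(offdiag & (A == 0))}
    if not empty:
        raise ValueError("complete interaction network has no empty positions")
    chosen = rng.choice(E, size=n_move, replace=False)
    for idx in chosen:
        i, j = edges[idx]
        w = A[i, j]
        A[i, j] = 0.0
        empty.add((i, j))
        slots = sorted(empty)
        ti, tj = slots[rng.integers(len(slots))]
        A[ti, tj] = w
        empty.discard((ti, tj))
    return out


def add_measurement_noise(
    p: np.ndarray, eps: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Corrupt a composition: p_i -> max{0, p_i + Normal(0, eps)}, renormalize.

    Every entry receives noise, including exact zeros, so absent taxa can be
    measured as present and rare taxa can vanish.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    p = np.asarray(p, dtype=float)
    if eps == 0:
        return p.copy()
    rng = np.random.default_rng(seed)
    noisy = np.maximum(p + rng.normal(0.0, eps, size=p.shape), 0.0)
    total = noisy.sum(axis=-1, keepdims=True)
    if (total == 0).any():
        raise ValueError(
            "measurement noise truncated every taxon to zero; use a smaller eps"
        )
    return noisy / total


# --------------------------------------------------------------------------
# bistable community model (true multistability)
# --------------------------------------------------------------------------


@dataclass
class BistableGLVParameters:
    """Community dynamics with saturating functional responses and two
    interior equilibria per assemblage.

    Per-capita growth of species i:

        b_i + a_i x_i^2 / (k_i^2 + x_i^2) - c_i x_i
            + sum_{j != i} A_ij x_j / (1 + x_j / k_j)

    The sigmoidal self-facilitation term (strength ``a_i``, half-saturation
    ``k_i``) against linear crowding ``c_i`` makes the isolated
    single-species dynamics bistable with two *positive* equilibria — a low
    regime near b/c and a high regime near a/c — while interspecies effects
    enter through saturating Holling-II responses, keeping both regimes
    intact for weak interactions.  ``b_i`` is the net baseline rate (growth
    minus mortality) and must be positive but small relative to ``a_i``.
    """

    base: GLVParameters
    half_saturation: np.ndarray = field(default=None)  # type: ignore[assignment]
    facilitation: np.ndarray = field(default=None)  # type: ignore[assignment]
    crowding: np.ndarray = field(default=None)  # type: ignore[assignment]
    baseline: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        N = self.base.N
        if self.half_saturation is None:
            self.half_saturation = np.ones(N)
        if self.facilitation is None:
            self.facilitation = np.full(N, 4.0)
        if self.crowding is None:
            self.crowding = np.full(N, 1.5)
        if self.baseline is None:
            # heterogeneous baselines (derived from the GLV growth rates,
            # squashed into the bistable window) separate the low-regime
            # composition, which is roughly proportional to baseline/crowding,
            # from the nearly uniform high-regime composition
            r01 = np.clip(self.base.r, 0.0, 1.0)
            self.baseline = 0.02 + 0.08 * r01
        for name in ("half_saturation", "facilitation", "crowding", "baseline"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (N,):
                raise ValueError(f"{name} must have length {N}")
            if (v <= 0).any():
                raise ValueError(f"{name} entries must be positive")
            setattr(self, name, v)

    @property
    def N(self) -> int:
        return self.base.N


def _bistable_rhs_factory(
    params: BistableGLVParameters,
) -> Callable[[float, np.ndarray], np.ndarray]:
    A = params.base.A.copy()
    np.fill_diagonal(A, 0.0)  # self-effects live in the facilitation/crowding terms
    k, a, c, b = (
        params.half_saturation,
        params.facilitation,
        params.crowding,
        params.baseline,
    )

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        sat = x / (1.0 + x / k)
        growth = b + a * x**2 / (k**2 + x**2) - c * x + A @ sat
        out = x * growth
        out[x == 0] = 0.0
        return out

    return rhs


#: initial-condition scale (relative to k) selecting the basin of attraction
_REGIME_X0 = {"low": 0.01, "high": 3.0}


def bistable_steady_state(
    params: BistableGLVParameters,
    z: np.ndarray,
    regime: str,
    settings: SteadyStateSettings | None = None,
    seed: int | np.random.Generator = 0,
) -> SteadyStateResult:
    """Equilibrium of the saturating dynamics in the chosen biomass regime.

    The regime is selected by the initial-condition scale: small (inside the
    low-biomass basin) or large (high-biomass basin); a mild random jitter
    decorrelates samples without leaving the basin.
    """
    if regime not in _REGIME_X0:
        raise ValueError(f"regime must be 'low' or 'high', got {regime!r}")
    settings = settings or SteadyStateSettings()
    z = np.asarray(z)
    support = z > 0
    if not support.any():
        raise ValueError("empty assemblage")
    rng = np.random.default_rng(seed)
    x0 = np.zeros(params.N)
    scale = _REGIME_X0[regime] * params.half_saturation[support]
    x0[support] = scale * rng.uniform(0.8, 1.2, size=int(support.sum()))

    rhs = _bistable_rhs_factory(params)

    def blowup(t: float, x: np.ndarray) -> float:
        return settings.divergence_bound - x.sum()

    blowup.terminal = True  # type: ignore[attr-defined]

    x = x0
    t = 0.0
    while t < settings.horizon:
        t_end = min(t + settings.window, settings.horizon)
        with np.errstate(over="ignore", invalid="ignore"):
            sol = solve_ivp(
                rhs, (t, t_end), x, method="LSODA", events=blowup,
                rtol=1e-8, atol=1e-10,
            )
        if sol.status != 0 or not np.isfinite(sol.y[:, -1]).all():
            return SteadyStateResult(sol.y[:, -1], False, True, float(sol.t[-1]))
        x = np.maximum(sol.y[:, -1], 0.0)
        x[~(np.asarray(z) > 0)] = 0.0
        x[x < settings.extinction_threshold] = 0.0
        t = float(sol.t[-1])
        alive = x > 0
        if not alive.any():
            return SteadyStateResult(x, False, False, t)
        rate = rhs(t, x)
        percap = np.zeros_like(x)
        percap[alive] = rate[alive] / x[alive]
        dying = alive & (x < settings.dying_threshold) & (
            percap < -settings.convergence_tol
        )
        x[dying] = 0.0
        alive = x > 0
        if not alive.any():
            return SteadyStateResult(x, False, False, t)
        if not dying.any() and np.abs(percap[alive]).max() < settings.convergence_tol:
            return SteadyStateResult(x, True, False, t)
    return SteadyStateResult(x, False, False, t)


def generate_multistable_dataset(
    params: BistableGLVParameters,
    S: int,
    mu: float,
    settings: SteadyStateSettings | None = None,
    seed: int = 0,
    presence_prob: float = 0.5,
    taxa: TaxonSet | None = None,
    max_attempt_factor: int = 20,
    return_regimes: bool = False,
):
    """Dataset mixing the two equilibrium regimes of a bistable community.

    round(S * (1 - mu)) samples come from the low-biomass regime and the
    rest from the high regime; regime labels are assigned to a seeded random
    subset of the sample slots.  Parameter draws whose two regimes collapse
    onto the same equilibrium (or fail to converge) are resampled; the
    accepted draws satisfy total biomass (high) > total biomass (low).
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    settings = settings or SteadyStateSettings()
    N = params.N
    taxa = taxa or TaxonSet.generic(N)
    n_low = round(S * (1.0 - mu))
    ss = np.random.SeedSequence(seed)
    asm_rng = np.random.default_rng(ss.spawn(2)[0])
    ic_rng = np.random.default_rng(ss.spawn(2)[1])
    regimes = np.array(["low"] * n_low + ["high"] * (S - n_low))
    asm_rng.shuffle(regimes)

    P_rows: list[np.ndarray] = []
    Z_rows: list[np.ndarray] = []
    out_regimes: list[str] = []
    seen: set[bytes] = set()
    attempts = 0
    max_attempts = max(max_attempt_factor * S, 100)
    while len(P_rows) < S:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"generated only {len(P_rows)}/{S} bistable samples after "
                f"{attempts} attempts; weaken interactions or relax settings"
            )
        attempts += 1
        z = _draw_assemblage(asm_rng, N, presence_prob)
        ic_seed = int(ic_rng.integers(2**31))
        if z.tobytes() in seen:
            continue
        lo = bistable_steady_state(params, z, "low", settings, seed=ic_seed)
        hi = bistable_steady_state(params, z, "high", settings, seed=ic_seed)
        if not (lo.converged and hi.converged):
            continue
        if not lo.x.any() or not hi.x.any():
            continue
        if hi.x.sum() <= lo.x.sum() * (1.0 + 1e-3):
            continue  # regimes collapsed; not truly bistable for this draw
        res = lo if regimes[len(P_rows)] == "low" else hi
        p = steady_composition(res.x)
        seen.add(z.tobytes())
        Z_rows.append(z)
        P_rows.append(p)
        out_regimes.append(regimes[len(P_rows) - 1])

    ds = MicrobiomeDataset.from_matrices(
        taxa, np.stack(P_rows), Z=np.stack(Z_rows).astype(np.int8)
    )
    if return_regimes:
        return ds, out_regimes
    return ds


def generate_robustness_suite(
    base_params: GLVParameters,
    spec: PerturbationSpec,
    S: int,
    settings: SteadyStateSettings | None = None,
    seed: int | None = None,
    presence_prob: float = 0.5,
    bistable_params: BistableGLVParameters | None = None,
) -> MicrobiomeDataset:
    """Dataset for one robustness condition (one point of a Fig.-2-style sweep).

    ``interaction_noise`` and ``rewiring`` draw a freshly perturbed GLV per
    sample; ``measurement_noise`` corrupts each composition of a clean GLV
    dataset; ``multistability`` delegates to the bistable generator.  At
    level 0, interaction_noise and measurement_noise reproduce the clean
    generator bit for bit under the same seed.
    """
    settings = settings or SteadyStateSettings()
    seed = spec.seed if seed is None else seed

    if spec.kind == "interaction_noise":
        return generate_glv_dataset(
            base_params, S, settings, seed=seed, presence_prob=presence_prob,
            params_for_sample=lambda k, rng: perturb_interactions(
                base_params, spec.level, rng
            ),
        )
    if spec.kind == "rewiring":
        return generate_glv_dataset(
            base_params, S, settings, seed=seed, presence_prob=presence_prob,
            params_for_sample=lambda k, rng: rewire_network(
                base_params, spec.level, rng
            ),
        )
    if spec.kind == "measurement_noise":
        clean = generate_glv_dataset(
            base_params, S, settings, seed=seed, presence_prob=presence_prob
        )
        if spec.level == 0:
            return clean
        noise_rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(4)[3]
        )
        P = np.stack(
            [add_measurement_noise(s.p, spec.level, noise_rng) for s in clean]
        )
        # the assemblage is what the corrupted measurement shows: absent
        # species can appear as present and truncated ones disappear
        return MicrobiomeDataset.from_matrices(clean.taxa, P, Z=(P > 0))
    # multistability
    bp = bistable_params or BistableGLVParameters(base=base_params)
    return generate_multistable_dataset(
        bp, S, spec.level, settings, seed=seed, presence_prob=presence_prob
    )
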
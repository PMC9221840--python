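"""Reverse-mode differentiation through the unrolled replicator solver.

The training loss is differentiated discretize-then-optimize: the RK4 (or
Euler/midpoint) steps of :func:`cnode.core.integrate_batch` are unrolled and
backpropagated exactly, so the analytic gradient is the gradient of the loss
actually computed, not of the continuous-time limit.

For the linear fitness f(h) = Theta h the replicator right-hand side is

    g(h) = h * (Theta h - (h' Theta h) 1)

whose vector-Jacobian products have closed forms.  With adjoint w:

    w'' dg/dh     = w*(f - s) + Theta' (w*h) - (w.h) (f + Theta' h)
    w'' dg/dTheta = ((w*h) - (w.h) h) h'

where f = Theta h and s = h' f.  Only the per-step states are stored on the
forward tape; RK stage values are recomputed during the backward sweep.
"""

from __future__ import annotations

import numpy as np

from .core import CNODEModel, _clip_renorm
from .dissimilarity import get_dissimilarity

__all__ = ["loss_and_grad", "forward_tape", "backward_from_tape"]


def _rhs(theta: np.ndarray, H: np.ndarray) -> np.ndarray:
    F = H @ theta.T
    s = np.einsum("bi,bi->b", H, F)
    return H * (F - s[:, None])


def _rhs_vjp(
    theta: np.ndarray, H: np.ndarray, W: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """VJPs of the replicator right-hand side at state batch ``H``."""
    F = H @ theta.T
    Ht = H @ theta  # rows: Theta' h
    s = np.einsum("bi,bi->b", H, F)
    wh = np.einsum("bi,bi->b", W, H)
    WH = W * H
    vjp_h = W * (F - s[:, None]) + WH @ theta - wh[:, None] * (F + Ht)
    vjp_theta = np.einsum("bi,bj->ij", WH - wh[:, None] * H, H)
    return vjp_h, vjp_theta


def forward_tape(model: CNODEModel, H0: np.ndarray) -> list[np.ndarray]:
    """Forward pass storing the state at every solver step boundary."""
    if not model.is_linear:
        raise ValueError("gradient training requires the linear fitness f(h)=Theta h")
    theta, s = model.theta, model.solver
    dt = s.tau_c / s.steps
    H = np.array(H0, dtype=float)
    tape = [H.copy()]
    for _ in range(s.steps):
        if s.method == "euler":
            H = H + dt * _rhs(theta, H)
        elif s.method == "midpoint":
            K1 = _rhs(theta, H)
            H = H + dt * _rhs(theta, H + 0.5 * dt * K1)
        else:
            K1 = _rhs(theta, H)
            K2 = _rhs(theta, H + 0.5 * dt * K1)
            K3 = _rhs(theta, H + 0.5 * dt * K2)
            K4 = _rhs(theta, H + dt * K3)
            H = H + (dt / 6.0) * (K1 + 2.0 * K2 + 2.0 * K3 + K4)
        if not np.isfinite(H).all():
            raise FloatingPointError("non-finite state during forward integration")
        tape.append(H.copy())
    return tape


def backward_from_tape(
    model: CNODEModel, tape: list[np.ndarray], W: np.ndarray
) -> np.ndarray:
    """Backpropagate the adjoint ``W`` (dL/d h(tau_c)) to grad wrt Theta."""
    theta, s = model.theta, model.solver
    dt = s.tau_c / s.steps
    grad_theta = np.zeros_like(theta)
    W = np.array(W, dtype=float)
    for n in range(s.steps, 0, -1):
        H = tape[n - 1]
        if s.method == "euler":
            gh, gt = _rhs_vjp(theta, H, dt * W)
            grad_theta += gt
            W = W + gh
        elif s.method == "midpoint":
            K1 = _rhs(theta, H)
            U2 = H + 0.5 * dt * K1
            gh2, gt2 = _rhs_vjp(theta, U2, dt * W)
            gh1, gt1 = _rhs_vjp(theta, H, 0.5 * dt * gh2)
            grad_theta += gt1 + gt2
            W = W + gh2 + gh1
        else:
            K1 = _rhs(theta, H)
            U2 = H + 0.5 * dt * K1
            K2 = _rhs(theta, U2)
            U3 = H + 0.5 * dt * K2
            K3 = _rhs(theta, U3)
            U4 = H + dt * K3
            a4 = (dt / 6.0) * W
            b_u4, gt4 = _rhs_vjp(theta, U4, a4)
            a3 = (2.0 * dt / 6.0) * W + dt * b_u4
            b_u3, gt3 = _rhs_vjp(theta, U3, a3)
            a2 = (2.0 * dt / 6.0) * W + 0.5 * dt * b_u3
            b_u2, gt2 = _rhs_vjp(theta, U2, a2)
            a1 = (dt / 6.0) * W + 0.5 * dt * b_u2
            b_h, gt1 = _rhs_vjp(theta, H, a1)
            grad_theta += gt1 + gt2 + gt3 + gt4
            W = W + b_u4 + b_u3 + b_u2 + b_h
    return grad_theta


def loss_and_grad(
    model: CNODEModel,
    Z: np.ndarray,
    P: np.ndarray,
    dissimilarity: str = "bray_curtis",
) -> tuple[float, np.ndarray]:
    """Mean prediction error over a batch and its exact gradient wrt Theta.

    ``Z`` is the (B, N) assemblage batch, ``P`` the matching compositions.
    The forward path is identical to :func:`cnode.core.predict_batch`
    (integration, clipping, renormalization), so the gradient matches the
    reported loss to machine precision.
    """
    Z = np.asarray(Z)
    P = np.asarray(P, dtype=float)
    B = Z.shape[0]
    if B == 0:
        raise ValueError("empty batch")
    H0 = Z / Z.sum(axis=1, keepdims=True)
    tape = forward_tape(model, H0)
    Hf = tape[-1]
    Phat = _clip_renorm(Hf, Z)

    value_fn, grad_fn = get_dissimilarity(dissimilarity)
    losses = np.asarray(value_fn(P, Phat))
    loss = float(losses.mean())

    W_phat = grad_fn(P, Phat) / B
    # back through p = m / t with m = max(h, 0) * [z > 0], t = sum(m)
    mask = (Z > 0) & (Hf > 0)
    totals = np.where(Z > 0, np.maximum(Hf, 0.0), 0.0).sum(axis=1)
    inner = np.einsum("bi,bi->b", W_phat, Phat)
    W_h = np.where(mask, (W_phat - inner[:, None]) / totals[:, None], 0.0)

    grad_theta = backward_from_tape(model, tape, W_h)
    if not np.isfinite(grad_theta).all():
        raise FloatingPointError("non-finite gradient")
    return loss, grad_theta
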
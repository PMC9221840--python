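"""Dissimilarity measures between compositions, with gradients.

Bray-Curtis is the default training loss and reporting metric.  For simplex
vectors it reduces to half the L1 distance, (1/2) sum_i |p_i - q_i|, which
equals 1 - sum_i min(p_i, q_i) and coincides with the total-variation
distance.  The root Jensen-Shannon divergence is provided as an alternative
(it is a metric on the simplex and bounded by sqrt(log 2)).

Each measure comes with the gradient of d(p, q) with respect to the
*prediction* q, used by the trainer; the gradients are subgradients at the
non-smooth points (ties contribute zero).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "bray_curtis",
    "total_variation",
    "root_jensen_shannon",
    "get_dissimilarity",
    "pairwise_values",
]

_EPS = 1e-12


def _as_batches(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    scalar = p.ndim == 1
    if p.shape != q.shape:
        raise ValueError(f"dimension mismatch: {p.shape} vs {q.shape}")
    if scalar:
        p, q = p[None, :], q[None, :]
    return p, q, scalar


def bray_curtis(p: np.ndarray, q: np.ndarray) -> float | np.ndarray:
    """(1/2) sum |p_i - q_i| for simplex vectors; in [0, 1]."""
    p, q, scalar = _as_batches(p, q)
    d = 0.5 * np.abs(p - q).sum(axis=1)
    return float(d[0]) if scalar else d


def _bray_curtis_grad(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    return 0.5 * np.sign(q - p)


def total_variation(p: np.ndarray, q: np.ndarray) -> float | np.ndarray:
    """Total-variation distance; identical to Bray-Curtis on the simplex."""
    return bray_curtis(p, q)


def root_jensen_shannon(p: np.ndarray, q: np.ndarray) -> float | np.ndarray:
    """sqrt(JSD(p, q)) with natural-log JSD; zero entries contribute zero."""
    p, q, scalar = _as_batches(p, q)
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(p > 0, p * np.log(p / np.maximum(m, _EPS)), 0.0)
        t2 = np.where(q > 0, q * np.log(q / np.maximum(m, _EPS)), 0.0)
    jsd = np.maximum(0.5 * (t1 + t2).sum(axis=1), 0.0)
    d = np.sqrt(jsd)
    return float(d[0]) if scalar else d


def _rjsd_grad(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    m = 0.5 * (p + q)
    d = np.asarray(root_jensen_shannon(p, q))
    d = np.atleast_1d(d)
    grad_jsd = 0.5 * np.log(np.maximum(q, _EPS) / np.maximum(m, _EPS))
    return grad_jsd / np.maximum(2.0 * d[:, None], _EPS)


_REGISTRY = {
    "bray_curtis": (bray_curtis, _bray_curtis_grad),
    "total_variation": (total_variation, _bray_curtis_grad),
    "root_jensen_shannon": (root_jensen_shannon, _rjsd_grad),
}


def get_dissimilarity(name: str):
    """Return ``(value_fn, grad_fn)`` for a registered measure.

    ``value_fn(P, Q)`` maps (B, N) batches to (B,) values; ``grad_fn(P, Q)``
    returns the (B, N) gradient with respect to ``Q``.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown dissimilarity {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def pairwise_values(name: str, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    value_fn, _ = get_dissimilarity(name)
    return np.asarray(value_fn(P, Q))
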
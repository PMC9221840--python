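"""Performance summaries, the null baseline, and dissimilarity-overlap
universality screening.

The null predictor returns the uniform composition over each sample's
assemblage — exactly what an untrained (Theta = 0) cNODE predicts — and is
the reference point for "did training learn anything".

The dissimilarity-overlap analysis screens a dataset for the signature of
universal dynamics: for every pair of samples, the *overlap* is the mean
total abundance both communities place on their shared taxa, and the
*dissimilarity* is the root Jensen-Shannon divergence between the two
compositions renormalized on the shared support.  Under one shared dynamics
the point cloud shows a negative trend at high overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import spearmanr

from .core import CNODEModel, predict_batch
from .datamodel import MicrobiomeDataset
from .dissimilarity import get_dissimilarity, root_jensen_shannon

__all__ = [
    "EvaluationResult",
    "DOCResult",
    "evaluate",
    "null_predictor_error",
    "dissimilarity_overlap",
]


@dataclass
class EvaluationResult:
    """Per-sample prediction errors with quartile summaries.

    Quartiles use linear interpolation on the sorted errors.  The
    ``representative_indices`` pick the five samples a boxplot-style figure
    would display: minimum error, nearest first quartile, nearest median,
    nearest third quartile, and maximum error.
    """

    per_sample_errors: list[float]
    dissimilarity: str = "bray_curtis"
    median: float = field(init=False)
    q1: float = field(init=False)
    q3: float = field(init=False)

    def __post_init__(self) -> None:
        errs = np.asarray(self.per_sample_errors, dtype=float)
        if errs.size == 0:
            raise ValueError("need at least one error")
        if (errs < 0).any():
            raise ValueError("errors must be nonnegative")
        self.q1, self.median, self.q3 = (
            float(v) for v in np.quantile(errs, [0.25, 0.5, 0.75], method="linear")
        )

    @classmethod
    def from_errors(
        cls, errors, dissimilarity: str = "bray_curtis"
    ) -> "EvaluationResult":
        return cls([float(e) for e in errors], dissimilarity)

    @property
    def S(self) -> int:
        return len(self.per_sample_errors)

    @property
    def representative_indices(self) -> dict[str, int]:
        errs = np.asarray(self.per_sample_errors)
        return {
            "min": int(np.argmin(errs)),
            "q1": int(np.argmin(np.abs(errs - self.q1))),
            "median": int(np.argmin(np.abs(errs - self.median))),
            "q3": int(np.argmin(np.abs(errs - self.q3))),
            "max": int(np.argmax(errs)),
        }

    def summary(self) -> dict:
        return {
            "S": self.S,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "mean": float(np.mean(self.per_sample_errors)),
            "dissimilarity": self.dissimilarity,
        }


def evaluate(
    model: CNODEModel,
    dataset: MicrobiomeDataset,
    dissimilarity: str = "bray_curtis",
) -> EvaluationResult:
    """Per-sample prediction errors of ``model`` on ``dataset``."""
    if dataset.S == 0:
        raise ValueError("empty dataset")
    value_fn, _ = get_dissimilarity(dissimilarity)
    Phat = predict_batch(model, dataset.Z)
    errors = np.asarray(value_fn(dataset.P, Phat))
    return EvaluationResult.from_errors(errors, dissimilarity)


def null_predictor_error(
    dataset: MicrobiomeDataset, dissimilarity: str = "bray_curtis"
) -> float:
    """Mean error of predicting the uniform composition over each assemblage."""
    if dataset.S == 0:
        raise ValueError("empty dataset")
    value_fn, _ = get_dissimilarity(dissimilarity)
    Z = dataset.Z.astype(float)
    U = Z / Z.sum(axis=1, keepdims=True)
    return float(np.asarray(value_fn(dataset.P, U)).mean())


@dataclass
class DOCResult:
    """Pairwise (overlap, dissimilarity) cloud plus a rank-trend summary."""

    pairs: list[tuple[float, float]]
    excluded_pairs: int = 0

    @property
    def overlaps(self) -> np.ndarray:
        return np.array([o for o, _ in self.pairs])

    @property
    def dissimilarities(self) -> np.ndarray:
        return np.array([d for _, d in self.pairs])

    def spearman(self, min_overlap: float | None = None) -> float:
        """Rank correlation of dissimilarity against overlap.

        ``min_overlap`` restricts to the high-overlap region (use the
        median overlap to screen for the universality signature: a
        negative correlation there); nan when fewer than 3 pairs qualify.
        """
        o, d = self.overlaps, self.dissimilarities
        if min_overlap is not None:
            keep = o >= min_overlap
            o, d = o[keep], d[keep]
        if o.size < 3:
            return float("nan")
        return float(spearmanr(o, d).statistic)


def dissimilarity_overlap(dataset: MicrobiomeDataset) -> DOCResult:
    """Dissimilarity-overlap point cloud over all sample pairs.

    For a pair (p, q) with shared support s = supp(p) & supp(q):
    overlap = (1/2) sum_{i in s} (p_i + q_i); dissimilarity = root
    Jensen-Shannon divergence between p and q renormalized on s.  Pairs
    with empty shared support are excluded and counted.
    """
    if dataset.S < 2:
        raise ValueError("need at least 2 samples")
    P = dataset.P
    pairs: list[tuple[float, float]] = []
    excluded = 0
    for a, b in combinations(range(dataset.S), 2):
        p, q = P[a], P[b]
        shared = (p > 0) & (q > 0)
        if not shared.any():
            excluded += 1
            continue
        overlap = 0.5 * (p[shared].sum() + q[shared].sum())
        ps = p[shared] / p[shared].sum()
        qs = q[shared] / q[shared].sum()
        pairs.append((float(overlap), float(root_jensen_shannon(ps, qs))))
    return DOCResult(pairs, excluded)
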
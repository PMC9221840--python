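"""Core data types for assemblage/composition observations.

A microbiome *sample* pairs a binary species assemblage ``z`` (which taxa
are present) with a composition ``p`` on the probability simplex (relative
abundances summing to one).  A dataset is an ordered collection of such
samples over one shared taxon pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = ["TaxonSet", "AssembledSample", "MicrobiomeDataset", "SIMPLEX_ATOL"]

#: tolerance on |sum(p) - 1| accepted by the sample invariant
SIMPLEX_ATOL = 1e-9


@dataclass(frozen=True)
class TaxonSet:
    """An ordered pool of uniquely named taxa."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        if len(self.names) < 1:
            raise ValueError("taxon set must contain at least one taxon")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate taxon names: {dupes}")

    @property
    def N(self) -> int:
        return len(self.names)

    @classmethod
    def generic(cls, N: int, prefix: str = "taxon_") -> "TaxonSet":
        """Placeholder names ``taxon_0 .. taxon_{N-1}``."""
        if N < 1:
            raise ValueError("N must be >= 1")
        return cls(tuple(f"{prefix}{i}" for i in range(N)))

    def __len__(self) -> int:
        return len(self.names)


class AssembledSample:
    """One (assemblage, composition) pair.

    Invariants enforced at construction: ``z`` is binary with at least one
    present taxon; ``p`` is nonnegative and sums to 1 within ``SIMPLEX_ATOL``;
    the support of ``p`` is contained in the support of ``z``.
    """

    __slots__ = ("z", "p")

    def __init__(self, z: Sequence[float], p: Sequence[float]) -> None:
        z_arr = np.asarray(z)
        p_arr = np.asarray(p, dtype=float)
        if z_arr.ndim != 1 or p_arr.ndim != 1 or z_arr.shape != p_arr.shape:
            raise ValueError(
                f"z and p must be 1-d vectors of equal length, got shapes "
                f"{z_arr.shape} and {p_arr.shape}"
            )
        if not np.isin(z_arr, (0, 1)).all():
            raise ValueError("assemblage z must be binary (entries in {0, 1})")
        z_arr = z_arr.astype(np.int8)
        if not z_arr.any():
            raise ValueError("assemblage must contain at least one present taxon")
        if (p_arr < 0).any():
            i = int(np.argmin(p_arr))
            raise ValueError(f"negative relative abundance p[{i}] = {p_arr[i]}")
        total = p_arr.sum()
        if abs(total - 1.0) > SIMPLEX_ATOL:
            raise ValueError(f"composition must sum to 1 (got {total!r})")
        if (p_arr[z_arr == 0] != 0).any():
            i = int(np.nonzero((z_arr == 0) & (p_arr != 0))[0][0])
            raise ValueError(
                f"support violation: taxon {i} absent (z=0) but p[{i}] = {p_arr[i]}"
            )
        self.z = z_arr
        self.z.setflags(write=False)
        self.p = p_arr
        self.p.setflags(write=False)

    @property
    def N(self) -> int:
        return self.z.shape[0]

    @property
    def richness(self) -> int:
        """Number of present taxa."""
        return int(self.z.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssembledSample):
            return NotImplemented
        return bool((self.z == other.z).all() and (self.p == other.p).all())

    def __repr__(self) -> str:
        return f"AssembledSample(N={self.N}, richness={self.richness})"


@dataclass
class MicrobiomeDataset:
    """Ordered samples over one taxon pool.

    Exposes stacked matrix views ``Z`` (S x N, int8) and ``P`` (S x N,
    float) for vectorised computation.
    """

    taxa: TaxonSet
    samples: list[AssembledSample] = field(default_factory=list)
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        for k, s in enumerate(self.samples):
            if s.N != self.taxa.N:
                raise ValueError(
                    f"sample {k} has dimension {s.N}, taxon set has {self.taxa.N}"
                )
        if self.sample_ids is None:
            self.sample_ids = [f"sample_{k}" for k in range(len(self.samples))]
        elif len(self.sample_ids) != len(self.samples):
            raise ValueError("sample_ids length must match number of samples")

    @property
    def N(self) -> int:
        return self.taxa.N

    @property
    def S(self) -> int:
        return len(self.samples)

    @property
    def Z(self) -> np.ndarray:
        return np.stack([s.z for s in self.samples]) if self.samples else np.zeros(
            (0, self.N), dtype=np.int8
        )

    @property
    def P(self) -> np.ndarray:
        return np.stack([s.p for s in self.samples]) if self.samples else np.zeros(
            (0, self.N)
        )

    @classmethod
    def from_matrices(
        cls,
        taxa: TaxonSet,
        P: np.ndarray,
        Z: np.ndarray | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "MicrobiomeDataset":
        """Build a dataset from stacked composition (and optional assemblage)
        matrices; assemblages default to the strict nonzero pattern of ``P``."""
        P = np.asarray(P, dtype=float)
        if P.ndim != 2 or P.shape[1] != taxa.N:
            raise ValueError(f"P must be S x {taxa.N}, got shape {P.shape}")
        if Z is None:
            Z = (P > 0).astype(np.int8)
        samples = [AssembledSample(z, p) for z, p in zip(np.asarray(Z), P)]
        ids = list(sample_ids) if sample_ids is not None else None
        return cls(taxa, samples, ids)

    def subset(self, indices: Iterable[int]) -> "MicrobiomeDataset":
        idx = list(indices)
        return MicrobiomeDataset(
            self.taxa,
            [self.samples[i] for i in idx],
            [self.sample_ids[i] for i in idx],
        )

    def concat(self, other: "MicrobiomeDataset") -> "MicrobiomeDataset":
        if other.taxa.names != self.taxa.names:
            raise ValueError("cannot concatenate datasets over different taxon sets")
        return MicrobiomeDataset(
            self.taxa,
            self.samples + other.samples,
            list(self.sample_ids) + list(other.sample_ids),
        )

    def __len__(self) -> int:
        return self.S

    def __iter__(self) -> Iterator[AssembledSample]:
        return iter(self.samples)

    def __getitem__(self, k: int) -> AssembledSample:
        return self.samples[k]

    def __repr__(self) -> str:
        return f"MicrobiomeDataset(S={self.S}, N={self.N})"
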
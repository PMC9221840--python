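"""Reading, writing and splitting delimited sample tables.

Tables are delimited text (TSV by default, CSV accepted): first row taxon
names, first column sample IDs, samples as rows.  Relative-abundance tables
in the wild sum to 1, 100 or raw read counts per sample, so compositions are
always renormalized on load.  An optional companion table with entries in
{0, 1} supplies the assemblage explicitly (e.g. when an introduced species
went extinct and is absent from the measured composition but present in the
experimental design).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import AssembledSample, MicrobiomeDataset, TaxonSet

__all__ = ["load_dataset", "save_dataset", "split_dataset"]


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric entries in {path}: {exc}") from exc
    return df


def load_dataset(
    path: str | Path,
    *,
    delimiter: str | None = None,
    orientation: str = "samples_as_rows",
    assemblage_path: str | Path | None = None,
    taxa: TaxonSet | None = None,
    detection_threshold: float = 0.0,
) -> MicrobiomeDataset:
    """Read a delimited abundance table as a :class:`MicrobiomeDataset`.

    Parameters
    ----------
    path:
        Abundance table; rows are samples, columns taxa (unless
        ``orientation="taxa_as_rows"``).  Delimiter defaults to tab, or
        comma for ``.csv`` files.
    orientation:
        ``"samples_as_rows"`` (default), ``"taxa_as_rows"``, or ``"auto"``
        which requires ``taxa`` and matches its names against either axis.
    assemblage_path:
        Optional companion binary table of the same shape and labels giving
        the assemblage; defaults to the strict nonzero pattern of ``p``.
    detection_threshold:
        Abundances at or below this value (after renormalization) are
        treated as absent.  Zero (default) keeps the strict nonzero pattern;
        a small positive value suppresses sequencing-noise presences in
        real tables.
    """
    df = _read_table(path, delimiter)

    if orientation == "auto":
        if taxa is None:
            raise ValueError("orientation='auto' requires a taxon list to match")
        if list(df.columns) == list(taxa.names):
            pass
        elif list(df.index) == list(taxa.names):
            df = df.T
        else:
            raise ValueError("could not match taxon names to either table axis")
    elif orientation == "taxa_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation: {orientation!r}")

    P = df.to_numpy(dtype=float)
    if (P < 0).any():
        i, j = map(int, np.argwhere(P < 0)[0])
        raise ValueError(
            f"negative abundance at sample {df.index[i]!r}, taxon "
            f"{df.columns[j]!r}: {P[i, j]}"
        )
    row_sums = P.sum(axis=1)
    if (row_sums == 0).any():
        i = int(np.argmin(row_sums))
        raise ValueError(f"sample {df.index[i]!r} has all-zero abundances")
    P = P / row_sums[:, None]
    if detection_threshold > 0:
        P = np.where(P <= detection_threshold, 0.0, P)
        sums = P.sum(axis=1)
        if (sums == 0).any():
            i = int(np.argmin(sums))
            raise ValueError(
                f"detection threshold {detection_threshold} removed every taxon "
                f"of sample {df.index[i]!r}"
            )
        P = P / sums[:, None]

    tset = TaxonSet(tuple(df.columns))

    Z = None
    if assemblage_path is not None:
        zdf = _read_table(assemblage_path, delimiter)
        if orientation == "taxa_as_rows":
            zdf = zdf.T
        if list(zdf.columns) != list(df.columns) or list(zdf.index) != list(df.index):
            raise ValueError(
                "assemblage table labels do not match the abundance table"
            )
        Z = zdf.to_numpy()
        if not np.isin(Z, (0, 1)).all():
            raise ValueError("assemblage table entries must be 0 or 1")
        Z = Z.astype(np.int8)

    return MicrobiomeDataset.from_matrices(
        tset, P, Z=Z, sample_ids=[str(i) for i in df.index]
    )


def save_dataset(
    dataset: MicrobiomeDataset, path: str | Path, *, delimiter: str | None = None
) -> None:
    """Write the composition table at full float precision (round-trip safe)."""
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(dataset.P, index=dataset.sample_ids, columns=dataset.taxa.names)
    df.index.name = "sample_id"
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def split_dataset(
    dataset: MicrobiomeDataset, test_fraction: float, seed: int
) -> tuple[MicrobiomeDataset, MicrobiomeDataset]:
    """Random disjoint train/test partition.

    Sizes are ``round(S * (1 - f))`` and the complement; the split is a
    seeded permutation, so the same seed always yields the same partition.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    S = dataset.S
    if S < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = round(S * (1.0 - test_fraction))
    n_train = min(max(n_train, 1), S - 1)  # both parts nonempty
    perm = np.random.default_rng(seed).permutation(S)
    return dataset.subset(np.sort(perm[:n_train])), dataset.subset(
        np.sort(perm[n_train:])
    )
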
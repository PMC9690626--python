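"""Binary band matrices for dominant molecular markers.

Dominant marker systems (ISSR, SCoT, protein SDS-PAGE profiles) are scored
as the presence (1) or absence (0) of an electrophoretic band in each
accession.  This module holds the scored matrix, classifies each band as
monomorphic / unique / non-unique polymorphic, reads and writes the CSV
dialect used throughout the package, and reconstructs matrices from
published band-class counts (useful when a study reports only the counts).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerSystem",
    "BandMatrix",
    "BandClassCounts",
    "read_band_csv",
    "write_band_csv",
    "classify_bands",
    "matrix_from_composition",
]


class MarkerSystem(str, enum.Enum):
    """Marker technology a band matrix came from."""

    ISSR = "ISSR"
    SCOT = "SCoT"
    PROTEIN = "PROTEIN"
    OTHER = "OTHER"


class BandMatrixError(ValueError):
    """Invalid band matrix content (non-binary cells, empty bands...)."""


@dataclass
class BandMatrix:
    """Presence/absence matrix of one primer's bands across accessions.

    Parameters
    ----------
    primer_id:
        Label of the primer (or gel) that produced the bands.
    marker_system:
        Technology that produced the profile (``ISSR``, ``SCoT``,
        ``PROTEIN`` or ``OTHER``).
    accession_ids:
        Row labels; at least two distinct accessions.
    presence:
        ``(A, B)`` array of 0/1 values, one row per accession, one column
        per band.  Every band must be observed in at least one accession —
        an all-zero column is a scoring artifact and is rejected.
    band_labels:
        Column labels; generated as ``band1..bandB`` when omitted.
    band_sizes:
        Optional fragment sizes (bp, or kDa for protein profiles); must be
        positive and one per band.
    """

    primer_id: str
    marker_system: MarkerSystem
    accession_ids: list[str]
    presence: np.ndarray
    band_labels: list[str] = field(default_factory=list)
    band_sizes: list[float] | None = None

    def __post_init__(self) -> None:
        self.marker_system = MarkerSystem(self.marker_system)
        self.presence = np.asarray(self.presence)
        if self.presence.ndim != 2:
            raise BandMatrixError("presence must be a 2-D matrix")
        a, b = self.presence.shape
        if a < 2:
            raise BandMatrixError("need at least two accessions")
        if b < 1:
            raise BandMatrixError("need at least one band")
        if len(self.accession_ids) != a:
            raise BandMatrixError("accession_ids length does not match matrix")
        if len(set(self.accession_ids)) != a:
            dupes = {x for x in self.accession_ids if self.accession_ids.count(x) > 1}
            raise BandMatrixError(f"duplicate accession id(s): {sorted(dupes)}")
        if not np.isin(self.presence, (0, 1)).all():
            raise BandMatrixError("presence cells must be 0 or 1")
        self.presence = self.presence.astype(np.int8)
        zero = np.flatnonzero(self.presence.sum(axis=0) == 0)
        if zero.size:
            raise BandMatrixError(
                f"band column(s) {zero.tolist()} are all-zero; a never-observed "
                "band is not a band"
            )
        if not self.band_labels:
            self.band_labels = [f"band{i + 1}" for i in range(b)]
        if len(self.band_labels) != b:
            raise BandMatrixError("band_labels length does not match matrix")
        if self.band_sizes is not None:
            if len(self.band_sizes) != b:
                raise BandMatrixError("band_sizes length does not match matrix")
            if any(s <= 0 for s in self.band_sizes):
                raise BandMatrixError("band sizes must be positive")

    @property
    def n_accessions(self) -> int:
        return self.presence.shape[0]

    @property
    def n_bands(self) -> int:
        return self.presence.shape[1]

    def band_frequencies(self) -> np.ndarray:
        """Fraction of accessions carrying each band (column means)."""
        return self.presence.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence, index=self.accession_ids, columns=self.band_labels
        )


@dataclass(frozen=True)
class BandClassCounts:
    """Partition of a primer's bands into the standard diversity classes.

    ``MB`` monomorphic (present in every accession), ``UB`` unique
    (present in exactly one), ``NB`` non-unique polymorphic (present in
    more than one but not all).  ``PB = UB + NB`` and ``TB = MB + PB``.
    """

    MB: int
    UB: int
    NB: int
    per_band_freq: tuple[float, ...]

    @property
    def PB(self) -> int:
        return self.UB + self.NB

    @property
    def TB(self) -> int:
        return self.MB + self.UB + self.NB

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.MB, self.UB, self.NB)


def classify_bands(m: BandMatrix) -> BandClassCounts:
    """Count monomorphic, unique and non-unique polymorphic bands.

    Classes are derived from band frequencies: a band carried by all
    accessions is monomorphic, by exactly one accession unique, and
    otherwise non-unique polymorphic.  This works for any number of
    accessions, not just three.
    """
    counts = m.presence.sum(axis=0)
    a = m.n_accessions
    mb = int((counts == a).sum())
    ub = int((counts == 1).sum()) if a > 1 else 0
    nb = m.n_bands - mb - ub
    return BandClassCounts(
        MB=mb, UB=ub, NB=nb, per_band_freq=tuple(counts / a)
    )


def matrix_from_composition(
    MB: int,
    UB: int,
    NB: int,
    A: int = 3,
    seed: int | np.random.Generator = 0,
    primer_id: str = "primer",
    marker_system: MarkerSystem | str = MarkerSystem.OTHER,
    accession_ids: Sequence[str] | None = None,
    unique_owners: Sequence[str] | None = None,
    close_pair: tuple[str, str] | None = None,
) -> BandMatrix:
    """Build a band matrix realizing the requested band-class counts.

    The accession carrying each unique band, and the accessions lacking
    each non-unique polymorphic band, are drawn from the seeded RNG
    (or fixed through ``unique_owners``, one accession id per unique
    band).  ``classify_bands`` on the result reproduces ``(MB, UB, NB)``
    exactly; for three accessions every non-unique band has frequency
    2/3 and every unique band 1/3.

    With three accessions, ``close_pair`` biases which pair shares each
    non-unique band: the named pair with probability 1/2, the other two
    pairs 1/4 each (genetically close accessions co-occur more often on
    shared bands).  Without it every eligible subset is equally likely.

    Raises
    ------
    ValueError
        If the composition is infeasible, e.g. a non-unique polymorphic
        band with fewer than three accessions, or no bands at all.
    """
    if min(MB, UB, NB) < 0:
        raise ValueError("band-class counts must be non-negative")
    if MB + UB + NB < 1:
        raise ValueError("composition must contain at least one band")
    if A < 2:
        raise ValueError("need at least two accessions")
    if NB > 0 and A < 3:
        raise ValueError(
            "a non-unique polymorphic band needs >=2 but not all accessions; "
            "infeasible with fewer than three accessions"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if accession_ids is None:
        accession_ids = [f"C{i + 1}" for i in range(A)]
    accession_ids = list(accession_ids)
    if len(accession_ids) != A:
        raise ValueError("accession_ids length must equal A")
    if unique_owners is not None and len(unique_owners) != UB:
        raise ValueError("unique_owners must name one accession per unique band")

    cols: list[np.ndarray] = []
    for _ in range(MB):
        cols.append(np.ones(A, dtype=np.int8))
    for i in range(UB):
        col = np.zeros(A, dtype=np.int8)
        if unique_owners is not None:
            owner = accession_ids.index(unique_owners[i])
        else:
            owner = rng.integers(A)
        col[owner] = 1
        cols.append(col)
    pair_idx = None
    if close_pair is not None and A == 3:
        try:
            pair_idx = tuple(accession_ids.index(x) for x in close_pair)
        except ValueError as exc:
            raise ValueError(f"close_pair names unknown accession: {exc}") from exc
    for _ in range(NB):
        col = np.zeros(A, dtype=np.int8)
        if pair_idx is not None:
            pairs = [set(pair_idx)] + [
                {i, j} for i in range(3) for j in range(i + 1, 3)
                if {i, j} != set(pair_idx)
            ]
            chosen = pairs[rng.choice(3, p=[0.5, 0.25, 0.25])]
            col[list(chosen)] = 1
        else:
            # present in k accessions, 2 <= k <= A-1
            k = int(rng.integers(2, A)) if A > 3 else 2
            col[rng.choice(A, size=k, replace=False)] = 1
        cols.append(col)
    return BandMatrix(
        primer_id=primer_id,
        marker_system=marker_system,
        accession_ids=accession_ids,
        presence=np.column_stack(cols),
    )


def read_band_csv(path: str | Path) -> BandMatrix:
    """Read a band matrix from CSV.

    Dialect: comma-separated UTF-8; header row holds band labels, first
    column holds accession ids, cells are 0/1.  The primer id defaults to
    the file stem; marker system to ``OTHER`` unless the stem starts with
    a known system name (``ISSR``, ``SCoT``...).
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    values = np.empty(df.shape, dtype=np.int8)
    for j, col in enumerate(df.columns):
        for i, idx in enumerate(df.index):
            cell = df.iat[i, j].strip()
            if cell not in ("0", "1"):
                raise BandMatrixError(
                    f"{path.name}: cell at accession {idx!r}, band {col!r} is "
                    f"{cell!r}; expected 0 or 1"
                )
            values[i, j] = int(cell)
    system = MarkerSystem.OTHER
    stem = path.stem
    for cand in (MarkerSystem.ISSR, MarkerSystem.SCOT, MarkerSystem.PROTEIN):
        if stem.upper().startswith(cand.value.upper()):
            system = cand
            break
    return BandMatrix(
        primer_id=stem,
        marker_system=system,
        accession_ids=[str(x) for x in df.index],
        presence=values,
        band_labels=[str(c) for c in df.columns],
    )


def write_band_csv(m: BandMatrix, path: str | Path) -> None:
    """Write a band matrix in the same CSV dialect ``read_band_csv`` reads."""
    m.to_frame().to_csv(Path(path), index_label="accession")
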
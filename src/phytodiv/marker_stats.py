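"""Per-primer informativeness statistics for dominant markers.

For a primer scored on ``A`` accessions the module computes the standard
panel used to rank primers in diversity surveys:

* **PIC** — polymorphism information content.  Each band is treated as a
  biallelic dominant locus with presence frequency ``p``; the per-band
  information ``1 - p^2 - (1-p)^2 = 2p(1-p)`` is averaged over all bands,
  which bounds PIC at 0.5 for dominant data.
* **EMR** — effective multiplex ratio, ``PB^2 / TB`` where ``PB`` is the
  number of polymorphic bands and ``TB`` the total: the polymorphic band
  count weighted by the polymorphic fraction of the assay.
* **MI** — marker index, ``PIC x EMR``.
* **RP** — resolving power, the sum of per-band informativeness ``Ib``.
  Two conventions are offered: ``doubled_frequency`` with ``Ib = 2 p``
  (the convention under which published RP columns of three-accession
  dominant-marker tables are reproducible) and ``prevost`` with
  ``Ib = 1 - 2|0.5 - p|`` (the common literature form).
* **P%** — percentage of polymorphic bands, ``100 PB / TB``.

Published PIC values are often not reproducible from band-class counts
alone (the computing path of many reports is unstated); ``summarize``
therefore accepts per-primer PIC overrides so that MI can be formed from
a published PIC together with the computed EMR.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .band_matrix import BandClassCounts, BandMatrix, classify_bands

__all__ = [
    "RPConvention",
    "PICMethod",
    "PrimerStats",
    "MarkerSummary",
    "pic",
    "emr",
    "mi",
    "rp",
    "polymorphism_pct",
    "summarize",
    "round_half_up",
]


class RPConvention(str, enum.Enum):
    DOUBLED_FREQUENCY = "doubled_frequency"
    PREVOST = "prevost"


class PICMethod(str, enum.Enum):
    BAND_2PQ_MEAN = "band_2pq_mean"
    EXTERNAL = "external"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as diversity tables are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pic(m: BandMatrix, method: PICMethod | str = PICMethod.BAND_2PQ_MEAN) -> float:
    """Polymorphism information content of a primer.

    With the default ``band_2pq_mean`` method each band is a dominant
    biallelic locus of presence frequency ``p`` contributing
    ``1 - p^2 - (1-p)^2``; the mean over all bands lies in [0, 0.5] and is
    0 for an all-monomorphic primer.
    """
    method = PICMethod(method)
    if method is not PICMethod.BAND_2PQ_MEAN:
        raise ValueError(f"pic cannot be computed with method {method.value!r}")
    p = m.band_frequencies()
    return float(np.mean(1.0 - p**2 - (1.0 - p) ** 2))


def emr(counts: BandClassCounts) -> float:
    """Effective multiplex ratio ``PB * (PB / TB)``.

    The polymorphic band count scaled by the polymorphic fraction of the
    assay; 0 when no band is polymorphic, and at most ``TB`` (equality
    when every band is polymorphic).
    """
    if counts.TB < 1:
        raise ValueError("EMR needs at least one band")
    return counts.PB**2 / counts.TB


def mi(PIC: float, EMR: float) -> float:
    """Marker index: the product of PIC and EMR."""
    if PIC < 0 or EMR < 0:
        raise ValueError("PIC and EMR must be non-negative")
    return PIC * EMR


def rp(
    m: BandMatrix,
    convention: RPConvention | str = RPConvention.DOUBLED_FREQUENCY,
) -> float:
    """Resolving power: sum of per-band informativeness ``Ib``.

    ``doubled_frequency`` uses ``Ib = 2 p`` (each monomorphic band adds 2);
    ``prevost`` uses ``Ib = 1 - 2|0.5 - p|`` which peaks for bands carried
    by half the accessions.
    """
    convention = RPConvention(convention)
    p = m.band_frequencies()
    if convention is RPConvention.DOUBLED_FREQUENCY:
        ib = 2.0 * p
    else:
        ib = 1.0 - 2.0 * np.abs(0.5 - p)
    return float(ib.sum())


def polymorphism_pct(counts: BandClassCounts) -> float:
    """Percentage of polymorphic bands, ``100 * PB / TB``."""
    if counts.TB < 1:
        raise ValueError("polymorphism percentage needs at least one band")
    return 100.0 * counts.PB / counts.TB


@dataclass(frozen=True)
class PrimerStats:
    """The informativeness panel of one primer."""

    primer_id: str
    counts: BandClassCounts
    PIC: float
    EMR: float
    MI: float
    RP: float
    P_pct: float
    rp_convention: RPConvention
    pic_method: PICMethod

    def as_row(self) -> dict[str, float | str | int]:
        c = self.counts
        return {
            "primer": self.primer_id,
            "MB": c.MB,
            "UB": c.UB,
            "NB": c.NB,
            "PB": c.PB,
            "TB": c.TB,
            "PIC": self.PIC,
            "EMR": self.EMR,
            "MI": self.MI,
            "RP": self.RP,
            "P_pct": self.P_pct,
        }


_NUMERIC = ["MB", "UB", "NB", "PB", "TB", "PIC", "EMR", "MI", "RP", "P_pct"]


@dataclass(frozen=True)
class MarkerSummary:
    """Per-primer panels plus the totals/averages block of a marker table."""

    per_primer: tuple[PrimerStats, ...]
    totals: Mapping[str, float]
    averages: Mapping[str, float]
    overall_P_pct: float

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        """Tabulate primers with Total and Average rows appended.

        ``rounded`` applies the half-up 2-decimal presentation used in
        printed tables; internal values are kept at full precision.
        """
        rows = [s.as_row() for s in self.per_primer]
        total = {"primer": "Total", **{k: self.totals[k] for k in _NUMERIC}}
        avg = {"primer": "Average", **{k: self.averages[k] for k in _NUMERIC}}
        # pooled, not mean-of-percentages
        total["P_pct"] = avg["P_pct"] = self.overall_P_pct
        df = pd.DataFrame(rows + [total, avg]).set_index("primer")
        for col in ("MB", "UB", "NB", "PB", "TB"):
            # integral everywhere except the Average row
            df[col] = df[col].map(
                lambda v: int(v) if float(v).is_integer() else round(float(v), 2)
            )
        if rounded:
            for col in ("PIC", "EMR", "MI", "RP", "P_pct"):
                df[col] = df[col].map(lambda v: round_half_up(v, 2))
        return df


def summarize(
    matrices: Sequence[BandMatrix],
    pic_overrides: Mapping[str, float] | None = None,
    rp_convention: RPConvention | str = RPConvention.DOUBLED_FREQUENCY,
) -> MarkerSummary:
    """Summarize a set of primers scored on the same accessions.

    ``pic_overrides`` maps primer ids to externally supplied PIC values
    (e.g. published ones); overridden primers are flagged
    ``pic_method = external`` and their MI uses the supplied PIC.  The
    overall polymorphism percentage is pooled (``100 ΣPB / ΣTB``), never
    the mean of per-primer percentages.
    """
    if not matrices:
        raise ValueError("summarize needs at least one band matrix")
    ref = matrices[0].accession_ids
    for m in matrices[1:]:
        if m.accession_ids != ref:
            raise ValueError(
                f"primer {m.primer_id!r} scored on different accessions "
                f"({m.accession_ids} vs {ref})"
            )
    rp_convention = RPConvention(rp_convention)
    pic_overrides = dict(pic_overrides or {})

    stats: list[PrimerStats] = []
    for m in matrices:
        counts = classify_bands(m)
        e = emr(counts)
        if m.primer_id in pic_overrides:
            p = float(pic_overrides[m.primer_id])
            method = PICMethod.EXTERNAL
        else:
            p = pic(m)
            method = PICMethod.BAND_2PQ_MEAN
        stats.append(
            PrimerStats(
                primer_id=m.primer_id,
                counts=counts,
                PIC=p,
                EMR=e,
                MI=mi(p, e),
                RP=rp(m, rp_convention),
                P_pct=polymorphism_pct(counts),
                rp_convention=rp_convention,
                pic_method=method,
            )
        )
    rows = pd.DataFrame([s.as_row() for s in stats])
    totals = rows[_NUMERIC].sum().to_dict()
    averages = rows[_NUMERIC].mean().to_dict()
    overall = 100.0 * totals["PB"] / totals["TB"]
    return MarkerSummary(
        per_primer=tuple(stats),
        totals=totals,
        averages=averages,
        overall_P_pct=overall,
    )
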
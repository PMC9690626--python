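"""Relative qPCR quantification by the 2^-ddCt (Livak) method.

Replicate threshold cycles (CT) are reduced per replicate to
dCt = CT_target - CT_reference, averaged, referenced to a calibrator
sample (ddCt = dCt_sample - dCt_calibrator) and expressed as a fold
change 2^-ddCt.  Amplification efficiency is fixed at 2 per cycle; no
efficiency correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CtTable", "FoldChange", "delta_ct", "fold_changes", "read_ct_csv"]

_COLUMNS = ["sample", "gene", "replicate", "ct"]


@dataclass
class CtTable:
    """Replicate CT measurements with a reference gene and calibrator.

    ``data`` columns: ``sample``, ``gene``, ``replicate``, ``ct``.  Every
    sample must carry the reference gene; CTs must be finite and > 0.
    """

    data: pd.DataFrame
    reference_gene: str
    calibrator: str

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"CT table missing column(s): {missing}")
        df = self.data[_COLUMNS].copy()
        df["ct"] = pd.to_numeric(df["ct"])
        if not np.isfinite(df["ct"]).all() or (df["ct"] <= 0).any():
            raise ValueError("CT values must be finite and positive")
        samples = df["sample"].unique()
        if self.calibrator not in samples:
            raise ValueError(f"calibrator sample {self.calibrator!r} not in table")
        for s in samples:
            genes = set(df.loc[df["sample"] == s, "gene"])
            if self.reference_gene not in genes:
                raise ValueError(
                    f"sample {s!r} lacks reference gene {self.reference_gene!r}"
                )
        self.data = df

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))

    @property
    def target_genes(self) -> list[str]:
        return [g for g in dict.fromkeys(self.data["gene"]) if g != self.reference_gene]


@dataclass(frozen=True)
class FoldChange:
    """Relative expression of one gene in one sample."""

    sample: str
    gene: str
    mean_dct: float
    sd_dct: float
    ddct: float
    fold: float
    fold_lo: float
    fold_hi: float

    @property
    def sd_fold(self) -> float:
        """Half the fold range spanned by mean dCt +/- SD(dCt)."""
        return (self.fold_hi - self.fold_lo) / 2.0


def delta_ct(ct_target: float, ct_ref: float) -> float:
    """dCt = CT_target - CT_reference (Livak sign convention)."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_ref)):
        raise ValueError("CT values must be finite")
    return ct_target - ct_ref


def _replicate_dcts(df: pd.DataFrame, sample: str, gene: str, ref: str) -> np.ndarray:
    sub = df[df["sample"] == sample]
    tgt = sub[sub["gene"] == gene].set_index("replicate")["ct"]
    rfs = sub[sub["gene"] == ref].set_index("replicate")["ct"]
    shared = tgt.index.intersection(rfs.index)
    if len(shared) == 0:
        raise ValueError(
            f"no replicate of gene {gene!r} in sample {sample!r} can be paired "
            f"with a reference replicate"
        )
    return (tgt.loc[shared] - rfs.loc[shared]).to_numpy(float)


def fold_changes(t: CtTable) -> list[FoldChange]:
    """Fold change per (sample, target gene) relative to the calibrator.

    Replicates are paired with the reference gene by replicate index and
    averaged at the dCt level.  The calibrator sample has fold 1 for
    every gene by construction.  ``fold_lo``/``fold_hi`` propagate the
    replicate spread as the fold range over mean dCt +/- SD(dCt).
    """
    df = t.data
    out: list[FoldChange] = []
    for gene in t.target_genes:
        with_gene = set(df.loc[df["gene"] == gene, "sample"])
        if t.calibrator not in with_gene:
            raise ValueError(
                f"calibrator {t.calibrator!r} has no measurements for gene {gene!r}"
            )
        cal_dct = float(np.mean(_replicate_dcts(df, t.calibrator, gene, t.reference_gene)))
        for sample in t.samples:
            if sample not in with_gene:
                raise ValueError(
                    f"sample {sample!r} has no measurements for gene {gene!r}"
                )
            dcts = _replicate_dcts(df, sample, gene, t.reference_gene)
            mean_dct = float(np.mean(dcts))
            sd_dct = float(np.std(dcts, ddof=1)) if len(dcts) > 1 else 0.0
            ddct = mean_dct - cal_dct
            out.append(
                FoldChange(
                    sample=sample,
                    gene=gene,
                    mean_dct=mean_dct,
                    sd_dct=sd_dct,
                    ddct=ddct,
                    fold=float(2.0 ** -ddct),
                    fold_lo=float(2.0 ** -(ddct + sd_dct)),
                    fold_hi=float(2.0 ** -(ddct - sd_dct)),
                )
            )
    return out


def fold_change_frame(changes: list[FoldChange]) -> pd.DataFrame:
    """Tabulate a list of fold changes."""
    return pd.DataFrame(
        [
            {
                "sample": c.sample,
                "gene": c.gene,
                "mean_dct": c.mean_dct,
                "sd_dct": c.sd_dct,
                "ddct": c.ddct,
                "fold": c.fold,
                "fold_lo": c.fold_lo,
                "fold_hi": c.fold_hi,
            }
            for c in changes
        ]
    )


def read_ct_csv(
    path: str | Path, reference_gene: str, calibrator: str
) -> CtTable:
    """Read a CT table CSV with columns sample, gene, replicate, ct."""
    return CtTable(
        data=pd.read_csv(path), reference_gene=reference_gene, calibrator=calibrator
    )
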
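"""Replicate-trait statistics: ANOVA, Duncan letter groups, Pearson matrix.

Phytochemical and enzyme-activity assays are typically reported as the
mean +/- SD of a few replicates per accession, compared by one-way ANOVA
followed by Duncan's multiple range test (letter display), with trait
co-variation summarized as a Pearson correlation matrix.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitTable",
    "AnovaResult",
    "DuncanGroups",
    "anova_oneway",
    "duncan",
    "pearson_matrix",
    "read_trait_csv",
]


@dataclass
class TraitTable:
    """Long-format replicate measurements: accession, trait, replicate, value."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["accession", "trait", "replicate", "value"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"trait table missing column(s): {missing}")
        df = self.data.copy()
        df["value"] = pd.to_numeric(df["value"])
        if not np.isfinite(df["value"]).all():
            raise ValueError("trait values must be finite")
        self.data = df

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.data["trait"]))

    @property
    def accessions(self) -> list[str]:
        return list(dict.fromkeys(self.data["accession"]))

    def groups(self, trait: str) -> dict[str, np.ndarray]:
        sub = self.data[self.data["trait"] == trait]
        if sub.empty:
            raise KeyError(f"no measurements for trait {trait!r}")
        return {
            acc: grp["value"].to_numpy(float)
            for acc, grp in sub.groupby("accession", sort=False)
        }


def read_trait_csv(path: str | Path) -> TraitTable:
    return TraitTable(data=pd.read_csv(path))


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    ms_error: float


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA from the between/within decomposition.

    Degenerate inputs: if the within-group variance is zero, F is 0 when
    the means are equal too (no signal, no noise) and infinite otherwise.
    """
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least two replicates")
    values = np.concatenate(list(arrays.values()))
    grand = values.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in arrays.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    df_b = len(arrays) - 1
    df_w = values.size - len(arrays)
    ms_error = ss_within / df_w
    if ss_within == 0:
        if np.isclose(ss_between, 0):
            return AnovaResult(F=0.0, p=1.0, df_between=df_b, df_within=df_w,
                               ms_error=0.0)
        return AnovaResult(F=np.inf, p=0.0, df_between=df_b, df_within=df_w,
                           ms_error=0.0)
    f_val = (ss_between / df_b) / ms_error
    p = float(stats.f.sf(f_val, df_b, df_w))
    return AnovaResult(F=float(f_val), p=p, df_between=df_b, df_within=df_w,
                       ms_error=float(ms_error))


@dataclass(frozen=True)
class DuncanGroups:
    """Duncan's multiple-range-test letter display.

    Accessions sharing any letter are not significantly different at
    ``alpha``; letters are assigned in descending-mean order.
    """

    means: dict[str, float]
    letters: dict[str, str]
    alpha: float


def _duncan_ranges(k_max: int, df_error: int, ms_error: float, n: float,
                   alpha: float) -> dict[int, float]:
    """Least significant ranges R_k for spans of k ordered means.

    Duncan's protection level for a span of k means is
    ``alpha_k = 1 - (1 - alpha)^(k-1)``; the critical value is the
    studentized-range quantile at that level.
    """
    se = np.sqrt(ms_error / n)
    ranges = {}
    for k in range(2, k_max + 1):
        alpha_k = 1.0 - (1.0 - alpha) ** (k - 1)
        q = stats.studentized_range.ppf(1.0 - alpha_k, k, df_error)
        ranges[k] = float(q * se)
    return ranges


def duncan(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> DuncanGroups:
    """Duncan's multiple range test with the standard letter display.

    Means are sorted in descending order and every span of adjacent means
    is tested against its least significant range (studentized-range
    quantile at Duncan's protection level); the step-down rule declares
    all sub-spans of a non-significant span non-significant.  Unequal
    replicate counts are handled with the harmonic mean n (warning).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be inside (0, 1)")
    res = anova_oneway(groups)
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    sizes = [v.size for v in arrays.values()]
    if len(set(sizes)) > 1:
        warnings.warn("unequal replicate counts; using harmonic-mean n")
        n = len(sizes) / sum(1.0 / s for s in sizes)
    else:
        n = float(sizes[0])

    order = sorted(arrays, key=lambda k: -arrays[k].mean())
    means = {k: float(arrays[k].mean()) for k in order}
    k_tot = len(order)
    if res.ms_error == 0:
        # zero noise: distinct means are trivially separated
        distinct: list[float] = []
        letters = {}
        for acc in order:
            m = means[acc]
            match = next((i for i, dm in enumerate(distinct) if np.isclose(dm, m)),
                         None)
            if match is None:
                distinct.append(m)
                match = len(distinct) - 1
            letters[acc] = _letter(match)
        return DuncanGroups(means=means, letters=letters, alpha=alpha)

    ranges = _duncan_ranges(k_tot, res.df_within, res.ms_error, n, alpha)
    mean_vec = [means[k] for k in order]

    ns_spans: list[tuple[int, int]] = []

    def subdivide(i: int, j: int) -> None:
        if i >= j:
            return
        if mean_vec[i] - mean_vec[j] <= ranges[j - i + 1]:
            ns_spans.append((i, j))
            return
        subdivide(i, j - 1)
        subdivide(i + 1, j)

    subdivide(0, k_tot - 1)
    # keep maximal spans only
    maximal = [
        s for s in ns_spans
        if not any(o != s and o[0] <= s[0] and s[1] <= o[1] for o in ns_spans)
    ]
    maximal.sort()
    covered = set()
    for i, j in maximal:
        covered.update(range(i, j + 1))
    spans = sorted(maximal + [(i, i) for i in range(k_tot) if i not in covered])

    letters = {acc: "" for acc in order}
    for rank, (i, j) in enumerate(spans):
        for pos in range(i, j + 1):
            letters[order[pos]] += _letter(rank)
    return DuncanGroups(means=means, letters=letters, alpha=alpha)


def _letter(i: int) -> str:
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = alphabet[rem] + out
    return out


class Aggregate(str, enum.Enum):
    REPLICATE_LEVEL = "replicate_level"
    MEAN_LEVEL = "mean_level"


def pearson_matrix(
    t: TraitTable, aggregate: Aggregate | str = Aggregate.MEAN_LEVEL
) -> pd.DataFrame:
    """Pearson correlation matrix across traits.

    ``mean_level`` correlates accession means (few observations: with
    only three accessions the estimate is flagged low-n);
    ``replicate_level`` pairs observations by (accession, replicate).
    Zero-variance traits yield NaN entries with a warning rather than a
    silent 0.
    """
    aggregate = Aggregate(aggregate)
    if aggregate is Aggregate.MEAN_LEVEL:
        wide = t.data.pivot_table(index="accession", columns="trait",
                                  values="value", aggfunc="mean")
        if wide.shape[0] < 3:
            raise ValueError("need at least three accessions for correlations")
        if wide.shape[0] == 3:
            warnings.warn("mean-level correlation with only 3 accessions (low n)")
    else:
        wide = t.data.pivot_table(index=["accession", "replicate"],
                                  columns="trait", values="value")
        if wide.dropna().shape[0] < 3:
            raise ValueError("need at least three paired observations per pair")
    sd = wide.std(ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        warnings.warn(f"zero-variance trait(s) {flat}: correlations undefined (NaN)")
    corr = wide.corr(method="pearson")
    for tr in flat:
        corr.loc[tr, :] = np.nan
        corr.loc[:, tr] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr
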
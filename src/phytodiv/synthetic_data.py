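"""Seeded generators for band matrices, alignments, CT and trait tables.

Every generator is a pure function of (profile, seed): the profile
carries the ground truth (band-class compositions and unique-band
allocations per accession, pairwise barcode divergences, per-gene fold
changes, per-trait means and SDs), the seed fixes the realization.  The
packaged default profile encodes a three-accession study: a close pair
of accessions (C1, C2) and a divergent third (C3), 21 dominant-marker
primers plus a protein profile, three target genes and nine traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .band_matrix import BandMatrix, MarkerSystem, matrix_from_composition
from .barcode_phylo import Alignment
from .expression import CtTable
from .phyto_stats import TraitTable

__all__ = [
    "PrimerComposition",
    "StudyProfile",
    "default_profile",
    "load_profile",
    "gen_band_study",
    "gen_alignment",
    "gen_ct_table",
    "gen_trait_table",
]


@dataclass(frozen=True)
class PrimerComposition:
    primer_id: str
    marker_system: MarkerSystem
    MB: int
    UB: int
    NB: int


@dataclass
class StudyProfile:
    """Ground truth for one synthetic characterization study."""

    accessions: list[str]
    primers: list[PrimerComposition] = field(default_factory=list)
    unique_allocation: dict[MarkerSystem, dict[str, int]] = field(default_factory=dict)
    published_pic: dict[str, float] = field(default_factory=dict)
    # barcode
    barcode_length: int = 600
    close_pair: tuple[str, str] = ("C1", "C2")
    divergence_close: float = 0.01
    divergence_far: float = 0.15
    # expression
    reference_gene: str = "Actin"
    calibrator: str = "C1"
    ct_replicates: int = 3
    ct_sigma: float = 0.2
    baseline_ct: float = 20.0
    delta_ct_base: float = 5.0
    folds: dict[str, dict[str, float]] = field(default_factory=dict)
    # traits
    trait_replicates: int = 3
    traits: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.accessions) < 2:
            raise ValueError("profile needs at least two accessions")
        if not 0.0 <= self.divergence_close < 0.75:
            raise ValueError("divergence_close must be in [0, 0.75)")
        if not 0.0 <= self.divergence_far < 0.75:
            raise ValueError("divergence_far must be in [0, 0.75)")
        for gene, per_sample in self.folds.items():
            for sample, fold in per_sample.items():
                if fold <= 0:
                    raise ValueError(f"fold for {gene}/{sample} must be positive")
        for trait, per_acc in self.traits.items():
            for acc, (mean, sd) in per_acc.items():
                if sd < 0:
                    raise ValueError(f"SD for {trait}/{acc} must be non-negative")
        if self.ct_sigma < 0:
            raise ValueError("ct_sigma must be non-negative")

    def primers_of(self, system: MarkerSystem) -> list[PrimerComposition]:
        return [p for p in self.primers if p.marker_system is system]

    @classmethod
    def from_dict(cls, raw: Mapping) -> "StudyProfile":
        primers: list[PrimerComposition] = []
        allocation: dict[MarkerSystem, dict[str, int]] = {}
        for system_name, block in (raw.get("markers") or {}).items():
            system = MarkerSystem(system_name)
            if "unique_allocation" in block:
                allocation[system] = dict(block["unique_allocation"])
            for p in block.get("primers", []):
                primers.append(
                    PrimerComposition(
                        primer_id=str(p["id"]),
                        marker_system=system,
                        MB=int(p["MB"]),
                        UB=int(p["UB"]),
                        NB=int(p["NB"]),
                    )
                )
        bc = raw.get("barcode") or {}
        ex = raw.get("expression") or {}
        tr = raw.get("traits") or {}
        return cls(
            accessions=[str(a) for a in raw["accessions"]],
            primers=primers,
            unique_allocation=allocation,
            published_pic={str(k): float(v)
                           for k, v in (raw.get("published_pic") or {}).items()},
            barcode_length=int(bc.get("length", 600)),
            close_pair=tuple(bc.get("close_pair", ("C1", "C2"))),
            divergence_close=float(bc.get("divergence_close", 0.01)),
            divergence_far=float(bc.get("divergence_far", 0.15)),
            reference_gene=str(ex.get("reference_gene", "Actin")),
            calibrator=str(ex.get("calibrator", "C1")),
            ct_replicates=int(ex.get("n_replicates", 3)),
            ct_sigma=float(ex.get("ct_sigma", 0.2)),
            baseline_ct=float(ex.get("baseline_ct", 20.0)),
            delta_ct_base=float(ex.get("delta_ct_base", 5.0)),
            folds={g: {s: float(f) for s, f in d.items()}
                   for g, d in (ex.get("folds") or {}).items()},
            trait_replicates=int(tr.get("n_replicates", 3)),
            traits={t: {a: (float(ms[0]), float(ms[1])) for a, ms in d.items()}
                    for t, d in (tr.get("values") or {}).items()},
        )


def load_profile(path: str | Path) -> StudyProfile:
    """Load a study profile from a YAML file."""
    with open(path) as fh:
        return StudyProfile.from_dict(yaml.safe_load(fh))


def default_profile() -> StudyProfile:
    """The packaged three-accession default profile."""
    text = resources.files("phytodiv.data").joinpath("default_profile.yaml").read_text()
    return StudyProfile.from_dict(yaml.safe_load(text))


def gen_band_study(
    profile: StudyProfile, seed: int | np.random.Generator = 0
) -> list[BandMatrix]:
    """Generate band matrices realizing the profile's compositions exactly.

    Within each marker system the accessions carrying unique bands are
    drawn to honour the profile's per-accession unique-band quotas (the
    quota total must equal the system's unique-band total); without a
    quota, owners are uniform.  Non-unique polymorphic bands are shared
    by the profile's close pair more often than by either far pair,
    emulating the genetic proximity the profile encodes.
    ``classify_bands`` of every output equals the requested (MB, UB, NB).
    """
    if not profile.primers:
        raise ValueError("profile contains no primer compositions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[BandMatrix] = []
    systems = dict.fromkeys(p.marker_system for p in profile.primers)
    for system in systems:
        primers = profile.primers_of(system)
        total_ub = sum(p.UB for p in primers)
        owners: list[str] | None = None
        if system in profile.unique_allocation:
            quota = profile.unique_allocation[system]
            if sum(quota.values()) != total_ub:
                raise ValueError(
                    f"{system.value}: unique-band quota total "
                    f"{sum(quota.values())} != composition total {total_ub}"
                )
            unknown = set(quota) - set(profile.accessions)
            if unknown:
                raise ValueError(f"quota names unknown accession(s): {sorted(unknown)}")
            pool = [acc for acc, k in quota.items() for _ in range(k)]
            owners = list(np.array(pool, dtype=object)[rng.permutation(total_ub)])
        cursor = 0
        for p in primers:
            owner_slice = None
            if owners is not None:
                owner_slice = owners[cursor : cursor + p.UB]
                cursor += p.UB
            out.append(
                matrix_from_composition(
                    p.MB,
                    p.UB,
                    p.NB,
                    A=len(profile.accessions),
                    seed=rng,
                    primer_id=p.primer_id,
                    marker_system=system,
                    accession_ids=profile.accessions,
                    unique_owners=owner_slice,
                    close_pair=(profile.close_pair
                                if len(profile.accessions) == 3 else None),
                )
            )
    return out


def _mutate(seq: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``prob`` by a different base."""
    out = seq.copy()
    hits = rng.random(seq.size) < prob
    idx = np.flatnonzero(hits)
    bases = np.array(list("ACGT"))
    for i in idx:
        choices = bases[bases != out[i]]
        out[i] = rng.choice(choices)
    return out


def gen_alignment(
    profile: StudyProfile, seed: int | np.random.Generator = 0
) -> Alignment:
    """Simulate a barcode alignment with a close pair and a divergent third.

    Sites mutate i.i.d. along an ultrametric three-taxon tree: the close
    pair diverges by ``divergence_close`` (half per branch), the third
    accession sits at ``divergence_far`` from both.  Realized p-distances
    match the targets to first order in the divergence (parallel and
    back substitutions bias them slightly downward).
    """
    if profile.barcode_length < 50:
        raise ValueError("barcode length must be at least 50")
    if len(profile.accessions) != 3:
        raise ValueError("alignment generator models exactly three accessions")
    d_close, d_far = profile.divergence_close, profile.divergence_far
    if d_far < d_close:
        raise ValueError("divergence_far must be >= divergence_close")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a, b = profile.close_pair
    (c,) = [x for x in profile.accessions if x not in profile.close_pair]
    root = np.array(list("ACGT"))[rng.integers(0, 4, size=profile.barcode_length)]
    stem = (d_far - d_close / 2.0) / 2.0  # per-lineage path to the split
    anc_close = _mutate(root, stem, rng)
    seqs = {
        a: _mutate(anc_close, d_close / 2.0, rng),
        b: _mutate(anc_close, d_close / 2.0, rng),
        c: _mutate(root, stem, rng),
    }
    ordered = [x for x in profile.accessions]
    return Alignment(ids=ordered, seqs=["".join(seqs[x]) for x in ordered])


def gen_ct_table(
    profile: StudyProfile, seed: int | np.random.Generator = 0
) -> CtTable:
    """Simulate replicate CT measurements realizing the profile's folds.

    Reference-gene CTs sit at ``baseline_ct``; target CTs at
    ``baseline_ct + delta_ct_base - log2(fold)``; every well receives
    independent N(0, ct_sigma) noise.  With zero noise the 2^-ddCt
    pipeline returns the truth exactly.
    """
    if not profile.folds:
        raise ValueError("profile defines no expression truth")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for gene, per_sample in profile.folds.items():
        for sample in profile.accessions:
            if sample not in per_sample:
                raise ValueError(f"no truth fold for gene {gene!r}, sample {sample!r}")
    for sample in profile.accessions:
        for rep in range(1, profile.ct_replicates + 1):
            rows.append(
                {
                    "sample": sample,
                    "gene": profile.reference_gene,
                    "replicate": rep,
                    "ct": profile.baseline_ct + profile.ct_sigma * rng.standard_normal(),
                }
            )
        for gene, per_sample in profile.folds.items():
            true_dct = profile.delta_ct_base - np.log2(per_sample[sample])
            for rep in range(1, profile.ct_replicates + 1):
                rows.append(
                    {
                        "sample": sample,
                        "gene": gene,
                        "replicate": rep,
                        "ct": profile.baseline_ct
                        + true_dct
                        + profile.ct_sigma * rng.standard_normal(),
                    }
                )
    return CtTable(
        data=pd.DataFrame(rows),
        reference_gene=profile.reference_gene,
        calibrator=profile.calibrator,
    )


def gen_trait_table(
    profile: StudyProfile, seed: int | np.random.Generator = 0
) -> TraitTable:
    """Simulate replicate trait measurements (normal noise around truth)."""
    if not profile.traits:
        raise ValueError("profile defines no trait truth")
    if profile.trait_replicates < 2:
        raise ValueError("traits need at least two replicates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for trait, per_acc in profile.traits.items():
        for acc in profile.accessions:
            if acc not in per_acc:
                raise ValueError(f"no truth for trait {trait!r}, accession {acc!r}")
            mean, sd = per_acc[acc]
            for rep in range(1, profile.trait_replicates + 1):
                rows.append(
                    {
                        "accession": acc,
                        "trait": trait,
                        "replicate": rep,
                        "value": mean + sd * rng.standard_normal(),
                    }
                )
    return TraitTable(data=pd.DataFrame(rows))
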
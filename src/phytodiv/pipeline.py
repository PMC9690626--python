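"""Whole-study orchestration: markers -> clustering, barcode, expression, traits.

``run_all`` drives every stage present in a :class:`RunConfig`, writes
full-precision CSV/Newick outputs plus a human-readable marker report,
and records a manifest with a SHA-256 hash per output so reruns can be
verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import band_matrix, barcode_phylo, clustering, expression, marker_stats, phyto_stats

log = logging.getLogger("phytodiv")

__all__ = ["RunConfig", "run_all", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed validation; the message names the stage."""


@dataclass
class RunConfig:
    """Inputs and options of a full characterization run."""

    out_dir: Path
    bands_dir: Path | None = None
    alignment_fasta: Path | None = None
    ct_csv: Path | None = None
    trait_csv: Path | None = None
    reference_gene: str = "Actin"
    calibrator: str = "C1"
    metric: str = "jaccard"
    rp_convention: str = "doubled_frequency"
    pic_overrides: Mapping[str, float] = field(default_factory=dict)
    alpha: float = 0.05
    bootstrap_reps: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not raw:
            raise PipelineError(f"config {path} is empty")
        base = path.parent

        def respath(key: str) -> Path | None:
            if key not in raw or raw[key] is None:
                return None
            p = Path(raw[key])
            return p if p.is_absolute() else base / p

        cfg = cls(
            out_dir=respath("out_dir") or base / "out",
            bands_dir=respath("bands_dir"),
            alignment_fasta=respath("alignment_fasta"),
            ct_csv=respath("ct_csv"),
            trait_csv=respath("trait_csv"),
            reference_gene=str(raw.get("reference_gene", "Actin")),
            calibrator=str(raw.get("calibrator", "C1")),
            metric=str(raw.get("metric", "jaccard")),
            rp_convention=str(raw.get("rp_convention", "doubled_frequency")),
            pic_overrides=dict(raw.get("pic_overrides") or {}),
            alpha=float(raw.get("alpha", 0.05)),
            bootstrap_reps=int(raw.get("bootstrap_reps", 200)),
            seed=int(raw.get("seed", 0)),
        )
        for name in ("bands_dir", "alignment_fasta", "ct_csv", "trait_csv"):
            p = getattr(cfg, name)
            if p is not None and not p.exists():
                raise PipelineError(f"config: {name} path {p} does not exist")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every configured stage; return the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                if exc is not None:
                    log.error("stage %s: failed after %.2fs: %s", name, dt, exc)
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                log.info("stage %s: done in %.2fs", name, dt)

        return _Timer()

    if config.bands_dir is not None:
        with stage("markers"):
            files = sorted(Path(config.bands_dir).glob("*.csv"))
            if not files:
                raise ValueError(f"no band CSVs in {config.bands_dir}")
            matrices = [band_matrix.read_band_csv(f) for f in files]
            summary = marker_stats.summarize(
                matrices,
                pic_overrides=config.pic_overrides,
                rp_convention=config.rp_convention,
            )
            mdir = out / "markers"
            mdir.mkdir(exist_ok=True)
            summary.to_frame().to_csv(mdir / "primer_stats.csv")
            summary.to_frame(rounded=True).to_csv(mdir / "primer_stats_report.csv")
            dist = clustering.similarity(matrices, metric=config.metric)
            dist.to_frame().to_csv(mdir / "distances.csv")
            tree = clustering.upgma(dist)
            (mdir / "upgma.nwk").write_text(clustering.to_newick(tree) + "\n")
            outputs += [
                mdir / "primer_stats.csv",
                mdir / "primer_stats_report.csv",
                mdir / "distances.csv",
                mdir / "upgma.nwk",
            ]

    if config.alignment_fasta is not None:
        with stage("barcode"):
            al = barcode_phylo.Alignment.from_fasta(config.alignment_fasta)
            bdir = out / "barcode"
            bdir.mkdir(exist_ok=True)
            rows = [
                {
                    "id": i,
                    "length_bp": len(s.replace("-", "")),
                    "gc_pct": barcode_phylo.gc_content(s.replace("-", "")),
                }
                for i, s in zip(al.ids, al.seqs)
            ]
            pd.DataFrame(rows).to_csv(bdir / "stats.csv", index=False)
            dist = barcode_phylo.p_distance(al)
            dist.to_frame().to_csv(bdir / "p_distances.csv")
            tree = barcode_phylo.bootstrap_tree(
                al, n_reps=config.bootstrap_reps, seed=config.seed
            )
            (bdir / "tree.nwk").write_text(clustering.to_newick(tree) + "\n")
            outputs += [bdir / "stats.csv", bdir / "p_distances.csv", bdir / "tree.nwk"]

    if config.ct_csv is not None:
        with stage("expression"):
            table = expression.read_ct_csv(
                config.ct_csv,
                reference_gene=config.reference_gene,
                calibrator=config.calibrator,
            )
            edir = out / "expression"
            edir.mkdir(exist_ok=True)
            folds = expression.fold_changes(table)
            expression.fold_change_frame(folds).to_csv(
                edir / "fold_changes.csv", index=False
            )
            outputs.append(edir / "fold_changes.csv")

    if config.trait_csv is not None:
        with stage("traits"):
            table = phyto_stats.read_trait_csv(config.trait_csv)
            tdir = out / "traits"
            tdir.mkdir(exist_ok=True)
            rows = []
            for trait in table.traits:
                groups = table.groups(trait)
                res = phyto_stats.anova_oneway(groups)
                letters = phyto_stats.duncan(groups, alpha=config.alpha)
                for acc in groups:
                    rows.append(
                        {
                            "trait": trait,
                            "accession": acc,
                            "mean": letters.means[acc],
                            "letters": letters.letters[acc],
                            "F": res.F,
                            "p": res.p,
                        }
                    )
            pd.DataFrame(rows).to_csv(tdir / "anova_duncan.csv", index=False)
            phyto_stats.pearson_matrix(table).to_csv(tdir / "pearson.csv")
            outputs += [tdir / "anova_duncan.csv", tdir / "pearson.csv"]

    if not outputs:
        raise PipelineError("config enables no stage (no inputs given)")

    manifest = {
        "seed": config.seed,
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in outputs
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
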
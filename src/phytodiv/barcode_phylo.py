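"""DNA-barcode descriptive statistics, distances and bootstrap trees.

Covers the desk side of a barcoding workflow: per-sequence length and
GC%, pairwise percent identity from a semi-global alignment, p-distance
matrices from a multiple alignment, and UPGMA trees with bootstrap
support obtained by resampling alignment columns.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .clustering import DistanceMatrix, UPGMATree, upgma

__all__ = [
    "Alignment",
    "read_fasta",
    "write_fasta",
    "gc_content",
    "pairwise_identity",
    "p_distance",
    "bootstrap_tree",
    "GapPolicy",
]

_IUPAC = set("ACGTRYSWKMBDHVN")
_BASES = set("ACGT")


def _seq_str(s: str | Seq | SeqRecord) -> str:
    if isinstance(s, SeqRecord):
        s = s.seq
    text = str(s).upper().replace("U", "T")
    if not text:
        raise ValueError("empty sequence")
    bad = set(text) - _IUPAC - {"-"}
    if bad:
        raise ValueError(f"non-IUPAC symbol(s) in sequence: {sorted(bad)}")
    return text


@dataclass
class Alignment:
    """Multiple sequence alignment: equal-length gapped DNA sequences."""

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs lengths differ")
        if len(self.seqs) < 2:
            raise ValueError("alignment needs at least two sequences")
        self.seqs = [_seq_str(s) for s in self.seqs]
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences have unequal lengths: {lengths}")
        cols = np.array([list(s) for s in self.seqs])
        if (cols == "-").all(axis=0).all() or cols.shape[1] == 0:
            raise ValueError("alignment must contain a non-gap column")

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def matrix(self) -> np.ndarray:
        return np.array([list(s) for s in self.seqs])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls(ids=[r.id for r in records], seqs=[str(r.seq) for r in records])

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(s), id=i, description="") for i, s in zip(self.ids, self.seqs)
        ]
        SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read plain (unaligned) FASTA records."""
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records: list[SeqRecord], path: str | Path) -> None:
    SeqIO.write(records, str(path), "fasta")


class Ambiguity(str, enum.Enum):
    EXCLUDE = "exclude"
    COUNT_S = "count_S"


def gc_content(
    s: str | Seq | SeqRecord, ambiguity: Ambiguity | str = Ambiguity.EXCLUDE
) -> float:
    """GC percentage of a sequence.

    ``exclude`` counts only unambiguous A/C/G/T in the denominator;
    ``count_S`` additionally treats the ambiguity code S (G or C) as GC.
    Gap characters are never counted.
    """
    ambiguity = Ambiguity(ambiguity)
    text = _seq_str(s)
    gc = text.count("G") + text.count("C")
    denom = sum(text.count(b) for b in "ACGT")
    if ambiguity is Ambiguity.COUNT_S:
        gc += text.count("S")
        denom += text.count("S")
    if denom == 0:
        raise ValueError("no countable bases for GC content")
    return 100.0 * gc / denom


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.internal_gap_score = -2
    # free terminal gaps (semi-global)
    aligner.end_gap_score = 0
    return aligner


def _identity_of(aligned_a: str, aligned_b: str) -> float:
    n = len(aligned_a)
    # strip columns where either sequence has a terminal gap
    start, end = 0, n
    for s in (aligned_a, aligned_b):
        lead = len(s) - len(s.lstrip("-"))
        trail = len(s) - len(s.rstrip("-"))
        start = max(start, lead)
        end = min(end, n - trail)
    cols = range(start, end)
    matches = sum(1 for i in cols if aligned_a[i] == aligned_b[i] != "-")
    total = end - start
    if total == 0:
        raise ValueError("no aligned columns after trimming terminal gaps")
    return 100.0 * matches / total


def pairwise_identity(
    a: str | Seq | SeqRecord, b: str | Seq | SeqRecord, max_alignments: int = 64
) -> float:
    """Percent identity of two sequences from a semi-global alignment.

    Alignment scoring: match +1, mismatch -1, gap -2, terminal gaps free.
    Identity = 100 x matches / aligned columns, excluding columns inside
    terminal gaps.  When several alignments are co-optimal, the highest
    identity among the first ``max_alignments`` of them is reported
    (deterministic tie-break favouring matched residues over terminal
    overhangs).  Identical sequences give exactly 100.
    """
    sa, sb = _seq_str(a), _seq_str(b)
    if sa == sb:
        return 100.0
    alignments = _make_aligner().align(sa, sb)
    best = 0.0
    for i, aln in enumerate(alignments):
        if i >= max_alignments:
            break
        text_a, text_b = aln[0], aln[1]
        best = max(best, _identity_of(text_a, text_b))
    return best


class GapPolicy(str, enum.Enum):
    PAIRWISE_DELETION = "pairwise_deletion"
    COMPLETE_DELETION = "complete_deletion"


def p_distance(
    al: Alignment, gap_policy: GapPolicy | str = GapPolicy.PAIRWISE_DELETION
) -> DistanceMatrix:
    """Proportion of differing sites between every pair of sequences.

    Only unambiguous A/C/G/T positions are compared.  Under
    ``pairwise_deletion`` each pair ignores its own unusable sites; under
    ``complete_deletion`` any column unusable in any sequence is removed
    for all pairs.  A pair with no comparable site raises.
    """
    gap_policy = GapPolicy(gap_policy)
    mat = al.matrix()
    usable = np.isin(mat, sorted(_BASES))
    if gap_policy is GapPolicy.COMPLETE_DELETION:
        keep = usable.all(axis=0)
        mat = mat[:, keep]
        usable = usable[:, keep]
    n = len(al.ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = usable[i] & usable[j]
            sites = int(ok.sum())
            if sites == 0:
                raise ValueError(
                    f"no comparable sites for pair ({al.ids[i]!r}, {al.ids[j]!r})"
                )
            diff = int((mat[i, ok] != mat[j, ok]).sum())
            values[i, j] = values[j, i] = diff / sites
    return DistanceMatrix(labels=list(al.ids), values=values)


def bootstrap_tree(
    al: Alignment,
    n_reps: int = 2000,
    seed: int | np.random.Generator = 0,
    gap_policy: GapPolicy | str = GapPolicy.PAIRWISE_DELETION,
) -> UPGMATree:
    """UPGMA tree from p-distances with column-resampling bootstrap support.

    Each replicate resamples alignment columns with replacement, rebuilds
    the p-distance matrix and UPGMA tree, and scores, for every internal
    node of the reference tree, the percentage of replicates containing
    the same leaf bipartition.  Fully reproducible for a given seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if len(al.ids) < 3:
        raise ValueError("bootstrap tree needs at least three sequences")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mat = al.matrix()
    if all((mat[:, j] == mat[0, j]).all() for j in range(mat.shape[1])):
        warnings.warn(
            "alignment columns are all identical; bootstrap support carries "
            "no information"
        )

    ref = upgma(p_distance(al, gap_policy))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in ref.bipartitions()}
    length = al.length
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        sampled = Alignment(
            ids=list(al.ids), seqs=["".join(row[cols]) for row in mat]
        )
        try:
            rep_tree = upgma(p_distance(sampled, gap_policy))
        except ValueError:  # replicate with an incomparable pair
            continue
        rep_parts = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_parts:
                counts[bp] += 1

    full = frozenset(ref.leaf_labels())
    for node in ref.internal_nodes():
        side = frozenset(node.leaf_labels())
        if 1 < len(side) < len(full):
            key = min(side, full - side, key=sorted)
            node.support = 100.0 * counts[key] / n_reps
    return ref
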
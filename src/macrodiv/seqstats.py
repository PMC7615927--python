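"""Per-species alignment statistics for barcode (COI) data.

Computes the three summary statistics used throughout the pipeline:

* nucleotide diversity ``pi`` — the per-site average number of differences
  between a pair of sequences (sum of pairwise differences divided by the
  number of pairs, then by the number of sites compared);
* ``S`` — number of segregating sites;
* ``PIS`` — number of parsimony-informative sites.

Gaps and IUPAC ambiguity codes are treated as missing data.  Under the
default ``complete`` deletion mode every column containing a non-ACGT
character is removed before *all* statistics are computed; under
``pairwise`` mode each sequence pair is compared over the sites where both
members are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AlignedSeqSet",
    "DiversityEstimate",
    "read_alignment",
    "nucleotide_diversity",
    "segregating_sites",
    "parsimony_informative_sites",
    "diversity_estimate",
    "diversity_table",
]

_BASES = "ACGT"
# integer codes: A=0 C=1 G=2 T=3, anything else (gap, N, IUPAC ambiguity) = -1
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("U")] = _CODE[ord("u")] = 3  # RNA-style input


@dataclass(frozen=True)
class AlignedSeqSet:
    """One species' equal-length sequence matrix.

    ``matrix`` holds integer-coded bases (A=0..T=3, missing=-1) with one row
    per sequence.
    """

    species_id: str
    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int8)
        if m.ndim != 2 or m.shape[1] == 0:
            raise ValueError("alignment matrix must be 2-D with L > 0")
        if len(self.ids) != m.shape[0]:
            raise ValueError("ids/matrix row mismatch")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_strings(
        cls, sequences: Iterable[str], species_id: str = "", ids: Iterable[str] | None = None
    ) -> "AlignedSeqSet":
        seqs = list(sequences)
        if not seqs:
            raise ValueError("empty sequence set")
        L = len(seqs[0])
        for i, s in enumerate(seqs):
            if len(s) != L:
                raise ValueError(
                    f"sequence {i} has length {len(s)}, expected {L}: alignment not rectangular"
                )
        if ids is None:
            ids = tuple(f"seq{i+1}" for i in range(len(seqs)))
        mat = _CODE[np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)]
        return cls(species_id, tuple(ids), mat.reshape(len(seqs), L))


@dataclass(frozen=True)
class DiversityEstimate:
    """Summary statistics for one species' alignment."""

    species_id: str
    pi: float
    S: int
    PIS: int
    n: int
    L: int  # sites retained under the deletion rule (complete mode)


def read_alignment(path: str | Path, species_id: str | None = None) -> AlignedSeqSet:
    """Read one species' aligned FASTA file.

    Sequences are uppercased on coding; record order is preserved.  Records
    of unequal length raise ``ValueError`` naming the offending record.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    L = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != L:
            raise ValueError(
                f"{path}: record '{rec.id}' has length {len(rec.seq)}, "
                f"expected {L} (alignment must be rectangular)"
            )
    return AlignedSeqSet.from_strings(
        (str(rec.seq) for rec in records),
        species_id=species_id if species_id is not None else path.stem,
        ids=tuple(rec.id for rec in records),
    )


def _complete_columns(mat: np.ndarray) -> np.ndarray:
    """Columns with no gap/ambiguity in any sequence."""
    return mat[:, (mat >= 0).all(axis=0)]


def nucleotide_diversity(
    aln: AlignedSeqSet, deletion_mode: Literal["complete", "pairwise"] = "complete"
) -> float:
    """Average per-site pairwise difference among the sequences.

    ``complete``: columns containing any missing state are dropped, then
    pi = [sum over pairs of differing sites] / C(n,2) / L_used.
    ``pairwise``: each pair is compared over its own unambiguous sites and
    pi is the mean of the per-pair per-site distances.
    """
    mat = aln.matrix
    n = mat.shape[0]
    if n < 2:
        raise ValueError("nucleotide diversity requires at least 2 sequences")
    if deletion_mode == "complete":
        m = _complete_columns(mat)
        L = m.shape[1]
        if L == 0:
            raise ValueError("no comparable sites after complete deletion")
        # column-wise identity counting: diffs per column = C(n,2) - sum_b C(count_b,2)
        total_pairs = n * (n - 1) // 2
        diff = 0.0
        for b in range(4):
            cnt = (m == b).sum(axis=0)
            diff -= (cnt * (cnt - 1) // 2).sum()
        diff += total_pairs * L
        return float(diff / total_pairs / L)
    if deletion_mode == "pairwise":
        dists = []
        for i in range(n):
            for j in range(i + 1, n):
                ok = (mat[i] >= 0) & (mat[j] >= 0)
                L_ij = int(ok.sum())
                if L_ij == 0:
                    raise ValueError(f"no comparable sites between rows {i} and {j}")
                dists.append((mat[i, ok] != mat[j, ok]).sum() / L_ij)
        return float(np.mean(dists))
    raise ValueError(f"unknown deletion_mode {deletion_mode!r}")


def segregating_sites(
    aln: AlignedSeqSet, deletion_mode: Literal["complete", "pairwise"] = "complete"
) -> int:
    """Number of columns with two or more distinct unambiguous bases."""
    mat = aln.matrix
    if mat.shape[0] < 2:
        raise ValueError("requires at least 2 sequences")
    if deletion_mode == "complete":
        mat = _complete_columns(mat)
    present = np.stack([(mat == b).any(axis=0) for b in range(4)])
    return int((present.sum(axis=0) >= 2).sum())


def parsimony_informative_sites(
    aln: AlignedSeqSet, deletion_mode: Literal["complete", "pairwise"] = "complete"
) -> int:
    """Columns with >=2 base states each carried by >=2 sequences."""
    mat = aln.matrix
    if mat.shape[0] < 2:
        raise ValueError("requires at least 2 sequences")
    if deletion_mode == "complete":
        mat = _complete_columns(mat)
    counts = np.stack([(mat == b).sum(axis=0) for b in range(4)])
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


def diversity_estimate(
    aln: AlignedSeqSet, deletion_mode: Literal["complete", "pairwise"] = "complete"
) -> DiversityEstimate:
    """Bundle pi, S, PIS, n and the effective length for one alignment."""
    L_used = _complete_columns(aln.matrix).shape[1] if deletion_mode == "complete" else aln.length
    return DiversityEstimate(
        species_id=aln.species_id,
        pi=nucleotide_diversity(aln, deletion_mode),
        S=segregating_sites(aln, deletion_mode),
        PIS=parsimony_informative_sites(aln, deletion_mode),
        n=aln.n,
        L=L_used,
    )


def diversity_table(
    alignments: Iterable[AlignedSeqSet],
    deletion_mode: Literal["complete", "pairwise"] = "complete",
) -> pd.DataFrame:
    """Per-species statistics as a DataFrame (species_id, n, L, pi, S, PIS)."""
    rows = []
    for aln in alignments:
        est = diversity_estimate(aln, deletion_mode)
        rows.append(
            {
                "species_id": est.species_id,
                "n": est.n,
                "L": est.L,
                "pi": est.pi,
                "S": est.S,
                "PIS": est.PIS,
            }
        )
    return pd.DataFrame(rows)
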
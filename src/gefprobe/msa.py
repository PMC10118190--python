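"""Percent-identity matrices, diagonal square clustering, and alignment helpers.

The clustering rule mirrors how GEF subfamilies are read off an identity
heatmap: scanning the sequence order of the alignment, find the largest
possible square neighborhoods along the matrix diagonal whose identity
satisfies a threshold (35% by default). Two criteria are offered — the mean
of the off-diagonal entries of the square (default) or the minimum pairwise
identity (strict).

Global pairwise alignment (Needleman-Wunsch with affine gaps, BLOSUM62,
gap open 10 / extend 0.5, EMBOSS-needle-like defaults) backs cross-species
identity estimates and the automatic residue mapping used by the steric
compatibility analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align, AlignIO, SeqIO
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX-")


@dataclass
class Msa:
    """A multiple sequence alignment: labels plus equal-length aligned rows."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows length mismatch")
        if self.rows:
            L = len(self.rows[0])
            for name, row in zip(self.names, self.rows):
                if len(row) != L:
                    raise ValueError(f"row {name!r} has length {len(row)} != {L}")
                bad = set(row.upper()) - AA_ALPHABET
                if bad:
                    raise ValueError(f"row {name!r} has invalid characters {bad}")
                if "X" in row.upper():
                    logger.info("sequence %r contains X (unknown residue)", name)
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def read_msa(path: str | Path, fmt: str | None = None) -> Msa:
    """Read an MSA from FASTA or Clustal; the format is sniffed if not given."""
    path = Path(path)
    if fmt is None:
        head = path.read_text().lstrip()[:30].upper()
        fmt = "clustal" if head.startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return Msa(names=[r.id for r in aln], rows=[str(r.seq) for r in aln])


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read unaligned FASTA sequences as {label: sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


@dataclass
class IdentityMatrix:
    """Symmetric pairwise percent-identity matrix over an MSA."""

    labels: list[str]
    values: np.ndarray  # percent, 0-100, diagonal 100
    mode: str = "both_ungapped"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("identity matrix must be symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class ClusterSet:
    """Maximal diagonal square clusters at an identity threshold.

    ``clusters`` holds inclusive index intervals [i, j] in MSA order,
    non-overlapping and left-to-right.
    """

    threshold: float
    criterion: str
    clusters: list[tuple[int, int]]

    def labels(self, im: IdentityMatrix) -> list[list[str]]:
        return [im.labels[i:j + 1] for i, j in self.clusters]


@dataclass
class DivergenceReport:
    """Where a query sequence deviates from conserved alignment columns.

    ``positions`` are the audited columns (0-based). Columns whose majority
    residue does not reach the conservation quorum are listed in
    ``not_conserved`` and excluded from the mismatch count.
    """

    query_label: str
    positions: list[int]
    flagged_positions: list[int]
    not_conserved: list[int]

    @property
    def n_divergent(self) -> int:
        return len(self.flagged_positions)


def pairwise_identity_matrix(m: Msa, mode: str = "both_ungapped") -> IdentityMatrix:
    """Percent identity for every sequence pair of an alignment.

    identity(i, j) = 100 * matches / denominator, where matches counts
    columns with identical non-gap residues, and the denominator is either
    the number of columns where both sequences are ungapped
    (``both_ungapped``) or the full alignment length (``alignment_length``).
    """
    if m.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    if mode not in ("both_ungapped", "alignment_length"):
        raise ValueError(f"unknown mode {mode!r}")
    arr = np.array([list(r) for r in m.rows])
    gap = arr == "-"
    n = m.n_sequences
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            matches = int(np.sum((arr[i] == arr[j]) & both))
            denom = int(both.sum()) if mode == "both_ungapped" else m.length
            ident = 100.0 * matches / denom if denom else 0.0
            vals[i, j] = vals[j, i] = ident
    return IdentityMatrix(labels=list(m.names), values=vals, mode=mode)


def _square_ok(values: np.ndarray, i: int, j: int, threshold: float,
               criterion: str) -> bool:
    """Does the diagonal square [i..j] satisfy the identity criterion?"""
    if i == j:
        return True
    block = values[i:j + 1, i:j + 1]
    off = block[~np.eye(block.shape[0], dtype=bool)]
    if criterion == "mean_offdiag":
        return float(off.mean()) >= threshold
    if criterion == "min_pairwise":
        return float(off.min()) >= threshold
    raise ValueError(f"unknown criterion {criterion!r}")


def diagonal_square_clusters(
    im: IdentityMatrix, threshold: float = 35.0, criterion: str = "mean_offdiag"
) -> ClusterSet:
    """Largest-possible diagonal square neighborhoods meeting the threshold.

    Greedy left-to-right scan: from each uncovered start index i, take the
    largest j such that the square [i..j] satisfies the criterion, emit
    [i, j], continue at j + 1. Singletons always satisfy (a sequence is 100%
    identical to itself).
    """
    n = len(im.labels)
    clusters: list[tuple[int, int]] = []
    i = 0
    while i < n:
        best = i
        for j in range(i + 1, n):
            if _square_ok(im.values, i, j, threshold, criterion):
                best = j
        clusters.append((i, best))
        i = best + 1
    return ClusterSet(threshold=threshold, criterion=criterion, clusters=clusters)


def average_identity(im: IdentityMatrix) -> pd.Series:
    """Mean off-diagonal identity per label, MSA order preserved.

    The minimum of this series identifies the family outlier (the sequence
    least like all others).
    """
    n = len(im.labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    off = im.values.copy()
    np.fill_diagonal(off, np.nan)
    means = np.nanmean(off, axis=1)
    return pd.Series(means, index=im.labels, name="average_identity")


def key_residue_divergence(
    m: Msa,
    positions: list[int],
    query_label: str,
    conservation_quorum: float = 0.8,
) -> DivergenceReport:
    """Count audited columns where the query deviates from a conserved majority.

    For each audited column, the majority residue among all non-query
    sequences (ignoring gaps) is computed; if its frequency reaches the
    quorum the column counts as conserved, and the query is flagged when its
    residue differs from that majority. Columns below quorum are reported as
    not conserved and excluded.
    """
    if query_label not in m.names:
        raise ValueError(f"query {query_label!r} not in alignment")
    qi = m.names.index(query_label)
    L = m.length
    flagged: list[int] = []
    not_conserved: list[int] = []
    for pos in positions:
        if not (0 <= pos < L):
            raise IndexError(f"column {pos} out of range (alignment length {L})")
        col = [row[pos] for k, row in enumerate(m.rows) if k != qi]
        residues = [c for c in col if c != "-"]
        if not residues:
            not_conserved.append(pos)
            continue
        uniq, counts = np.unique(residues, return_counts=True)
        top = int(np.argmax(counts))
        if counts[top] / len(residues) < conservation_quorum:
            not_conserved.append(pos)
            continue
        if m.rows[qi][pos] != uniq[top]:
            flagged.append(pos)
    return DivergenceReport(
        query_label=query_label,
        positions=list(positions),
        flagged_positions=flagged,
        not_conserved=not_conserved,
    )


@dataclass(frozen=True)
class GlobalAlignment:
    """A global pairwise alignment with its score and percent identity."""

    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float  # over columns where both are non-gap


def global_align(
    a: str,
    b: str,
    substitution: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> GlobalAlignment:
    """Needleman-Wunsch global alignment with affine gap penalties.

    A gap of length L costs gap_open + gap_extend * (L - 1). Identity is
    100 * identical aligned pairs / columns where both sequences are
    non-gap. The highest-scoring alignment is returned deterministically.
    """
    a = a.strip().upper()
    b = b.strip().upper()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    alns = aligner.align(a, b)
    best = alns[0]
    sa, sb = str(best[0]), str(best[1])
    both = [(x, y) for x, y in zip(sa, sb) if x != "-" and y != "-"]
    matches = sum(1 for x, y in both if x == y)
    ident = 100.0 * matches / len(both) if both else 0.0
    return GlobalAlignment(
        aligned_a=sa, aligned_b=sb, score=float(best.score), percent_identity=ident
    )
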
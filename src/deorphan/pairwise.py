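"""Pairwise alignment, identity, and corrected distance matrices.

Global alignment is Needleman–Wunsch with affine gaps via Biopython's
:class:`Bio.Align.PairwiseAligner` under a bundled substitution matrix
(default BLOSUM62, gap open 11 / extend 1 — the community default for
protein search). Distances over a fixed multiple alignment use pairwise
deletion of gap columns and an optional multiple-hit correction:

* ``none``     — raw p-distance
* ``poisson``  — d = -ln(1 - p)
* ``kimura``   — d = -ln(1 - p - 0.2 p^2)

p values whose correction diverges are clamped to a documented ceiling
(default 10 substitutions/site) with a warning. Columns containing the
unknown residue ``X`` are scored as mismatches.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

GAP = "-"
_X = "X"

#: Ceiling (substitutions/site) applied when a correction diverges.
DEFAULT_DISTANCE_CLAMP = 10.0

CORRECTIONS = ("none", "poisson", "kimura")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A scored global alignment of two sequences."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    identity: float


def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    try:
        matrix = substitution_matrices.load(matrix_name)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {matrix_name!r}") from exc
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    # A gap of length L costs open + (L - 1) * extend.
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    *,
    id_a: str = "a",
    id_b: str = "b",
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences.

    The traceback is deterministic: among co-optimal alignments the
    aligner's first is taken. Identity is matches over columns where
    both rows carry a residue (``X`` never matches).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(matrix_name, gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    shared = matches = 0
    for x, y in zip(row_a, row_b):
        if x == GAP or y == GAP:
            continue
        shared += 1
        if x == y and x != _X:
            matches += 1
    identity = matches / shared if shared else 0.0
    return PairwiseAlignment(
        id_a=id_a, id_b=id_b, aligned_a=row_a, aligned_b=row_b,
        score=float(alignment.score), identity=identity,
    )


def p_distance_pair(row_a: str, row_b: str) -> float:
    """p-distance between two equal-length gapped rows (pairwise deletion).

    Mismatches over columns where both rows carry a residue; a column
    with ``X`` in either row counts as a mismatch. If the rows share no
    residue columns the distance is 1.0 (with a warning).
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    shared = mism = 0
    for x, y in zip(row_a, row_b):
        if x == GAP or y == GAP:
            continue
        shared += 1
        if x != y or x == _X:
            mism += 1
    if shared == 0:
        warnings.warn("no shared residue columns; p-distance set to 1.0")
        return 1.0
    return mism / shared


def correct_p(p, correction: str, clamp: float = DEFAULT_DISTANCE_CLAMP):
    """Apply a multiple-hit correction to p-distance(s).

    Works elementwise on scalars or arrays; divergent values are clamped
    to ``clamp`` with a warning.
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}; choose from {CORRECTIONS}")
    p_arr = np.asarray(p, dtype=float)
    if correction == "none":
        out = p_arr.copy()
    else:
        if correction == "poisson":
            arg = 1.0 - p_arr
        else:  # kimura
            arg = 1.0 - p_arr - 0.2 * p_arr ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            out = -np.log(arg)
        bad = arg <= 0.0
        if np.any(bad):
            warnings.warn(
                f"{int(np.count_nonzero(bad))} p-distance(s) not correctable under "
                f"{correction}; clamped to {clamp}"
            )
            out = np.where(bad, clamp, out)
        out = np.minimum(out, clamp)
    return float(out) if np.isscalar(p) or out.ndim == 0 else out


@dataclass
class AlignmentMatrix:
    """A multiple sequence alignment: equal-length gapped rows over record ids."""

    ids: list
    rows: list

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.rows = list(self.rows)
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have the same length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in alignment")
        if self.rows:
            length = len(self.rows[0])
            for rid, row in zip(self.ids, self.rows):
                if len(row) != length:
                    raise ValueError(f"row {rid} has length {len(row)} != {length}")
        self._encoded: Optional[np.ndarray] = None

    @classmethod
    def from_records(cls, records) -> "AlignmentMatrix":
        """Identity alignment of equal-length, ungapped records."""
        ids = [r.id for r in records]
        rows = [r.sequence for r in records]
        return cls(ids, rows)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def encoded(self) -> np.ndarray:
        """Rows as a (n, length) uint8 array of character codes (cached)."""
        if self._encoded is None:
            self._encoded = np.frombuffer(
                "".join(self.rows).encode("ascii"), dtype=np.uint8
            ).reshape(self.n_rows, self.length)
        return self._encoded

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]

    def take_columns(self, columns) -> "AlignmentMatrix":
        """New alignment from a column index array (bootstrap resampling)."""
        sub = self.encoded[:, np.asarray(columns, dtype=int)]
        rows = [bytes(r).decode("ascii") for r in sub]
        return AlignmentMatrix(list(self.ids), rows)

    def subset(self, ids) -> "AlignmentMatrix":
        keep = [self.ids.index(i) for i in ids]
        return AlignmentMatrix([self.ids[i] for i in keep], [self.rows[i] for i in keep])


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances over an ordered id list."""

    ids: list
    d: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance array must be {n}x{n}, got {self.d.shape}")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix has non-finite entries")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")
        self.d = (self.d + self.d.T) / 2.0
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])


def msa_distances(
    msa: AlignmentMatrix,
    correction: str = "poisson",
    columns=None,
    clamp: float = DEFAULT_DISTANCE_CLAMP,
) -> DistanceMatrix:
    """Corrected pairwise distances from a multiple alignment.

    Gap handling is pairwise deletion: each pair's p-distance is taken
    over the columns where both rows carry a residue. ``columns`` may
    give a column index array (used by the bootstrap to resample sites
    without rebuilding row strings). Pairs sharing no residue columns
    get p = 1 with a warning.
    """
    if msa.n_rows < 2:
        raise ValueError("need at least two rows to compute distances")
    arr = msa.encoded
    if columns is not None:
        arr = arr[:, np.asarray(columns, dtype=int)]
    gap = ord(GAP)
    xcode = ord(_X)
    valid = arr != gap
    both = valid[:, None, :] & valid[None, :, :]
    diff = (arr[:, None, :] != arr[None, :, :])
    is_x = arr == xcode
    diff |= is_x[:, None, :] | is_x[None, :, :]
    mism = (diff & both).sum(axis=2)
    shared = both.sum(axis=2)
    if np.any((shared == 0) & ~np.eye(msa.n_rows, dtype=bool)):
        warnings.warn("some row pairs share no residue columns; p set to 1.0")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(shared > 0, mism / np.maximum(shared, 1), 1.0)
    np.fill_diagonal(p, 0.0)
    d = correct_p(p, correction, clamp=clamp)
    d = np.asarray(d, dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(msa.ids), d)
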
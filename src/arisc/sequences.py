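"""Pairwise sequence comparison and the A-RISC cross-reactivity index.

The A-RISC index (Allergens'-Relative Identity, Similarity and
Cross-reactivity index) of a pair of homologous allergens is the arithmetic
mean of their pairwise sequence identity and similarity, both expressed as
fractions in [0, 1].  The index is binned into four cross-reactivity risk
categories:

    high         arisc >= 0.75
    medium-high  0.50 <= arisc < 0.75
    medium-low   0.25 <= arisc < 0.50
    low          arisc < 0.25

Identity and similarity depend on three conventions that published
percent-identity servers leave implicit, all of which are explicit (and
recorded in every result) here:

* the alignment: an optimal global (Needleman-Wunsch) alignment with affine
  gap costs under a substitution matrix (default BLOSUM62, gap open 10,
  gap extend 0.5), or a pair of rows extracted from a precomputed MSA;
* the denominator: length of the shorter sequence (default), mean sequence
  length, or full alignment length;
* "similar": same amino-acid class under a fixed partition of the alphabet
  (default ``GAVLI / FYW / CM / ST / KRH / DENQ / P``) or, alternatively, a
  positive substitution-matrix score.  Identical residues are always
  similar.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: Default amino-acid classes used for "similar" calls.  The seven classes
#: partition the full 20-letter alphabet: small/aliphatic, aromatic,
#: sulfur-containing, hydroxyl, basic, acidic/amide, and proline alone.
DEFAULT_SIMILARITY_GROUPS: tuple[str, ...] = (
    "GAVLI", "FYW", "CM", "ST", "KRH", "DENQ", "P",
)

DENOMINATOR_MODES = ("shorter-sequence", "mean-length", "alignment-length")
SIMILARITY_MODES = ("group-based", "matrix-positive")

CATEGORY_THRESHOLDS = (
    (0.75, "high"),
    (0.50, "medium-high"),
    (0.25, "medium-low"),
)


@dataclass(frozen=True)
class ProteinSequence:
    """A mature protein sequence (signal/pro-peptides already removed)."""

    id: str
    residues: str
    name: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty sequence")
        bad = sorted({c for c in self.residues if c not in AMINO_ACIDS})
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: non-standard residue character(s) "
                f"{', '.join(bad)} (allowed: {AMINO_ACIDS})"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment and similarity conventions used throughout the package."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    similarity_mode: str = "group-based"
    similarity_groups: tuple[str, ...] = DEFAULT_SIMILARITY_GROUPS

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")
        if self.similarity_mode not in SIMILARITY_MODES:
            raise ValueError(f"unknown similarity_mode {self.similarity_mode!r}")
        seen: set[str] = set()
        for group in self.similarity_groups:
            overlap = seen.intersection(group)
            if overlap:
                raise ValueError(f"similarity groups overlap on {sorted(overlap)}")
            seen.update(group)

    @functools.cached_property
    def matrix(self):
        return substitution_matrices.load(self.matrix_name)

    @functools.cached_property
    def _group_of(self) -> dict[str, int]:
        return {aa: k for k, g in enumerate(self.similarity_groups) for aa in g}

    def is_similar(self, a: str, b: str) -> bool:
        """Whether residues *a* and *b* count as similar (identity implies
        similarity in either mode)."""
        if a == b:
            return True
        if self.similarity_mode == "group-based":
            ga, gb = self._group_of.get(a), self._group_of.get(b)
            return ga is not None and ga == gb
        return self.matrix[a, b] > 0

    def to_dict(self) -> dict:
        return {
            "matrix_name": self.matrix_name,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "similarity_mode": self.similarity_mode,
            "similarity_groups": list(self.similarity_groups),
        }


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two equal-length gapped strings plus the score that produced them."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")
        if any(x == GAP and y == GAP for x, y in zip(self.aligned_a, self.aligned_b)):
            raise ValueError("alignment contains an all-gap column")

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace(GAP, "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.aligned_a)


@dataclass(frozen=True)
class IdentitySimilarityResult:
    id_a: str
    id_b: str
    n_identical: int
    n_similar: int
    denominator: float
    denominator_mode: str
    identity: float
    similarity: float


@dataclass(frozen=True)
class ARISCResult:
    pair: tuple[str, str]
    identity: float
    similarity: float
    arisc: float
    category: str


def read_fasta(path: str | Path, permissive: bool = False) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file.

    Sequences are upper-cased and validated against the 20-letter standard
    alphabet.  With ``permissive=True`` records containing non-standard
    characters are dropped (reported on the returned list's behalf via a
    ValueError message otherwise).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        try:
            out.append(
                ProteinSequence(
                    id=rec.id,
                    residues=str(rec.seq).upper(),
                    name=rec.description,
                    source=str(path),
                )
            )
        except ValueError:
            if not permissive:
                raise
    if not out:
        raise ValueError(f"{path}: no valid records after filtering")
    return out


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}" + (f" {s.name}" if s.name else "") + "\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Global alignment (Gotoh affine-gap Needleman-Wunsch)
# ---------------------------------------------------------------------------

# A gap of length L costs gap_open + (L - 1) * gap_extend.  The dynamic
# program runs in integer half-units (BLOSUM scores are integers and the
# default extend penalty is 0.5) so traceback comparisons are exact.

_NEG = -(10 ** 9)


def align_pair(
    a: ProteinSequence, b: ProteinSequence, scheme: ScoringScheme | None = None
) -> PairwiseAlignment:
    """Optimal global alignment of *a* and *b* under *scheme*.

    Ties during traceback are broken deterministically: an aligned residue
    pair is preferred over a gap in the first sequence, which is preferred
    over a gap in the second.
    """
    scheme = scheme or ScoringScheme()
    sa, sb = a.residues, b.residues
    n, m = len(sa), len(sb)
    mat = scheme.matrix
    sub = [[int(round(2 * mat[x, y])) for y in sb] for x in sa]
    go = int(round(2 * scheme.gap_open))
    ge = int(round(2 * scheme.gap_extend))

    # M: column ends in residue pair; X: gap in b (consumes a);
    # Y: gap in a (consumes b).
    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = -go - (i - 1) * ge
    for j in range(1, m + 1):
        Y[0][j] = -go - (j - 1) * ge
    for i in range(1, n + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        si = sub[i - 1]
        for j in range(1, m + 1):
            s = si[j - 1]
            Mi[j] = max(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + s
            Xi[j] = max(Mp[j] - go, Xp[j] - ge, Yp[j] - go)
            Yi[j] = max(Mi[j - 1] - go, Xi[j - 1] - go, Yi[j - 1] - ge)

    # Traceback; state preference M > Y (gap in aligned_a) > X (gap in
    # aligned_b) at equal score.
    i, j = n, m
    best = max(M[n][m], Y[n][m], X[n][m])
    if M[n][m] == best:
        state = "M"
    elif Y[n][m] == best:
        state = "Y"
    else:
        state = "X"
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = sub[i - 1][j - 1]
            target = M[i][j] - s
            i, j = i - 1, j - 1
            ra.append(sa[i])
            rb.append(sb[j])
            if i == 0 and j == 0:
                break
            if M[i][j] == target:
                state = "M"
            elif Y[i][j] == target:
                state = "Y"
            else:
                state = "X"
        elif state == "Y":
            val = Y[i][j]
            j -= 1
            ra.append(GAP)
            rb.append(sb[j])
            if M[i][j] - go == val:
                state = "M"
            elif Y[i][j] - ge == val:
                state = "Y"
            else:
                state = "X"
        else:  # X
            val = X[i][j]
            i -= 1
            ra.append(sa[i])
            rb.append(GAP)
            if M[i][j] - go == val:
                state = "M"
            elif Y[i][j] - go == val:
                state = "Y"
            else:
                state = "X"
    return PairwiseAlignment(
        id_a=a.id,
        id_b=b.id,
        aligned_a="".join(reversed(ra)),
        aligned_b="".join(reversed(rb)),
        score=best / 2.0,
    )


def score_alignment(aln: PairwiseAlignment, scheme: ScoringScheme | None = None) -> float:
    """Score a fixed alignment under *scheme* (same gap model as align_pair)."""
    scheme = scheme or ScoringScheme()
    mat = scheme.matrix
    total = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == GAP:
            total -= scheme.gap_extend if in_gap_a else scheme.gap_open
            in_gap_a, in_gap_b = True, False
        elif y == GAP:
            total -= scheme.gap_extend if in_gap_b else scheme.gap_open
            in_gap_a, in_gap_b = False, True
        else:
            total += float(mat[x, y])
            in_gap_a = in_gap_b = False
    return total


# ---------------------------------------------------------------------------
# Identity / similarity / A-RISC
# ---------------------------------------------------------------------------


def identity_similarity(
    aln: PairwiseAlignment,
    scheme: ScoringScheme | None = None,
    denominator_mode: str = "shorter-sequence",
) -> IdentitySimilarityResult:
    """Count identical and similar alignment columns and normalise them.

    Gapped columns never count as identical or similar; the denominator is
    controlled by *denominator_mode* (see module docstring).
    """
    scheme = scheme or ScoringScheme()
    if denominator_mode not in DENOMINATOR_MODES:
        raise ValueError(
            f"unknown denominator_mode {denominator_mode!r}; "
            f"expected one of {DENOMINATOR_MODES}"
        )
    n_id = n_sim = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == GAP or y == GAP:
            continue
        if x == y:
            n_id += 1
            n_sim += 1
        elif scheme.is_similar(x, y):
            n_sim += 1
    la, lb = len(aln.seq_a), len(aln.seq_b)
    if denominator_mode == "shorter-sequence":
        denom = float(min(la, lb))
    elif denominator_mode == "mean-length":
        denom = (la + lb) / 2.0
    else:
        denom = float(len(aln))
    return IdentitySimilarityResult(
        id_a=aln.id_a,
        id_b=aln.id_b,
        n_identical=n_id,
        n_similar=n_sim,
        denominator=denom,
        denominator_mode=denominator_mode,
        identity=n_id / denom,
        similarity=n_sim / denom,
    )


def categorize(arisc_value: float) -> str:
    """Cross-reactivity risk category for an A-RISC value (inclusive lower
    bounds: 0.75 is high, 0.50 medium-high, 0.25 medium-low)."""
    for threshold, label in CATEGORY_THRESHOLDS:
        if arisc_value >= threshold:
            return label
    return "low"


def arisc(idsim: IdentitySimilarityResult) -> ARISCResult:
    """A-RISC index: the mean of identity and similarity, with its risk
    category."""
    value = (idsim.identity + idsim.similarity) / 2.0
    return ARISCResult(
        pair=(idsim.id_a, idsim.id_b),
        identity=idsim.identity,
        similarity=idsim.similarity,
        arisc=value,
        category=categorize(value),
    )


def arisc_pair(
    a: ProteinSequence,
    b: ProteinSequence,
    scheme: ScoringScheme | None = None,
    denominator_mode: str = "shorter-sequence",
) -> ARISCResult:
    """Align two sequences and compute their A-RISC index.

    Inputs are ordered canonically by id before alignment so the index is
    exactly symmetric in its arguments.
    """
    first, second = sorted((a, b), key=lambda s: s.id)
    aln = align_pair(first, second, scheme)
    result = arisc(identity_similarity(aln, scheme, denominator_mode))
    if (result.pair[0], result.pair[1]) != (a.id, b.id):
        result = replace(result, pair=(a.id, b.id))
    return result


def arisc_profile(
    query: ProteinSequence,
    family: Sequence[ProteinSequence],
    scheme: ScoringScheme | None = None,
    denominator_mode: str = "shorter-sequence",
) -> pd.DataFrame:
    """A-RISC of *query* against every family member, highest risk first.

    Returns a DataFrame with columns id, name, identity, similarity, arisc
    and category, sorted by descending arisc (ties broken by id); the query
    itself is excluded from its own profile.
    """
    members = [s for s in family if s.id != query.id]
    if not members:
        raise ValueError("family contains no sequences other than the query")
    rows = []
    for member in members:
        res = arisc_pair(query, member, scheme, denominator_mode)
        rows.append(
            {
                "id": member.id,
                "name": member.name,
                "identity": res.identity,
                "similarity": res.similarity,
                "arisc": res.arisc,
                "category": res.category,
            }
        )
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        ["arisc", "id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return frame


# ---------------------------------------------------------------------------
# MSA support
# ---------------------------------------------------------------------------


def read_msa(path: str | Path, fmt: str | None = None):
    """Read a multiple sequence alignment (aligned FASTA or Clustal)."""
    path = Path(path)
    formats = [fmt] if fmt else ["fasta", "clustal"]
    last_err: Exception | None = None
    for f in formats:
        try:
            return AlignIO.read(str(path), f)
        except ValueError as err:  # wrong format or ragged rows
            last_err = err
    raise ValueError(f"{path}: could not parse as MSA ({last_err})")


def pair_from_msa(msa, id_a: str, id_b: str, scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Extract the induced pairwise alignment of two MSA rows.

    Columns gapped in both rows are dropped so the result satisfies the
    pairwise-alignment invariants; the score is the fixed alignment's score
    under *scheme*.
    """
    rows = {rec.id: str(rec.seq).upper() for rec in msa}
    for wanted in (id_a, id_b):
        if wanted not in rows:
            raise KeyError(f"id {wanted!r} not present in MSA (has {sorted(rows)})")
    ra, rb = rows[id_a], rows[id_b]
    kept = [(x, y) for x, y in zip(ra, rb) if not (x == GAP and y == GAP)]
    aligned_a = "".join(x for x, _ in kept)
    aligned_b = "".join(y for _, y in kept)
    aln = PairwiseAlignment(id_a=id_a, id_b=id_b, aligned_a=aligned_a, aligned_b=aligned_b, score=0.0)
    return replace(aln, score=score_alignment(aln, scheme))
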
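"""Position-specific scoring profile construction and local domain search.

A profile is built from a reference multiple alignment of the domain
(match columns = columns with gap fraction below one half, the usual
profile-HMM convention) and is then aligned locally against query
proteins with affine gap penalties. The best local hit yields a mapping
from the profile's canonical column numbering onto protein positions;
that numbering is the coordinate system every downstream rule (basic
region = columns 1-17, the 19 conserved positions, intron references)
lives in.

Scores are log-odds in bits:

    score(c, r) = log2( (n_c(r) + w * b(r)) / (n_c + w) / b(r) )

where ``n_c(r)`` counts residue ``r`` among the non-gap residues of
match column ``c``, ``n_c`` is the column's non-gap total, ``b`` the
background distribution and ``w`` the pseudocount weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .alphabet import AMINO_ACIDS, GAP, check_protein
from .errors import (
    AlignmentShapeError,
    AlphabetError,
    ConfigError,
    ConsistencyError,
    InputError,
)

UNIFORM_BACKGROUND = {aa: 1.0 / 20.0 for aa in AMINO_ACIDS}

DEFAULT_GAP_OPEN = 4.0
DEFAULT_GAP_EXTEND = 0.5
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class ReferenceAlignment:
    """A rectangular gapped alignment of reference domain sequences.

    ``match_mask[j]`` is True for columns whose gap fraction is < 0.5;
    only those columns become profile columns and receive canonical
    numbers 1..n in left-to-right order.
    """

    records: tuple[tuple[str, str], ...]
    match_mask: tuple[bool, ...]

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, str]]) -> "ReferenceAlignment":
        if len(records) < 2:
            raise AlignmentShapeError("reference alignment needs >= 2 rows")
        width = len(records[0][1])
        clean = []
        for name, row in records:
            row = check_protein(row, allow_gap=True)
            if len(row) != width:
                raise AlignmentShapeError(
                    f"row {name!r} has length {len(row)}, expected {width}"
                )
            clean.append((name, row))
        if width == 0:
            raise AlignmentShapeError("alignment has zero columns")
        n = len(clean)
        mask = tuple(
            sum(row[j] == GAP for _, row in clean) / n < 0.5 for j in range(width)
        )
        return cls(records=tuple(clean), match_mask=mask)

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.match_mask)

    def match_columns(self) -> list[int]:
        """0-based indices of match columns."""
        return [j for j, m in enumerate(self.match_mask) if m]

    def member_match_sequence(self, index: int) -> str:
        """Row ``index`` restricted to match columns, gaps kept."""
        row = self.records[index][1]
        return "".join(row[j] for j in self.match_columns())


@dataclass(frozen=True)
class ScoringProfile:
    """Log-odds scoring profile over canonical columns 1..n_columns."""

    n_columns: int
    scores: tuple[Mapping[str, float], ...]
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    background: Mapping[str, float] = field(
        default_factory=lambda: dict(UNIFORM_BACKGROUND)
    )
    pseudocount_weight: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        if self.n_columns < 1:
            raise ConfigError("profile needs at least one column")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ConfigError("gap penalties must be >= 0")
        total = sum(self.background.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"background frequencies sum to {total}, not 1")

    def score(self, column: int, residue: str) -> float:
        """Score of ``residue`` at canonical ``column`` (1-based)."""
        return self.scores[column - 1][residue]

    def self_score(self, sequence: str) -> float:
        """Ungapped score of a sequence laid column-by-column on the profile.

        Gap characters contribute the affine penalty for the run they
        belong to. Used to calibrate ``min_score`` from reference members.
        """
        seq = check_protein(sequence, allow_gap=True)
        if len(seq) != self.n_columns:
            raise InputError(
                f"sequence length {len(seq)} != profile columns {self.n_columns}"
            )
        total = 0.0
        in_gap = False
        for col, res in enumerate(seq, start=1):
            if res == GAP:
                total -= self.gap_extend if in_gap else self.gap_open
                in_gap = True
            else:
                total += self.score(col, res)
                in_gap = False
        return total


@dataclass(frozen=True)
class DomainHit:
    """Best local alignment of the profile within one protein.

    ``column_map[c-1]`` is the 1-based protein position matched to
    canonical column ``c``, or None where the column is deleted or
    outside the aligned span. ``insertions`` lists protein residues that
    fall between profile columns as ``(after_column, positions)``.
    """

    protein_id: str
    start: int
    end: int
    score: float
    column_map: tuple[Optional[int], ...]
    insertions: tuple[tuple[int, tuple[int, ...]], ...] = ()
    sequence: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise InputError("hit coordinates must satisfy 1 <= start <= end")
        mapped = [p for p in self.column_map if p is not None]
        if any(b <= a for a, b in zip(mapped, mapped[1:])):
            raise InputError("mapped positions must be strictly increasing")


@dataclass(frozen=True)
class AlignedDomain:
    """A domain expressed in canonical column coordinates.

    ``residues[c-1]`` is the residue at canonical column ``c`` or None
    for a gap; ``positions`` carries the matching protein positions.
    """

    protein_id: str
    residues: tuple[Optional[str], ...]
    positions: tuple[Optional[int], ...] = ()
    insertions: tuple[tuple[int, str], ...] = ()

    @classmethod
    def from_sequence(cls, sequence: str, protein_id: str = "") -> "AlignedDomain":
        """Treat an (optionally gapped) string as columns 1..len."""
        seq = check_protein(sequence, allow_gap=True)
        residues = tuple(None if ch == GAP else ch for ch in seq)
        pos: list[Optional[int]] = []
        p = 0
        for ch in seq:
            if ch == GAP:
                pos.append(None)
            else:
                p += 1
                pos.append(p)
        return cls(protein_id=protein_id, residues=residues, positions=tuple(pos))

    @property
    def n_columns(self) -> int:
        return len(self.residues)

    def residue(self, column: int) -> Optional[str]:
        if not 1 <= column <= self.n_columns:
            raise InputError(f"canonical column {column} outside 1..{self.n_columns}")
        return self.residues[column - 1]


def build_profile(
    aln: ReferenceAlignment,
    pseudocount_weight: float = DEFAULT_PSEUDOCOUNT,
    background: Optional[Mapping[str, float]] = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> ScoringProfile:
    """Build a log-odds profile over the alignment's match columns."""
    if pseudocount_weight < 0:
        raise ConfigError("pseudocount_weight must be >= 0")
    bg = dict(background) if background is not None else dict(UNIFORM_BACKGROUND)
    missing = set(AMINO_ACIDS) - set(bg)
    if missing:
        raise ConfigError(f"background lacks residues: {sorted(missing)}")
    scores = []
    for j in aln.match_columns():
        column = [row[j] for _, row in aln.records if row[j] != GAP]
        n_eff = len(column)
        col_scores = {}
        for aa in AMINO_ACIDS:
            num = column.count(aa) + pseudocount_weight * bg[aa]
            denom = (n_eff + pseudocount_weight) * bg[aa]
            col_scores[aa] = math.log2(num / denom) if num > 0 else float("-inf")
        scores.append(col_scores)
    if not scores:
        raise AlignmentShapeError("alignment has no match columns")
    return ScoringProfile(
        n_columns=len(scores),
        scores=tuple(scores),
        gap_open=gap_open,
        gap_extend=gap_extend,
        background=bg,
        pseudocount_weight=pseudocount_weight,
    )


def default_min_score(
    profile: ScoringProfile, aln: ReferenceAlignment, fraction: float = 0.8
) -> float:
    """Calibrate the hit threshold from the reference members.

    Returns ``fraction`` times the minimum self-score over the members
    of the alignment the profile was built from, so every reference
    member clears the threshold with margin.
    """
    selfs = [
        profile.self_score(aln.member_match_sequence(i)) for i in range(aln.n_rows)
    ]
    return fraction * min(selfs)


# DP states: M = column matched to residue, I = protein residues inserted
# between columns, D = profile column deleted. Local alignments start and
# end in M. Gap of length k costs gap_open + (k-1)*gap_extend.
_NEG = float("-inf")


def locate_domain(
    protein: str,
    profile: ScoringProfile,
    min_score: float = 0.0,
    protein_id: str = "",
) -> Optional[DomainHit]:
    """Maximum-scoring local alignment of the profile to ``protein``.

    Returns None when the best score is below ``min_score``. Ties are
    broken toward the smallest protein start, then the smallest end.
    """
    seq = check_protein(protein)
    if not seq:
        raise InputError("empty protein sequence")
    n, L = profile.n_columns, len(seq)
    open_, ext = profile.gap_open, profile.gap_extend

    # Row-major DP over columns i=1..n, positions j=1..L.
    M = [[_NEG] * (L + 1) for _ in range(n + 1)]
    I = [[_NEG] * (L + 1) for _ in range(n + 1)]
    D = [[_NEG] * (L + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        row_scores = profile.scores[i - 1]
        Mi, Ii, Di = M[i], I[i], D[i]
        Mp, Ip, Dp = M[i - 1], I[i - 1], D[i - 1]
        for j in range(1, L + 1):
            s = row_scores[seq[j - 1]]
            best_prev = max(0.0, Mp[j - 1], Ip[j - 1], Dp[j - 1])
            Mi[j] = s + best_prev
            Ii[j] = max(Mi[j - 1] - open_, Ii[j - 1] - ext)
            Di[j] = max(Mp[j] - open_, Dp[j] - ext)

    best = _NEG
    for i in range(1, n + 1):
        row = M[i]
        m = max(row[1:])
        if m > best:
            best = m
    if best == _NEG or best < min_score:
        return None

    # Collect optimal endpoints, traceback each, keep smallest (start, end).
    candidates = []
    for i in range(1, n + 1):
        for j in range(1, L + 1):
            if M[i][j] == best:
                candidates.append((i, j))
    chosen = None
    for i_end, j_end in candidates:
        col_map, insertions, start = _traceback(
            M, I, D, profile, seq, i_end, j_end, open_, ext
        )
        key = (start, j_end)
        if chosen is None or key < chosen[0]:
            chosen = (key, i_end, j_end, col_map, insertions, start)
    _, i_end, j_end, col_map, insertions, start = chosen
    return DomainHit(
        protein_id=protein_id,
        start=start,
        end=j_end,
        score=best,
        column_map=tuple(col_map),
        insertions=tuple(
            (after, tuple(pos)) for after, pos in sorted(insertions.items())
        ),
        sequence=seq,
    )


def _close(a: float, b: float) -> bool:
    return a == b or math.isclose(a, b, rel_tol=1e-9, abs_tol=1e-9)


def _traceback(M, I, D, profile, seq, i, j, open_, ext):
    n = profile.n_columns
    col_map: list[Optional[int]] = [None] * n
    insertions: dict[int, list[int]] = {}
    state = "M"
    start = j
    while True:
        if state == "M":
            col_map[i - 1] = j
            prev = M[i][j] - profile.scores[i - 1][seq[j - 1]]
            # Prefer extending over a fresh local start: smaller start wins.
            if i > 1 and j > 1 and _close(prev, M[i - 1][j - 1]):
                state = "M"
            elif i > 1 and j > 1 and _close(prev, D[i - 1][j - 1]):
                state = "D"
            elif i > 1 and j > 1 and _close(prev, I[i - 1][j - 1]):
                state = "I"
            else:  # local start of the alignment
                start = j
                break
            i, j = i - 1, j - 1
        elif state == "I":
            insertions.setdefault(i, []).insert(0, j)
            state = "M" if _close(I[i][j], M[i][j - 1] - open_) else "I"
            j -= 1
        else:  # D: profile column i deleted
            state = "M" if _close(D[i][j], M[i - 1][j] - open_) else "D"
            i -= 1
    return col_map, insertions, start


def canonical_map(hit: DomainHit, profile: ScoringProfile) -> AlignedDomain:
    """Express a hit as residues over canonical columns 1..n_columns."""
    if len(hit.column_map) != profile.n_columns:
        raise ConsistencyError(
            f"hit maps {len(hit.column_map)} columns but profile has "
            f"{profile.n_columns}"
        )
    if not hit.sequence:
        raise ConsistencyError("hit carries no sequence; produced by locate_domain?")
    residues = tuple(
        None if p is None else hit.sequence[p - 1] for p in hit.column_map
    )
    ins = tuple(
        (after, "".join(hit.sequence[p - 1] for p in positions))
        for after, positions in hit.insertions
    )
    return AlignedDomain(
        protein_id=hit.protein_id,
        residues=residues,
        positions=hit.column_map,
        insertions=ins,
    )
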
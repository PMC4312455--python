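"""Family-membership filtering by conserved-residue mismatches.

The bHLH domain carries 19 characteristically conserved positions in
canonical column coordinates: five in the basic region, five in the
first helix, one in the loop and eight in the second helix. A candidate
domain is accepted into the family when at most ``max_mismatches``
(default 9) of those positions carry a residue outside the position's
allowed set; a gap at a conserved position counts as a mismatch, and a
region whose conserved positions are all gapped marks the domain as
incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .errors import ConfigError, InputError, MappingError
from .profile_search import AlignedDomain

REGIONS = ("basic", "helix1", "loop", "helix2")

#: Canonical column spans of the domain's structural regions.
REGION_SPANS = {
    "basic": (1, 17),
    "helix1": (18, 28),
    "loop": (29, 43),
    "helix2": (44, 61),
}


@dataclass(frozen=True)
class ConservedPosition:
    column: int
    region: str
    allowed: frozenset[str]
    frequencies: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ConservedPositionSet:
    """The conserved positions with their allowed residue sets."""

    entries: tuple[ConservedPosition, ...]

    def __post_init__(self) -> None:
        cols = [e.column for e in self.entries]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ConfigError("conserved positions must be strictly increasing")
        bad = {e.region for e in self.entries} - set(REGIONS)
        if bad:
            raise ConfigError(f"unknown regions: {sorted(bad)}")

    @classmethod
    def default(cls) -> "ConservedPositionSet":
        """The 19 positions and allowed residues of the tomato bHLH family."""
        with resources.files("bhlhkit.data").joinpath(
            "conserved_positions.tsv"
        ).open() as fh:
            return cls.from_tsv(fh)

    @classmethod
    def from_tsv(cls, source) -> "ConservedPositionSet":
        """Load a rule file: column, region, allowed_residues[, frequencies]."""
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                return cls.from_tsv(fh)
        entries = []
        header = None
        for line in source:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            row = dict(zip(header, fields))
            freqs = {}
            if row.get("frequencies"):
                for item in row["frequencies"].split(","):
                    aa, pct = item.split(":")
                    freqs[aa] = float(pct)
            entries.append(
                ConservedPosition(
                    column=int(row["column"]),
                    region=row["region"],
                    allowed=frozenset(row["allowed_residues"].split(",")),
                    frequencies=freqs,
                )
            )
        if not entries:
            raise InputError("empty conserved-position rule file")
        return cls(entries=tuple(entries))

    @property
    def columns(self) -> tuple[int, ...]:
        return tuple(e.column for e in self.entries)

    def by_region(self, region: str) -> tuple[ConservedPosition, ...]:
        return tuple(e for e in self.entries if e.region == region)


@dataclass(frozen=True)
class FamilyFilterConfig:
    max_mismatches: int = 9
    require_all_regions: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.max_mismatches <= 19:
            raise ConfigError("max_mismatches must be within 0..19")


@dataclass(frozen=True)
class FilterReport:
    protein_id: str
    mismatch_count: int
    passed: bool
    failing_positions: tuple[int, ...]
    incomplete_regions: tuple[str, ...]

    @property
    def reason(self) -> str:
        if self.passed:
            return "pass"
        if self.incomplete_regions:
            return "incomplete domain"
        return "too many mismatches"


def _check_coverage(domain: AlignedDomain, consensus: ConservedPositionSet) -> None:
    if domain.n_columns < max(consensus.columns):
        raise MappingError(
            f"domain covers {domain.n_columns} canonical columns; "
            f"consensus requires {max(consensus.columns)}"
        )


def count_mismatches(domain: AlignedDomain, consensus: ConservedPositionSet) -> int:
    """Number of conserved positions whose residue is outside the allowed set.

    A gap at a conserved position is a mismatch.
    """
    _check_coverage(domain, consensus)
    n = 0
    for entry in consensus.entries:
        res = domain.residue(entry.column)
        if res is None or res not in entry.allowed:
            n += 1
    return n


def passes_family_filter(
    domain: AlignedDomain,
    consensus: Optional[ConservedPositionSet] = None,
    cfg: FamilyFilterConfig = FamilyFilterConfig(),
) -> FilterReport:
    """Apply the mismatch and completeness criteria to one domain."""
    consensus = consensus or ConservedPositionSet.default()
    _check_coverage(domain, consensus)
    failing = []
    for entry in consensus.entries:
        res = domain.residue(entry.column)
        if res is None or res not in entry.allowed:
            failing.append(entry.column)
    incomplete = []
    if cfg.require_all_regions:
        for region in REGIONS:
            positions = consensus.by_region(region)
            if positions and all(
                domain.residue(e.column) is None for e in positions
            ):
                incomplete.append(region)
    passed = len(failing) <= cfg.max_mismatches and not incomplete
    return FilterReport(
        protein_id=domain.protein_id,
        mismatch_count=len(failing),
        passed=passed,
        failing_positions=tuple(failing),
        incomplete_regions=tuple(incomplete),
    )


def filter_family(
    domains: Iterable[AlignedDomain],
    consensus: Optional[ConservedPositionSet] = None,
    cfg: FamilyFilterConfig = FamilyFilterConfig(),
) -> list[FilterReport]:
    consensus = consensus or ConservedPositionSet.default()
    return [passes_family_filter(d, consensus, cfg) for d in domains]
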
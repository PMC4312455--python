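"""Intron positions relative to the domain CDS and pattern classification.

Introns are located by walking the CDS segments of a gene model in
transcript orientation and expressing each exon/exon boundary as a
(codon offset, phase) pair relative to the first codon of the domain's
coding region. An intron sitting exactly between domain codons k and
k+1 is reported as (k, 0); one interrupting a codon after its first or
second base carries phase 1 or 2.

Patterns are labels over which of the reference intron positions
(anchored to the PIF3 domain; three by default) a gene carries plus how
many non-reference introns it has. Pattern I means all three reference
introns and nothing else; pattern XI means an intron-free domain. The
remaining labels come from a catalogue table keyed by (matched subset,
extra count); unknown keys fall back to "other".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

from .errors import ConfigError, CoordinateError, GenerationError, InputError, ModelError

IntronPosition = tuple[int, int]  # (codon offset within domain, phase 0/1/2)

#: Documented default anchor positions of the three reference introns,
#: as codon offsets from the domain start (phase 0 = between codons).
DEFAULT_REFERENCE_POSITIONS: tuple[IntronPosition, ...] = ((9, 0), (27, 1), (45, 0))


@dataclass(frozen=True)
class GeneModel:
    """A transcript's CDS geometry plus the protein span of its domain."""

    gene_id: str
    chromosome: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]  # genomic, 1-based inclusive, 5'->3'
    domain_span: tuple[int, int]  # protein coordinates, 1-based inclusive

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ModelError(f"{self.gene_id}: strand must be + or -")
        for a, b in self.cds_segments:
            if a > b:
                raise ModelError(f"{self.gene_id}: CDS segment {a}..{b} inverted")
        spans = sorted(self.cds_segments)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ModelError(f"{self.gene_id}: overlapping CDS segments")

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds_segments)

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3


def domain_intron_positions(model: GeneModel) -> list[IntronPosition]:
    """Intron (codon, phase) offsets falling inside the domain CDS."""
    if model.cds_length % 3 != 0:
        raise ModelError(
            f"{model.gene_id}: CDS length {model.cds_length} not divisible by 3"
        )
    dstart, dend = model.domain_span
    if not 1 <= dstart <= dend <= model.protein_length:
        raise CoordinateError(
            f"{model.gene_id}: domain span {dstart}..{dend} outside protein "
            f"1..{model.protein_length}"
        )
    # cumulative CDS bases at each internal exon boundary, transcript order
    boundaries = []
    acc = 0
    for a, b in model.cds_segments[:-1]:
        acc += b - a + 1
        boundaries.append(acc)
    domain_cds_start = (dstart - 1) * 3  # bases before the domain's first codon
    domain_cds_len = (dend - dstart + 1) * 3
    positions = []
    for c in boundaries:
        d = c - domain_cds_start
        if 0 < d < domain_cds_len:
            positions.append((d // 3, d % 3))
    return positions


@dataclass(frozen=True)
class IntronReference:
    """Reference intron positions within the domain and a match tolerance."""

    positions: tuple[IntronPosition, ...] = DEFAULT_REFERENCE_POSITIONS
    tolerance: int = 0  # codons

    def __post_init__(self) -> None:
        codons = [c for c, _ in self.positions]
        if any(b <= a for a, b in zip(codons, codons[1:])):
            raise ConfigError("reference positions must be strictly increasing")
        if self.tolerance < 0:
            raise ConfigError("tolerance must be >= 0")

    def match(self, intron: IntronPosition) -> Optional[int]:
        """1-based index of the reference position this intron matches."""
        codon, phase = intron
        for idx, (ref_codon, ref_phase) in enumerate(self.positions, start=1):
            if self.tolerance == 0:
                if (codon, phase) == (ref_codon, ref_phase):
                    return idx
            elif abs(codon - ref_codon) <= self.tolerance:
                return idx
        return None


@dataclass(frozen=True)
class PatternCatalogue:
    """Lookup from (matched reference subset, extra intron count) to label."""

    table: dict[tuple[frozenset[int], int], str] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "PatternCatalogue":
        with resources.files("bhlhkit.data").joinpath(
            "pattern_catalogue.tsv"
        ).open() as fh:
            return cls.from_tsv(fh)

    @classmethod
    def from_tsv(cls, source) -> "PatternCatalogue":
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                return cls.from_tsv(fh)
        table = {}
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
            refs = row["matched_refs"]
            matched = (
                frozenset()
                if refs in ("-", "")
                else frozenset(int(x) for x in refs.split(","))
            )
            table[(matched, int(row["extra_introns"]))] = row["label"]
        if not table:
            raise InputError("empty pattern catalogue")
        cat = cls(table=table)
        # pinned meanings: these two labels are defined by the text itself
        if cat.table.get((frozenset({1, 2, 3}), 0)) != "I":
            raise ConfigError("catalogue must map all-three-references/0-extra to I")
        if cat.table.get((frozenset(), 0)) != "XI":
            raise ConfigError("catalogue must map the intron-free key to XI")
        return cat

    def key_for_label(self, label: str) -> tuple[frozenset[int], int]:
        for key, lab in self.table.items():
            if lab == label:
                return key
        raise GenerationError(f"label {label!r} not in pattern catalogue")


def classify_intron_pattern(
    positions: Sequence[IntronPosition],
    ref: IntronReference = IntronReference(),
    catalogue: Optional[PatternCatalogue] = None,
) -> str:
    """Assign the intron-distribution pattern label for one gene."""
    catalogue = catalogue or PatternCatalogue.default()
    matched: set[int] = set()
    extra = 0
    for intron in sorted(positions):
        idx = ref.match(intron)
        if idx is not None and idx not in matched:
            matched.add(idx)
        else:
            extra += 1
    return catalogue.table.get((frozenset(matched), extra), "other")
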
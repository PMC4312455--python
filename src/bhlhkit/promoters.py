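"""Promoter window extraction and degenerate cis-element scanning.

Promoters are the ``length`` bases immediately 5' of the transcription
start site in transcript orientation (reverse-complemented for minus-
strand genes). Motifs are IUPAC strings matched exactly on both
strands; hit positions are the 5'-most base of the match on the
promoter's forward orientation, reported both 1-based within the window
and as a negative offset where -1 is the base immediately upstream of
the TSS.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence, Union

from .alphabet import IUPAC_DNA, check_iupac, revcomp
from .duplication import GeneLocus
from .errors import CoordinateError, InputError


@dataclass(frozen=True)
class MotifLibrary:
    """Named IUPAC motifs; the defaults are the five fruit-development
    elements (ethylene-responsive ERELEE4, the TGTCACA enhancer, the
    I-box and its core, and the I-box-like negative element)."""

    motifs: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "motifs",
            {name: check_iupac(m) for name, m in self.motifs.items()},
        )

    @classmethod
    def default(cls) -> "MotifLibrary":
        with resources.files("bhlhkit.data").joinpath("motifs.tsv").open() as fh:
            return cls.from_tsv(fh)

    @classmethod
    def from_tsv(cls, source) -> "MotifLibrary":
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                return cls.from_tsv(fh)
        motifs = {}
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
            motifs[row["name"]] = row["iupac"]
        if not motifs:
            raise InputError("empty motif library")
        return cls(motifs=motifs)


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int  # 1-based, 5'-most base on the promoter's forward orientation
    strand: str  # "+" | "-"
    offset: int  # position relative to the TSS; -1 = base just upstream

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError("strand must be + or -")


def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for code in motif:
        bases = IUPAC_DNA[code]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead keeps overlapping occurrences
    return re.compile(f"(?=({''.join(parts)}))")


def scan_motifs(
    seq: str, library: Union[MotifLibrary, None] = None
) -> list[MotifHit]:
    """All degenerate matches of the library on both strands of ``seq``.

    Minus-strand hits are matches of a motif's reverse complement on
    the forward sequence, with the position of their 5'-most forward
    base reported. Hits are ordered by (start, strand, motif name).
    """
    library = library or MotifLibrary.default()
    seq = seq.upper()
    L = len(seq)
    hits = []
    for name, motif in library.motifs.items():
        for pattern, strand in (
            (_iupac_regex(motif), "+"),
            (_iupac_regex(revcomp(motif)), "-"),
        ):
            for match in pattern.finditer(seq):
                start = match.start() + 1
                hits.append(
                    MotifHit(
                        motif=name,
                        start=start,
                        strand=strand,
                        offset=start - L - 1,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand, h.motif))
    return hits


def extract_promoter(
    genome: Mapping[str, str],
    locus: GeneLocus,
    length: int = 1500,
) -> str:
    """The ``length`` bases 5' of the TSS in transcript orientation.

    For a plus-strand gene the TSS is the gene start and the window is
    the genomic interval [start-length, start-1]; for a minus-strand
    gene the TSS is the gene end and the window is [end+1, end+length]
    reverse-complemented. Windows truncated by a contig edge shrink
    with a warning.
    """
    if locus.chromosome not in genome:
        raise CoordinateError(f"{locus.gene_id}: contig {locus.chromosome!r} unknown")
    chrom = genome[locus.chromosome]
    if not 1 <= locus.start <= locus.end <= len(chrom):
        raise CoordinateError(
            f"{locus.gene_id}: locus {locus.start}..{locus.end} outside contig "
            f"of length {len(chrom)}"
        )
    if locus.strand == "+":
        lo = locus.start - length
        if lo < 1:
            warnings.warn(
                f"{locus.gene_id}: promoter truncated to {locus.start - 1} bp "
                "by contig start"
            )
            lo = 1
        return chrom[lo - 1 : locus.start - 1].upper()
    hi = locus.end + length
    if hi > len(chrom):
        warnings.warn(
            f"{locus.gene_id}: promoter truncated to {len(chrom) - locus.end} bp "
            "by contig end"
        )
        hi = len(chrom)
    return revcomp(chrom[locus.end : hi])


def scan_promoters(
    promoters: Mapping[str, str], library: Union[MotifLibrary, None] = None
) -> dict[str, list[MotifHit]]:
    library = library or MotifLibrary.default()
    return {name: scan_motifs(seq, library) for name, seq in promoters.items()}
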
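"""Gene-duplication classification and tandem-array detection.

Protein pairs are aligned globally (BLOSUM62, affine gaps, free end
gaps) and classified as high-stringency duplications at >= 50% identity
and >= 90% coverage, or low-stringency at >= 30% identity and >= 70%
coverage. Identity is identical aligned pairs over aligned non-gap
pairs; coverage is aligned non-gap pairs over the longer sequence
length, which keeps both statistics symmetric in the pair.

Tandem array genes (TAGs) are family members adjacent in chromosomal
gene order or separated by at most ``max_spacers`` non-family genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .alphabet import check_protein
from .errors import ConfigError, InputError


@dataclass(frozen=True)
class StringencyThresholds:
    min_identity: float
    min_coverage: float


@dataclass(frozen=True)
class DuplicationConfig:
    low: StringencyThresholds = StringencyThresholds(30.0, 70.0)
    high: StringencyThresholds = StringencyThresholds(50.0, 90.0)
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if (
            self.high.min_identity < self.low.min_identity
            or self.high.min_coverage < self.low.min_coverage
        ):
            raise ConfigError("high-stringency thresholds must be >= low ones")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ConfigError("gap penalties must be >= 0")


@dataclass(frozen=True)
class PairStats:
    id_a: str
    id_b: str
    identity: float
    coverage: float
    dup_class: str  # "high" | "low" | "none"


def _make_aligner(cfg: DuplicationConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(cfg.matrix)
    aligner.open_gap_score = -cfg.gap_open
    aligner.extend_gap_score = -cfg.gap_extend
    # free end gaps: coverage, not end-to-end similarity, is the question
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _classify(identity: float, coverage: float, cfg: DuplicationConfig) -> str:
    if identity >= cfg.high.min_identity and coverage >= cfg.high.min_coverage:
        return "high"
    if identity >= cfg.low.min_identity and coverage >= cfg.low.min_coverage:
        return "low"
    return "none"


def pairwise_stats(
    a: str,
    b: str,
    cfg: DuplicationConfig = DuplicationConfig(),
    id_a: str = "a",
    id_b: str = "b",
    aligner: Optional[Align.PairwiseAligner] = None,
) -> PairStats:
    """Identity/coverage statistics and stringency class for one pair."""
    a, b = check_protein(a), check_protein(b)
    if not a or not b:
        raise InputError("cannot align an empty sequence")
    if aligner is None:
        aligner = _make_aligner(cfg)
    # canonical orientation keeps tie-broken alignments symmetric in (a, b)
    swap = (len(a), a) > (len(b), b)
    s1, s2 = (b, a) if swap else (a, b)
    alignment = aligner.align(s1, s2)[0]
    aligned_pairs = 0
    identical = 0
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        aligned_pairs += t1 - t0
        identical += sum(
            s1[t0 + k] == s2[q0 + k] for k in range(t1 - t0)
        )
    longer = max(len(a), len(b))
    identity = 100.0 * identical / aligned_pairs if aligned_pairs else 0.0
    coverage = 100.0 * aligned_pairs / longer
    return PairStats(
        id_a=id_a,
        id_b=id_b,
        identity=identity,
        coverage=coverage,
        dup_class=_classify(identity, coverage, cfg),
    )


def classify_family_duplications(
    members: Mapping[str, str], cfg: DuplicationConfig = DuplicationConfig()
) -> tuple[dict[str, str], list[PairStats]]:
    """All-vs-all duplication classes for a family.

    A gene is "high" if it participates in at least one high-stringency
    pair, else "low" if in at least one low-stringency pair, else
    "singleton". Returns the per-gene class map and all pair statistics.
    """
    ids = list(members)
    if len(ids) < 2:
        raise InputError("need at least two family members")
    if len(set(ids)) != len(ids):
        raise InputError("duplicate gene ids")
    aligner = _make_aligner(cfg)
    gene_class = {g: "singleton" for g in ids}
    pairs = []
    rank = {"singleton": 0, "low": 1, "high": 2}
    for ga, gb in itertools.combinations(ids, 2):
        stats = pairwise_stats(
            members[ga], members[gb], cfg, id_a=ga, id_b=gb, aligner=aligner
        )
        pairs.append(stats)
        if stats.dup_class != "none":
            for g in (ga, gb):
                if rank[stats.dup_class] > rank[gene_class[g]]:
                    gene_class[g] = stats.dup_class
    return gene_class, pairs


def duplication_counts(gene_class: Mapping[str, str]) -> dict[str, int]:
    return {
        "high": sum(1 for c in gene_class.values() if c == "high"),
        "low": sum(1 for c in gene_class.values() if c == "low"),
        "singleton": sum(1 for c in gene_class.values() if c == "singleton"),
    }


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int
    family_member: bool = True

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise InputError(f"{self.gene_id}: strand must be + or -")


def rank_loci(loci: Iterable[GeneLocus]) -> list[GeneLocus]:
    """Assign per-chromosome gene-order ranks by start coordinate."""
    out = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chromosome, []).append(locus)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end, l.gene_id))
        for i, locus in enumerate(ordered, start=1):
            out.append(
                GeneLocus(
                    gene_id=locus.gene_id,
                    chromosome=locus.chromosome,
                    start=locus.start,
                    end=locus.end,
                    strand=locus.strand,
                    rank=i,
                    family_member=locus.family_member,
                )
            )
    return out


def find_tags(
    loci: Sequence[GeneLocus], max_spacers: int = 1
) -> list[tuple[GeneLocus, ...]]:
    """Maximal tandem clusters of family loci.

    Consecutive family members on a chromosome belong to one cluster
    when at most ``max_spacers`` non-family genes lie between them;
    clusters of size >= 2 are returned in chromosome, then rank order.
    """
    if max_spacers < 0:
        raise ConfigError("max_spacers must be >= 0")
    by_chrom: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chromosome, []).append(locus)
    clusters = []
    for chrom in sorted(by_chrom):
        chrom_loci = sorted(by_chrom[chrom], key=lambda l: l.rank)
        ranks = [l.rank for l in chrom_loci]
        if len(set(ranks)) != len(ranks):
            raise InputError(f"rank collision on chromosome {chrom}")
        family = [l for l in chrom_loci if l.family_member]
        current: list[GeneLocus] = []
        for locus in family:
            if current and locus.rank - current[-1].rank - 1 <= max_spacers:
                current.append(locus)
            else:
                if len(current) >= 2:
                    clusters.append(tuple(current))
                current = [locus]
        if len(current) >= 2:
            clusters.append(tuple(current))
    return clusters
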
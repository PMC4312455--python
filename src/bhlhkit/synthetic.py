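"""Synthetic inputs with machine-readable planted truth.

Every generator takes a master seed and draws from hierarchical
substreams keyed by (seed, stream, entity index), so adding one entity
never reshuffles the others and regeneration is bit-identical.

The generators emulate the inputs of a genome-wide family
characterization: a reference domain alignment with controlled
per-column conservation; domain-bearing member proteins whose planted
mismatch counts and basic-region composition realize chosen DNA-binding
categories; decoy proteins verified by exhaustive window scan to carry
no acceptable domain; gene models whose introns realize chosen pattern
labels on either strand; duplicate protein pairs at target
identity/coverage; chromosomal gene orders with planted tandem arrays;
RPKM matrices with planted tissue-specific and fruit-trend genes; and
promoters with planted cis-elements. Decoys, duplicate pairs and
promoters are verified against the pipeline's own operations at
generation time, so "the truth is recoverable" is a checked property.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .alphabet import AMINO_ACIDS, DNA
from .binding import BindingCategory, BindingRuleSet, classify_binding
from .duplication import DuplicationConfig, GeneLocus, pairwise_stats
from .errors import GenerationError
from .expression import DEFAULT_FRUIT_STAGES, ExpressionConfig, ExpressionMatrix
from .family_filter import ConservedPositionSet
from .gene_structure import (
    GeneModel,
    IntronReference,
    PatternCatalogue,
)
from .profile_search import AlignedDomain, ReferenceAlignment
from .promoters import MotifLibrary, scan_motifs

import pandas as pd

DOMAIN_LENGTH = 61

#: Residue pools for the variable (non-conserved) basic-region columns.
#: Members and reference rows draw from the same pools, emulating a
#: family whose basic-region composition varies by binding type while
#: staying within a common compositional envelope.
BASIC_POOL = "KRH"
NONBASIC_POOL = "AGSTNQDE"

_STREAMS = {
    "template": 1,
    "reference": 2,
    "member": 3,
    "decoy": 4,
    "gene": 5,
    "expression": 6,
    "duplicate": 7,
    "promoter": 8,
    "loci": 9,
    "qpcr": 10,
}


def _rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _STREAMS[stream], int(index)])
    )


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA), size=length))


# ---------------------------------------------------------------------------
# Reference alignment and protein family


def consensus_template(
    consensus: ConservedPositionSet,
    seed: int = 0,
    domain_len: int = DOMAIN_LENGTH,
) -> str:
    """A gap-free template domain matching every conserved position."""
    rng = _rng(seed, "template")
    residues = [rng.choice(list(AMINO_ACIDS)) for _ in range(domain_len)]
    for entry in consensus.entries:
        if entry.column > domain_len:
            continue
        if entry.frequencies:
            residues[entry.column - 1] = max(
                sorted(entry.frequencies), key=lambda r: entry.frequencies[r]
            )
        else:
            residues[entry.column - 1] = sorted(entry.allowed)[0]
    return "".join(residues)


def _allowed_distribution(entry) -> tuple[list[str], list[float]]:
    """Residues and draw probabilities at a conserved position, following
    the reported frequencies where available."""
    residues = sorted(entry.allowed)
    weights = [entry.frequencies.get(r, 5.0) for r in residues]
    total = sum(weights)
    return residues, [w / total for w in weights]


def _variable_basic_columns(
    consensus: ConservedPositionSet, domain_len: int = DOMAIN_LENGTH
) -> list[int]:
    """Basic-region columns not constrained by the conserved positions."""
    cons = set(consensus.columns)
    return [c for c in range(1, min(17, domain_len) + 1) if c not in cons]


def _column_dominants(
    consensus: ConservedPositionSet, seed: int, domain_len: int = DOMAIN_LENGTH
) -> dict[int, tuple[str, str]]:
    """Family-specific dominant (basic, non-basic) residue per variable
    basic-region column. Both the reference rows and the members favour
    these dominants, so each column carries positional information even
    though its basic/non-basic balance varies by binding type."""
    rng = _rng(seed, "template", 1)
    return {
        c: (rng.choice(list(BASIC_POOL)), rng.choice(list(NONBASIC_POOL)))
        for c in _variable_basic_columns(consensus, domain_len)
    }


def _draw_variable(
    rng: np.random.Generator, dominants: tuple[str, str], want_basic: bool,
    fidelity: float = 0.8,
) -> str:
    dom_basic, dom_nonbasic = dominants
    if want_basic:
        return dom_basic if rng.random() < fidelity else rng.choice(list(BASIC_POOL))
    return (
        dom_nonbasic if rng.random() < fidelity else rng.choice(list(NONBASIC_POOL))
    )


def generate_reference_alignment(
    n_rows: int = 12,
    consensus: Optional[ConservedPositionSet] = None,
    conservation: float = 0.9,
    seed: int = 0,
    domain_len: int = DOMAIN_LENGTH,
) -> ReferenceAlignment:
    """Gap-free reference alignment around the consensus template.

    Each row keeps the template residue with probability
    ``conservation``; substitutions at conserved positions stay within
    the allowed set so every row passes the family filter.
    """
    consensus = consensus or ConservedPositionSet.default()
    template = consensus_template(consensus, seed=seed, domain_len=domain_len)
    dists = {
        e.column: _allowed_distribution(e)
        for e in consensus.entries
        if e.column <= domain_len
    }
    # non-conserved basic-region columns vary with binding type, not
    # family identity: half the rows carry the column's dominant basic
    # residue, half its dominant non-basic residue
    dominants = _column_dominants(consensus, seed, domain_len)
    records = []
    for i in range(n_rows):
        rng = _rng(seed, "reference", i)
        row = list(template)
        for col in range(1, domain_len + 1):
            if col in dominants:
                row[col - 1] = _draw_variable(
                    rng, dominants[col], want_basic=rng.random() < 0.5
                )
            elif col in dists:
                residues, probs = dists[col]
                row[col - 1] = rng.choice(residues, p=probs)
            elif rng.random() >= conservation:
                row[col - 1] = rng.choice(list(AMINO_ACIDS))
        records.append((f"REF{i + 1:03d}", "".join(row)))
    return ReferenceAlignment.from_records(records)


_CATEGORY_PINS = {
    # column -> residue choices; the realization draws one per member
    BindingCategory.G_BOX: {9: "HK", 13: "E", 16: "R", 17: "R"},
    BindingCategory.E_BOX_NON_G: {
        9: NONBASIC_POOL,
        13: "E",
        16: "R",
        17: NONBASIC_POOL,
    },
    BindingCategory.NON_E_BOX: {13: "A", 16: "R"},
    BindingCategory.NON_DNA_BINDING: {13: "A"},
}


def _build_member_domain(
    rng: np.random.Generator,
    template: str,
    consensus: ConservedPositionSet,
    category: BindingCategory,
    n_mismatches: int,
    rules: BindingRuleSet,
    dominants: Optional[dict[int, tuple[str, str]]] = None,
) -> str:
    """One domain realizing the category with exactly n_mismatches."""
    domain = list(template)
    cons_cols = set(consensus.columns)
    allowed_at = {e.column: e.allowed for e in consensus.entries}
    lo, hi = rules.basic_region_columns
    if dominants is None:
        dominants = {
            c: (BASIC_POOL[0], NONBASIC_POOL[0])
            for c in range(lo, hi + 1)
            if c not in cons_cols
        }

    pins = {}
    for col, choices in _CATEGORY_PINS[category].items():
        dom = dominants.get(col)
        if dom is not None:
            dom_basic, dom_nonbasic = dom
            # prefer the family's dominant residue when it satisfies the
            # category predicate: keeps pinned columns well-scoring
            if dom_basic in choices:
                pins[col] = dom_basic
                continue
            if dom_nonbasic in choices:
                pins[col] = dom_nonbasic
                continue
            if set(choices) <= set(NONBASIC_POOL):
                pins[col] = dom_nonbasic if dom_nonbasic in choices else rng.choice(
                    list(choices)
                )
                continue
        pins[col] = rng.choice(list(choices))
    # columns whose residue the category fixes and a mismatch may not touch;
    # the terminal columns stay matched so a local domain search never
    # trims a planted mismatch off the alignment ends
    protected = {min(cons_cols), sorted(cons_cols)[1], max(cons_cols)}
    if category in (BindingCategory.G_BOX, BindingCategory.E_BOX_NON_G):
        protected |= {13, 16}
    eligible = sorted(cons_cols - protected)
    if n_mismatches > len(eligible):
        raise GenerationError(
            f"cannot plant {n_mismatches} mismatches for category "
            f"{category.value}: only {len(eligible)} conserved positions free"
        )
    for col, res in pins.items():
        domain[col - 1] = res
    mismatch_cols = sorted(
        rng.choice(eligible, size=n_mismatches, replace=False).tolist()
    )
    for col in mismatch_cols:
        bad_pool = sorted(set(AMINO_ACIDS) - allowed_at[col])
        if lo <= col <= hi:
            bad_pool = sorted(set(bad_pool) - rules.basic_residues - {"E"})
        domain[col - 1] = rng.choice(bad_pool)

    # steer the basic-residue count: free columns are basic-region columns
    # that are neither conserved nor pinned by the category
    free = [
        c
        for c in range(lo, hi + 1)
        if c not in cons_cols and c not in pins
    ]
    for c in free:
        domain[c - 1] = _draw_variable(rng, dominants[c], want_basic=False)
    count = sum(
        1 for c in range(lo, hi + 1) if domain[c - 1] in rules.basic_residues
    )
    if category is BindingCategory.NON_DNA_BINDING:
        if count > rules.min_basic_count - 2:
            raise GenerationError(
                f"basic count {count} too high for a non-binding member"
            )
    else:
        target = rules.min_basic_count + 2  # margin; basic regions are basic-rich
        for c in free:
            if count >= target:
                break
            domain[c - 1] = _draw_variable(rng, dominants[c], want_basic=True)
            count += 1
        if count < rules.min_basic_count:
            raise GenerationError(
                f"cannot reach {rules.min_basic_count} basic residues for "
                f"{category.value} with {n_mismatches} planted mismatches"
            )
    return "".join(domain)


def _window_min_mismatches(seq: str, consensus: ConservedPositionSet, domain_len: int) -> int:
    """Minimum mismatch count over all ungapped windows of the sequence."""
    best = len(consensus.entries)
    cols = [(e.column - 1, e.allowed) for e in consensus.entries]
    for off in range(0, max(len(seq) - domain_len, 0) + 1):
        mm = sum(1 for rel, allowed in cols if off + rel >= len(seq) or seq[off + rel] not in allowed)
        best = min(best, mm)
    return best


def generate_family(
    n_members: int,
    n_decoys: int,
    consensus: Optional[ConservedPositionSet] = None,
    mismatch_spectrum: Optional[Sequence[int]] = None,
    binding_mix: Optional[Mapping[Union[str, BindingCategory], float]] = None,
    seed: int = 0,
    rules: Optional[BindingRuleSet] = None,
    max_mismatches: int = 9,
    flank_range: tuple[int, int] = (15, 60),
    reference_alignment: Optional[ReferenceAlignment] = None,
    verify: bool = True,
) -> tuple[dict[str, str], dict]:
    """Proteome of domain-bearing members plus verified decoys.

    The default mismatch spectrum cycles 0..4 (family members resemble
    the consensus closely); the default binding mix uses the category
    proportions observed in the tomato family (45% G-box, 16% other
    E-box, 8% non-E-box, 31% non-binding). Decoys are random sequences
    re-verified to contain no window within ``max_mismatches`` of the
    consensus. When ``verify`` is on, each member is additionally
    checked against the profile built from the same-seed reference
    alignment: the best local hit must recover the planted span,
    mismatch count and category exactly, and members failing the check
    are redrawn (the planted parameters never change).
    """
    consensus = consensus or ConservedPositionSet.default()
    rules = rules or BindingRuleSet()
    template = consensus_template(consensus, seed=seed)
    dominants = _column_dominants(consensus, seed)
    profile = min_score = None
    if verify:
        from .family_filter import passes_family_filter
        from .profile_search import (
            build_profile,
            canonical_map,
            default_min_score,
            locate_domain,
        )

        aln = reference_alignment or generate_reference_alignment(
            consensus=consensus, seed=seed
        )
        profile = build_profile(aln)
        min_score = default_min_score(profile, aln)
    if mismatch_spectrum is None:
        mismatch_spectrum = (0, 1, 2, 3, 4)
    if binding_mix is None:
        binding_mix = {
            BindingCategory.G_BOX: 0.45,
            BindingCategory.E_BOX_NON_G: 0.16,
            BindingCategory.NON_E_BOX: 0.08,
            BindingCategory.NON_DNA_BINDING: 0.31,
        }
    mix = {
        (BindingCategory(k) if isinstance(k, str) else k): v
        for k, v in binding_mix.items()
    }
    total = sum(mix.values())
    if not math.isclose(total, 1.0, rel_tol=1e-6) and total > 1.5:
        # counts were passed instead of proportions
        mix = {k: v / total for k, v in mix.items()}
    elif not math.isclose(total, 1.0, rel_tol=1e-6):
        raise GenerationError(f"binding mix sums to {total}, expected 1 or counts")
    # largest-remainder apportionment of members to categories
    raw = {k: n_members * v for k, v in mix.items()}
    counts = {k: int(v) for k, v in raw.items()}
    short = n_members - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    categories: list[BindingCategory] = []
    for cat in BindingCategory:
        categories.extend([cat] * counts.get(cat, 0))

    records: dict[str, str] = {}
    truth_proteins: dict[str, dict] = {}
    for i in range(n_members):
        rng = _rng(seed, "member", i)
        category = categories[i]
        n_mm = int(mismatch_spectrum[i % len(mismatch_spectrum)])
        for _attempt in range(60):
            domain = _build_member_domain(
                rng, template, consensus, category, n_mm, rules, dominants
            )
            call = classify_binding(AlignedDomain.from_sequence(domain), rules)
            realized_mm = sum(
                1
                for e in consensus.entries
                if domain[e.column - 1] not in e.allowed
            )
            if call.category is not category or realized_mm != n_mm:
                raise GenerationError(
                    f"member {i}: realized ({call.category.value}, "
                    f"{realized_mm}) != planted ({category.value}, {n_mm})"
                )
            left = _random_protein(rng, int(rng.integers(*flank_range)))
            right = _random_protein(rng, int(rng.integers(*flank_range)))
            record = left + domain + right
            if not verify:
                break
            hit = locate_domain(record, profile, min_score=min_score)
            if hit is None or (hit.start, hit.end) != (
                len(left) + 1,
                len(left) + len(domain),
            ):
                continue
            mapped = canonical_map(hit, profile)
            report = passes_family_filter(mapped, consensus)
            recovered = classify_binding(mapped, rules)
            if (
                report.mismatch_count == n_mm
                and recovered.category is category
            ):
                break
        else:
            raise GenerationError(
                f"member {i}: planted ({category.value}, {n_mm}) not "
                "recoverable by the profile search after 60 draws"
            )
        name = f"FAM{i + 1:04d}"
        records[name] = record
        truth_proteins[name] = {
            "role": "member",
            "domain_start": len(left) + 1,
            "domain_end": len(left) + len(domain),
            "domain_seq": domain,
            "mismatch_count": n_mm,
            "category": category.value,
            "basic_count": call.basic_count,
        }
    for i in range(n_decoys):
        rng = _rng(seed, "decoy", i)
        length = int(rng.integers(120, 260))
        for _ in range(200):
            seq = _random_protein(rng, length)
            if _window_min_mismatches(seq, consensus, DOMAIN_LENGTH) > max_mismatches:
                break
        else:
            raise GenerationError(f"decoy {i}: could not avoid consensus windows")
        name = f"DEC{i + 1:04d}"
        records[name] = seq
        truth_proteins[name] = {"role": "decoy"}
    truth = {
        "seed": seed,
        "template": template,
        "n_members": n_members,
        "n_decoys": n_decoys,
        "proteins": truth_proteins,
    }
    return records, truth


# ---------------------------------------------------------------------------
# Gene models with planted intron patterns


def generate_gene_models(
    patterns: Mapping[str, int],
    ref: Optional[IntronReference] = None,
    seed: int = 0,
    catalogue: Optional[PatternCatalogue] = None,
    protein_length: int = 130,
    domain_span: tuple[int, int] = (35, 95),
) -> tuple[dict[str, str], list[GeneModel], dict]:
    """Gene models realizing the requested intron-pattern labels.

    Each gene sits on its own synthetic contig, strand drawn at random;
    returns (genome, models, truth).
    """
    ref = ref or IntronReference()
    catalogue = catalogue or PatternCatalogue.default()
    dstart, dend = domain_span
    domain_codons = dend - dstart + 1
    domain_cds_start = (dstart - 1) * 3
    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    truth_genes: dict[str, dict] = {}
    index = 0
    for label in sorted(patterns):
        matched, extra = catalogue.key_for_label(label)
        for _ in range(patterns[label]):
            rng = _rng(seed, "gene", index)
            gene_id = f"GENE{index + 1:04d}"
            positions = [ref.positions[j - 1] for j in sorted(matched)]
            # extra introns at codons clear of every reference position
            taken = {c for c, _ in positions}
            candidates = [
                c
                for c in range(2, domain_codons - 1)
                if all(abs(c - rc) > ref.tolerance for rc, _ in ref.positions)
                and c not in taken
            ]
            picks = rng.choice(candidates, size=extra, replace=False)
            for c in sorted(int(x) for x in picks):
                positions.append((c, int(rng.integers(0, 3))))
            positions.sort()
            cds = _random_dna(rng, protein_length * 3)
            offsets = [domain_cds_start + 3 * c + p for c, p in positions]
            pieces = []
            prev = 0
            for off in offsets:
                pieces.append(("exon", cds[prev:off]))
                intron = "GT" + _random_dna(rng, int(rng.integers(40, 120))) + "AG"
                pieces.append(("intron", intron))
                prev = off
            pieces.append(("exon", cds[prev:]))
            region = "".join(p for _, p in pieces)
            strand = "+" if rng.random() < 0.5 else "-"
            flank_l = _random_dna(rng, int(rng.integers(100, 300)))
            flank_r = _random_dna(rng, int(rng.integers(100, 300)))
            chrom_name = f"ctg_{gene_id}"
            # exon offsets within the transcript region (1-based)
            segments = []
            pos = 1
            for kind, piece in pieces:
                if kind == "exon" and piece:
                    segments.append((pos, pos + len(piece) - 1))
                pos += len(piece)
            p0 = len(flank_l) + 1
            n_region = len(region)
            if strand == "+":
                genome[chrom_name] = flank_l + region + flank_r
                genomic = [(p0 + a - 1, p0 + b - 1) for a, b in segments]
            else:
                from .alphabet import revcomp

                genome[chrom_name] = flank_l + revcomp(region) + flank_r
                genomic = [
                    (p0 + n_region - b - 1 + 1, p0 + n_region - a - 1 + 1)
                    for a, b in segments
                ]
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    chromosome=chrom_name,
                    strand=strand,
                    cds_segments=tuple(genomic),
                    domain_span=domain_span,
                )
            )
            truth_genes[gene_id] = {
                "pattern": label,
                "strand": strand,
                "intron_positions": [list(p) for p in positions],
            }
            index += 1
    truth = {"seed": seed, "genes": truth_genes, "domain_span": list(domain_span)}
    return genome, models, truth


# ---------------------------------------------------------------------------
# Expression matrices

DEFAULT_TISSUES = ("Root", "Leaf", "Flower", "Bud") + DEFAULT_FRUIT_STAGES


def generate_expression(
    n_genes: int,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    planted_specific: Union[int, Mapping[str, str]] = 0,
    planted_trends: Union[int, Mapping[str, str]] = 0,
    noise_sd_fraction: float = 0.0,
    seed: int = 0,
    fruit_stages: Sequence[str] = DEFAULT_FRUIT_STAGES,
    cfg: Optional[ExpressionConfig] = None,
) -> tuple[ExpressionMatrix, dict]:
    """RPKM matrix with planted tissue-specific and fruit-trend genes.

    Background genes are low (below the expressed threshold) and flat
    (within-gene fold < 1.3), so with zero noise the planted call sets
    are recovered exactly. Specific genes clear the fold rule with a
    >= 20% margin; trend genes are geometric series over the fruit
    stages (stage ratio 1.7, so they never double between adjacent
    stages and cannot masquerade as tissue-specific). Noise multiplies
    every value by exp(sigma * N(0,1)).
    """
    cfg = cfg or ExpressionConfig()
    tissues = list(tissues)
    stages = [t for t in fruit_stages if t in tissues]
    gene_names = [f"G{i + 1:04d}" for i in range(n_genes)]
    non_fruit = [t for t in tissues if t not in stages]
    n_specific = (
        planted_specific
        if isinstance(planted_specific, int)
        else len(planted_specific)
    )
    n_trends = (
        planted_trends if isinstance(planted_trends, int) else len(planted_trends)
    )
    if n_specific + n_trends > n_genes:
        raise GenerationError("more planted genes than n_genes")
    if isinstance(planted_specific, int):
        pool = non_fruit or tissues
        planted_specific = {
            gene_names[i]: pool[i % len(pool)] for i in range(planted_specific)
        }
    if isinstance(planted_trends, int):
        offset = len(planted_specific)
        planted_trends = {
            gene_names[offset + i]: ("increasing" if i % 2 == 0 else "decreasing")
            for i in range(planted_trends)
        }
    overlap = set(planted_specific) & set(planted_trends)
    if overlap:
        raise GenerationError(f"genes planted twice: {sorted(overlap)}")
    if len(planted_specific) + len(planted_trends) > n_genes:
        raise GenerationError("more planted genes than n_genes")
    if planted_trends and len(stages) < 3:
        raise GenerationError("trend genes need >= 3 fruit stages among tissues")

    ratio = 1.7
    values = np.zeros((n_genes, len(tissues)))
    t_index = {t: j for j, t in enumerate(tissues)}
    for i, gene in enumerate(gene_names):
        rng = _rng(seed, "expression", i)
        if gene in planted_specific:
            target = planted_specific[gene]
            if target not in t_index:
                raise GenerationError(f"{gene}: unknown tissue {target!r}")
            base = rng.uniform(0.4, 1.0)
            row = base * rng.uniform(0.9, 1.1, size=len(tissues))
            peak = max(
                cfg.specificity_fold * 1.2 * row.max() * 1.1,
                cfg.expressed_threshold * 1.5,
            ) * rng.uniform(1.0, 1.5)
            row[t_index[target]] = peak
        elif gene in planted_trends:
            direction = planted_trends[gene]
            if direction not in ("increasing", "decreasing"):
                raise GenerationError(f"{gene}: bad trend {direction!r}")
            start = rng.uniform(1.6, 2.4)
            series = start * ratio ** np.arange(len(stages))
            if direction == "decreasing":
                series = series[::-1]
            base = rng.uniform(0.4, 1.0)
            row = base * rng.uniform(0.9, 1.1, size=len(tissues))
            for s, v in zip(stages, series):
                row[t_index[s]] = v
        else:
            base = rng.uniform(0.2, 1.0)
            row = base * rng.uniform(0.9, 1.1, size=len(tissues))
        if noise_sd_fraction > 0:
            row = row * np.exp(
                noise_sd_fraction * rng.standard_normal(len(tissues))
            )
        values[i] = row
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_names, columns=tissues),
        fruit_stages=tuple(stages),
    )
    truth = {
        "seed": seed,
        "specific": dict(planted_specific),
        "trends": dict(planted_trends),
        "background": [
            g
            for g in gene_names
            if g not in planted_specific and g not in planted_trends
        ],
        "noise_sd_fraction": noise_sd_fraction,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# Duplicate pairs


def generate_duplicates(
    pairs: Sequence[tuple[float, float]],
    seed: int = 0,
    base_length: int = 150,
    cfg: Optional[DuplicationConfig] = None,
    tolerance: float = 2.0,
    max_attempts: int = 40,
) -> tuple[dict[str, str], dict]:
    """Protein pairs realized at target (identity%, coverage%).

    Realization is verified with the duplication module itself. For
    targets in the alignable regime (identity at or above the low-
    stringency threshold) the measured identity and coverage must land
    within ``tolerance`` points of the targets. Below that regime
    substitution mutagenesis cannot pin the aligner's statistics to a
    point value, so the pair is built from an unrelated sequence and
    verified to classify as "none" with identity at least 5 points
    under the low threshold.
    """
    cfg = cfg or DuplicationConfig()
    records: dict[str, str] = {}
    truth_pairs = []
    from .duplication import _classify

    for i, (target_id, target_cov) in enumerate(pairs):
        rng = _rng(seed, "duplicate", i)
        m = max(2, round(target_cov / 100.0 * base_length))
        n_mut = round((1.0 - target_id / 100.0) * m)
        alignable = target_id >= cfg.low.min_identity
        realized = None
        for _ in range(max_attempts):
            a = _random_protein(rng, base_length)
            if alignable:
                b = list(a[:m])
                sites = rng.choice(m, size=min(n_mut, m), replace=False)
                for s in sites:
                    choices = [x for x in AMINO_ACIDS if x != b[s]]
                    b[s] = rng.choice(choices)
                b = "".join(b)
            else:
                b = _random_protein(rng, m)
            stats = pairwise_stats(a, b, cfg)
            if alignable:
                if (
                    abs(stats.identity - target_id) <= tolerance
                    and abs(stats.coverage - target_cov) <= tolerance
                ):
                    realized = (a, b, stats)
                    break
                # feedback: nudge the mutation count toward the target
                n_mut = max(
                    0, n_mut + round((stats.identity - target_id) / 100.0 * m)
                )
            elif (
                stats.dup_class == "none"
                and stats.identity <= cfg.low.min_identity - 5.0
            ):
                realized = (a, b, stats)
                break
        if realized is None:
            raise GenerationError(
                f"pair {i}: could not realize identity {target_id}, "
                f"coverage {target_cov} within +/-{tolerance} points"
            )
        a, b, stats = realized
        id_a, id_b = f"DUPA{i + 1:04d}", f"DUPB{i + 1:04d}"
        records[id_a], records[id_b] = a, b
        truth_pairs.append(
            {
                "id_a": id_a,
                "id_b": id_b,
                "target_identity": target_id,
                "target_coverage": target_cov,
                "realized_identity": stats.identity,
                "realized_coverage": stats.coverage,
                "class": _classify(target_id, target_cov, cfg),
            }
        )
    return records, {"seed": seed, "pairs": truth_pairs}


# ---------------------------------------------------------------------------
# Chromosomal gene order with planted tandem arrays


def generate_tag_loci(
    cluster_sizes: Sequence[int],
    n_scattered: int = 5,
    max_spacers: int = 1,
    seed: int = 0,
    chromosome: str = "chr01",
) -> tuple[list[GeneLocus], dict]:
    """A chromosome gene order with planted tandem clusters.

    Family members inside a cluster are separated by 0..max_spacers
    non-family genes; clusters and scattered family genes are isolated
    from each other by more than ``max_spacers`` spacers.
    """
    rng = _rng(seed, "loci", 0)
    loci: list[GeneLocus] = []
    rank = 0
    position = 1
    fam_idx = 0
    bg_idx = 0
    truth_clusters: list[list[str]] = []

    def add(family: bool) -> str:
        nonlocal rank, position, fam_idx, bg_idx
        rank += 1
        length = int(rng.integers(500, 3000))
        start = position
        end = start + length
        position = end + int(rng.integers(200, 1500))
        if family:
            fam_idx += 1
            gid = f"TAGFAM{fam_idx:03d}"
        else:
            bg_idx += 1
            gid = f"BG{bg_idx:04d}"
        loci.append(
            GeneLocus(
                gene_id=gid,
                chromosome=chromosome,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                rank=rank,
                family_member=family,
            )
        )
        return gid

    def isolate() -> None:
        for _ in range(max_spacers + 1 + int(rng.integers(1, 4))):
            add(False)

    isolate()
    for size in cluster_sizes:
        if size < 2:
            raise GenerationError("tandem clusters need >= 2 members")
        cluster = [add(True)]
        for _ in range(size - 1):
            for _ in range(int(rng.integers(0, max_spacers + 1))):
                add(False)
            cluster.append(add(True))
        truth_clusters.append(cluster)
        isolate()
    for _ in range(n_scattered):
        add(True)
        isolate()
    truth = {
        "seed": seed,
        "clusters": truth_clusters,
        "max_spacers": max_spacers,
        "scattered": [l.gene_id for l in loci if l.family_member][
            sum(cluster_sizes) :
        ],
    }
    return loci, truth


# ---------------------------------------------------------------------------
# Promoters with planted motifs


def generate_promoters(
    placements: Mapping[str, Sequence[tuple[str, int, str]]],
    seed: int = 0,
    length: int = 1500,
    library: Optional[MotifLibrary] = None,
    max_cleanup_rounds: int = 500,
) -> tuple[dict[str, str], dict]:
    """Promoter windows with planted cis-elements and nothing else.

    ``placements[promoter] = [(motif_name, offset, strand), ...]`` with
    offsets negative (-1 = base just upstream of the TSS). Degenerate
    codes are realized randomly; the background is mutated until a scan
    finds no hit outside the planted intervals, so recovery is exact by
    construction (note a planted motif may legitimately imply a hit of
    a contained motif, e.g. an I-box contains the I-box core; such hits
    fall inside planted intervals and are kept).
    """
    library = library or MotifLibrary.default()
    genome: dict[str, str] = {}
    truth_promoters: dict[str, list] = {}
    from .alphabet import IUPAC_DNA, revcomp

    for p_idx, (name, placed) in enumerate(sorted(placements.items())):
        rng = _rng(seed, "promoter", p_idx)
        seq = list(_random_dna(rng, length))
        intervals = []
        for motif_name, offset, strand in placed:
            if motif_name not in library.motifs:
                raise GenerationError(f"unknown motif {motif_name!r}")
            motif = library.motifs[motif_name]
            width = len(motif)
            start = length + 1 + offset  # 1-based 5'-most base
            if not 1 <= start <= length - width + 1:
                raise GenerationError(
                    f"{name}: motif {motif_name} at offset {offset} "
                    f"does not fit the {length}-bp window"
                )
            realized = "".join(rng.choice(list(IUPAC_DNA[c])) for c in motif)
            if strand == "-":
                realized = revcomp(realized)
            for inter_s, inter_e in intervals:
                if not (start + width - 1 < inter_s or start > inter_e):
                    raise GenerationError(
                        f"{name}: overlapping placements at offset {offset}"
                    )
            seq[start - 1 : start - 1 + width] = list(realized)
            intervals.append((start, start + width - 1))
        # scrub accidental matches outside the planted intervals
        for _ in range(max_cleanup_rounds):
            hits = scan_motifs("".join(seq), library)
            stray = [
                h
                for h in hits
                if not any(
                    s <= h.start and h.start + len(library.motifs[h.motif]) - 1 <= e
                    for s, e in intervals
                )
            ]
            if not stray:
                break
            h = stray[0]
            width = len(library.motifs[h.motif])
            editable = [
                j
                for j in range(h.start, h.start + width)
                if not any(s <= j <= e for s, e in intervals)
            ]
            if not editable:
                raise GenerationError(
                    f"{name}: accidental {h.motif} hit overlaps planted motifs"
                )
            j = int(rng.choice(editable))
            current = seq[j - 1]
            seq[j - 1] = rng.choice([b for b in DNA if b != current])
        else:
            raise GenerationError(f"{name}: background cleanup did not converge")
        genome[name] = "".join(seq)
        truth_promoters[name] = [
            {"motif": m, "offset": o, "strand": s} for m, o, s in placed
        ]
    return genome, {"seed": seed, "length": length, "promoters": truth_promoters}


# ---------------------------------------------------------------------------
# qPCR Ct tables


def generate_qpcr(
    fold_changes: Mapping[str, Mapping[str, float]],
    calibrator_condition: str,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Ct tables realizing planted relative-expression fold changes.

    ``fold_changes[gene][condition]`` is the planted 2^-ddCt value
    relative to ``calibrator_condition`` (whose own value must be 1 or
    absent).
    """
    rows = []
    truth: dict[str, dict[str, float]] = {}
    for g_idx, (gene, conditions) in enumerate(sorted(fold_changes.items())):
        rng = _rng(seed, "qpcr", g_idx)
        ct_ref = float(rng.uniform(16.0, 20.0))
        d0 = float(rng.uniform(2.0, 6.0))  # calibrator delta-Ct
        rows.append(
            {
                "gene": gene,
                "condition": calibrator_condition,
                "ct_target": ct_ref + d0,
                "ct_reference": ct_ref,
                "calibrator": 1,
            }
        )
        truth[gene] = {calibrator_condition: 1.0}
        for condition, fold in sorted(conditions.items()):
            if condition == calibrator_condition:
                if not math.isclose(fold, 1.0):
                    raise GenerationError(
                        f"{gene}: calibrator fold must be 1, got {fold}"
                    )
                continue
            if fold <= 0:
                raise GenerationError(f"{gene}/{condition}: fold must be > 0")
            ct_ref_c = float(rng.uniform(16.0, 20.0))
            delta = d0 - math.log2(fold)
            rows.append(
                {
                    "gene": gene,
                    "condition": condition,
                    "ct_target": ct_ref_c + delta,
                    "ct_reference": ct_ref_c,
                    "calibrator": 0,
                }
            )
            truth[gene][condition] = fold
    table = pd.DataFrame(
        rows, columns=["gene", "condition", "ct_target", "ct_reference", "calibrator"]
    )
    return table, {"seed": seed, "calibrator": calibrator_condition, "folds": truth}


# ---------------------------------------------------------------------------
# Fixture bundles


def generate_bundle(
    outdir,
    seed: int = 0,
    n_members: int = 12,
    n_decoys: int = 6,
    patterns: Optional[Mapping[str, int]] = None,
    n_expression_genes: int = 40,
    n_specific: int = 6,
    n_trends: int = 6,
    noise_sd_fraction: float = 0.0,
) -> dict:
    """Write a complete fixture bundle (FASTA/GFF3/TSV + truth JSON).

    The bundle feeds every pipeline stage: reference alignment,
    proteome with members and decoys, gene models with planted intron
    patterns on their own contigs, an RPKM matrix, promoters with
    planted motifs, and a qPCR Ct table. Returns the merged truth.
    """
    from pathlib import Path

    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    consensus = ConservedPositionSet.default()
    aln = generate_reference_alignment(consensus=consensus, seed=seed)
    _io.write_fasta(dict(aln.records), outdir / "reference_alignment.fasta")

    proteome, family_truth = generate_family(
        n_members, n_decoys, consensus=consensus, seed=seed
    )
    _io.write_fasta(proteome, outdir / "proteome.fasta")

    patterns = dict(patterns or {"I": 2, "XI": 2, "V": 2, "IX": 2})
    genome, models, gene_truth = generate_gene_models(patterns, seed=seed)
    _io.write_fasta(genome, outdir / "genome.fasta")
    _io.write_gff3(
        models, outdir / "models.gff3", {c: len(s) for c, s in genome.items()}
    )
    spans = pd.DataFrame(
        {
            "gene_id": m.gene_id,
            "start": m.domain_span[0],
            "end": m.domain_span[1],
        }
        for m in models
    )
    _io.write_report(spans, outdir / "domain_spans.tsv")

    matrix, expr_truth = generate_expression(
        n_expression_genes,
        planted_specific=n_specific,
        planted_trends=n_trends,
        noise_sd_fraction=noise_sd_fraction,
        seed=seed,
    )
    matrix.to_tsv(outdir / "expression.tsv")

    placements = {
        "PROM0001": [("ERELEE4", -1200, "+"), ("I-box", -420, "-")],
        "PROM0002": [("TGTCACA-element", -700, "+"), ("I-box-core", -77, "+")],
        "PROM0003": [("I-box-like", -999, "-")],
    }
    promoters, prom_truth = generate_promoters(placements, seed=seed)
    _io.write_fasta(promoters, outdir / "promoters.fasta")

    qpcr, qpcr_truth = generate_qpcr(
        {"QG1": {"treated": 4.0, "control": 1.0}, "QG2": {"treated": 0.25}},
        calibrator_condition="control",
        seed=seed,
    )
    qpcr.to_csv(outdir / "qpcr.tsv", sep="\t", index=False)

    truth = {
        "seed": seed,
        "family": family_truth,
        "genes": gene_truth,
        "expression": expr_truth,
        "promoters": prom_truth,
        "qpcr": qpcr_truth,
    }
    _io.write_truth(truth, outdir / "truth.json")
    return truth
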
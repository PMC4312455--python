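"""End-to-end orchestration of the characterization stages.

Stages run in dependency order: profile search over the proteome,
family filtering, binding classification, conservation statistics,
duplication and tandem-array analysis, intron patterns, expression
rules, promoter scanning and qPCR quantification. Stages whose inputs
are not configured are skipped with a logged notice; every threshold
that reaches a report comes from the RunConfig object.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io
from .binding import BindingRuleSet, classify_binding, summarize_categories
from .conservation import (
    column_frequencies,
    conserved_positions,
    export_logo_table,
    percent_report,
)
from .duplication import (
    DuplicationConfig,
    classify_family_duplications,
    duplication_counts,
    find_tags,
    rank_loci,
    GeneLocus,
)
from .errors import InputError
from .expression import (
    ExpressionConfig,
    ExpressionMatrix,
    expressed_genes,
    fruit_trend_genes,
    read_qpcr_table,
    relative_expression_table,
    tissue_specific_genes,
)
from .family_filter import ConservedPositionSet, FamilyFilterConfig, passes_family_filter
from .gene_structure import (
    IntronReference,
    PatternCatalogue,
    classify_intron_pattern,
    domain_intron_positions,
)
from .profile_search import (
    build_profile,
    canonical_map,
    default_min_score,
    locate_domain,
)
from .promoters import MotifLibrary, extract_promoter, scan_motifs

log = logging.getLogger("bhlhkit")


@dataclass
class RunConfig:
    """All inputs and thresholds of a full characterization run."""

    reference_alignment: Optional[str] = None
    proteome: Optional[str] = None
    genome: Optional[str] = None
    gff3: Optional[str] = None
    expression_tsv: Optional[str] = None
    promoter_fasta: Optional[str] = None
    qpcr_tsv: Optional[str] = None
    domain_spans_tsv: Optional[str] = None  # gene_id, start, end (protein coords)
    output_dir: str = "bhlhkit_out"
    seed: int = 0

    pseudocount_weight: float = 1.0
    gap_open: float = 4.0
    gap_extend: float = 0.5
    min_score_fraction: float = 0.8
    filter_cfg: FamilyFilterConfig = field(default_factory=FamilyFilterConfig)
    binding_rules: BindingRuleSet = field(default_factory=BindingRuleSet)
    duplication_cfg: DuplicationConfig = field(default_factory=DuplicationConfig)
    max_spacers: int = 1
    intron_reference: IntronReference = field(default_factory=IntronReference)
    expression_cfg: ExpressionConfig = field(default_factory=ExpressionConfig)
    promoter_length: int = 1500

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    hits: Optional[pd.DataFrame] = None
    family: Optional[pd.DataFrame] = None
    binding: Optional[pd.DataFrame] = None
    binding_summary: Optional[pd.DataFrame] = None
    conservation: Optional[pd.DataFrame] = None
    conserved_columns: Optional[list[int]] = None
    duplication_pairs: Optional[pd.DataFrame] = None
    duplication_classes: Optional[pd.DataFrame] = None
    tags: Optional[pd.DataFrame] = None
    introns: Optional[pd.DataFrame] = None
    expression_calls: Optional[pd.DataFrame] = None
    promoter_hits: Optional[pd.DataFrame] = None
    qpcr: Optional[pd.DataFrame] = None
    domains: dict = field(default_factory=dict)


def _column_map_cigar(column_map) -> str:
    parts = []
    for pos in column_map:
        parts.append("-" if pos is None else str(pos))
    return ",".join(parts)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute every configured stage; write one TSV per stage."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = cfg.as_dict()
    cfg_dict.pop("output_dir")  # hash covers analytic settings, not paths
    result = PipelineResult()

    if not (cfg.reference_alignment and cfg.proteome):
        raise InputError("a run needs at least reference_alignment and proteome")

    aln = io.read_reference_alignment(cfg.reference_alignment)
    profile = build_profile(
        aln,
        pseudocount_weight=cfg.pseudocount_weight,
        gap_open=cfg.gap_open,
        gap_extend=cfg.gap_extend,
    )
    min_score = default_min_score(profile, aln, cfg.min_score_fraction)
    log.info(
        "profile: %d columns, min_score %.2f bits (fraction %.2f)",
        profile.n_columns,
        min_score,
        cfg.min_score_fraction,
    )

    proteome = io.read_fasta(cfg.proteome)
    if not proteome:
        raise InputError("no sequences in proteome")
    hit_rows = []
    domains = {}
    consensus = ConservedPositionSet.default()
    family_rows = []
    binding_calls = []
    member_domains = []
    for pid, seq in proteome.items():
        hit = locate_domain(seq, profile, min_score=min_score, protein_id=pid)
        if hit is None:
            hit_rows.append(
                {"protein_id": pid, "start": 0, "end": 0, "score_bits": float("nan"),
                 "column_map": ""}
            )
            family_rows.append(
                {"protein_id": pid, "mismatch_count": -1, "pass": False,
                 "reason": "no domain hit", "failing_positions": ""}
            )
            continue
        hit_rows.append(
            {
                "protein_id": pid,
                "start": hit.start,
                "end": hit.end,
                "score_bits": round(hit.score, 4),
                "column_map": _column_map_cigar(hit.column_map),
            }
        )
        domain = canonical_map(hit, profile)
        domains[pid] = (hit, domain)
        report = passes_family_filter(domain, consensus, cfg.filter_cfg)
        family_rows.append(
            {
                "protein_id": pid,
                "mismatch_count": report.mismatch_count,
                "pass": report.passed,
                "reason": report.reason,
                "failing_positions": ",".join(map(str, report.failing_positions)),
            }
        )
        if report.passed:
            member_domains.append(domain)
            binding_calls.append(classify_binding(domain, cfg.binding_rules))

    result.hits = pd.DataFrame(hit_rows)
    result.family = pd.DataFrame(family_rows)
    result.domains = domains
    io.write_report(result.hits, out / "domain_hits.tsv", cfg_dict)
    io.write_report(result.family, out / "family_filter.tsv", cfg_dict)

    if binding_calls:
        result.binding = pd.DataFrame(
            {
                "protein_id": c.protein_id,
                "basic_count": c.basic_count,
                "ebox": c.ebox_ok,
                "gbox": c.gbox_ok,
                "category": c.category.value,
            }
            for c in binding_calls
        )
        result.binding_summary = summarize_categories(binding_calls)
        io.write_report(result.binding, out / "binding.tsv", cfg_dict)
        io.write_report(
            result.binding_summary,
            out / "binding_summary.tsv",
            cfg_dict,
            index=True,
            index_label="category",
        )

        profiles = column_frequencies(member_domains)
        result.conservation = export_logo_table(profiles)
        result.conserved_columns = conserved_positions(profiles)
        io.write_report(result.conservation, out / "conservation.tsv", cfg_dict)
        io.write_report(
            percent_report(profiles), out / "conservation_summary.tsv", cfg_dict
        )

        member_ids = [d.protein_id for d in member_domains]
        if len(member_ids) >= 2:
            gene_class, pair_stats = classify_family_duplications(
                {g: proteome[g] for g in member_ids}, cfg.duplication_cfg
            )
            result.duplication_pairs = pd.DataFrame(
                {
                    "id_a": p.id_a,
                    "id_b": p.id_b,
                    "identity": round(p.identity, 2),
                    "coverage": round(p.coverage, 2),
                    "class": p.dup_class,
                }
                for p in pair_stats
            )
            counts = duplication_counts(gene_class)
            result.duplication_classes = pd.DataFrame(
                [{"gene_id": g, "class": c} for g, c in sorted(gene_class.items())]
            )
            log.info("duplication counts: %s", counts)
            io.write_report(
                result.duplication_pairs, out / "duplication_pairs.tsv", cfg_dict
            )
            io.write_report(
                result.duplication_classes, out / "duplication_classes.tsv", cfg_dict
            )
    else:
        log.info("no proteins passed the family filter")

    genome = io.read_fasta(cfg.genome) if cfg.genome else None

    if cfg.gff3:
        if cfg.domain_spans_tsv:
            spans_df = io.read_report(cfg.domain_spans_tsv)
            domain_spans = {
                str(r.gene_id): (int(r.start), int(r.end))
                for r in spans_df.itertuples()
            }
        else:
            domain_spans = {pid: _protein_span(domains[pid][0]) for pid in domains}
        models = io.read_gff3_models(cfg.gff3, domain_spans)
        intron_rows = []
        catalogue = PatternCatalogue.default()
        loci = []
        for model in models:
            positions = domain_intron_positions(model)
            label = classify_intron_pattern(
                positions, cfg.intron_reference, catalogue
            )
            intron_rows.append(
                {
                    "gene_id": model.gene_id,
                    "introns": ";".join(f"{c}.{p}" for c, p in positions),
                    "pattern": label,
                }
            )
            start = min(a for a, _ in model.cds_segments)
            end = max(b for _, b in model.cds_segments)
            loci.append(
                GeneLocus(
                    gene_id=model.gene_id,
                    chromosome=model.chromosome,
                    start=start,
                    end=end,
                    strand=model.strand,
                    rank=0,
                    family_member=True,
                )
            )
        result.introns = pd.DataFrame(intron_rows)
        io.write_report(result.introns, out / "intron_patterns.tsv", cfg_dict)

        ranked = rank_loci(loci)
        clusters = find_tags(ranked, cfg.max_spacers)
        result.tags = pd.DataFrame(
            {
                "cluster": i + 1,
                "chromosome": cluster[0].chromosome,
                "genes": ",".join(l.gene_id for l in cluster),
            }
            for i, cluster in enumerate(clusters)
        )
        io.write_report(result.tags, out / "tandem_arrays.tsv", cfg_dict)

        if genome:
            promoter_rows = []
            library = MotifLibrary.default()
            for locus in ranked:
                seq = extract_promoter(genome, locus, cfg.promoter_length)
                for h in scan_motifs(seq, library):
                    promoter_rows.append(
                        {
                            "gene_id": locus.gene_id,
                            "motif": h.motif,
                            "offset": h.offset,
                            "strand": h.strand,
                        }
                    )
            result.promoter_hits = pd.DataFrame(
                promoter_rows, columns=["gene_id", "motif", "offset", "strand"]
            )
            io.write_report(
                result.promoter_hits, out / "promoter_hits.tsv", cfg_dict
            )
    else:
        log.info("no GFF3 configured; skipping intron/TAG/promoter stages")

    if cfg.promoter_fasta:
        promoters = io.read_fasta(cfg.promoter_fasta)
        library = MotifLibrary.default()
        rows = []
        for name, seq in promoters.items():
            for h in scan_motifs(seq, library):
                rows.append(
                    {
                        "gene_id": name,
                        "motif": h.motif,
                        "offset": h.offset,
                        "strand": h.strand,
                    }
                )
        result.promoter_hits = pd.DataFrame(
            rows, columns=["gene_id", "motif", "offset", "strand"]
        )
        io.write_report(result.promoter_hits, out / "promoter_hits.tsv", cfg_dict)

    if cfg.expression_tsv:
        matrix = ExpressionMatrix.from_tsv(cfg.expression_tsv)
        expressed = expressed_genes(matrix, cfg.expression_cfg)
        specific = tissue_specific_genes(matrix, cfg.expression_cfg)
        trends = (
            fruit_trend_genes(matrix, cfg.expression_cfg)
            if len(matrix.fruit_stages) >= 3
            else {}
        )
        result.expression_calls = pd.DataFrame(
            {
                "gene_id": g,
                "expressed": g in expressed,
                "specific_tissue": specific.get(g, ""),
                "fruit_trend": trends.get(g, "none"),
            }
            for g in matrix.genes
        )
        io.write_report(
            result.expression_calls, out / "expression_calls.tsv", cfg_dict
        )
    else:
        log.info("no expression matrix configured; skipping expression stage")

    if cfg.qpcr_tsv:
        samples = read_qpcr_table(cfg.qpcr_tsv)
        result.qpcr = relative_expression_table(samples)
        io.write_report(result.qpcr, out / "qpcr_relative_expression.tsv", cfg_dict)

    return result


def _protein_span(hit) -> tuple[int, int]:
    """Protein-coordinate span of a domain hit (start, end)."""
    return (hit.start, hit.end)
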
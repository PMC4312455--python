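"""File I/O: FASTA, aligned FASTA, the GFF3 subset used here, and TSV
reports with provenance header comments."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .errors import InputError, ModelError
from .gene_structure import GeneModel
from .profile_search import ReferenceAlignment

PathLike = Union[str, Path]


def read_fasta(path: PathLike) -> dict[str, str]:
    """FASTA file -> ordered id -> sequence mapping."""
    records = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise InputError(f"{path}: duplicate sequence id {rec.id!r}")
            records[rec.id] = str(rec.seq).upper()
    except ValueError as exc:
        raise InputError(f"{path}: {exc}") from exc
    if not records:
        raise InputError(f"{path}: no sequences")
    return records


def write_fasta(records: Mapping[str, str], path: PathLike, width: int = 60) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_reference_alignment(path: PathLike) -> ReferenceAlignment:
    """Aligned FASTA (equal-length gapped rows) -> ReferenceAlignment."""
    records = read_fasta(path)
    return ReferenceAlignment.from_records(list(records.items()))


# ---------------------------------------------------------------------------
# GFF3 (gene/mRNA/CDS subset)

def write_gff3(
    models: Sequence[GeneModel],
    path: PathLike,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##sequence-region {name} 1 {length}\n")
        for model in models:
            gstart = min(a for a, _ in model.cds_segments)
            gend = max(b for _, b in model.cds_segments)
            gid = model.gene_id
            fh.write(
                f"{model.chromosome}\tbhlhkit\tgene\t{gstart}\t{gend}\t.\t"
                f"{model.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{model.chromosome}\tbhlhkit\tmRNA\t{gstart}\t{gend}\t.\t"
                f"{model.strand}\t.\tID={gid}.1;Parent={gid}\n"
            )
            for i, (a, b) in enumerate(sorted(model.cds_segments)):
                fh.write(
                    f"{model.chromosome}\tbhlhkit\tCDS\t{a}\t{b}\t.\t"
                    f"{model.strand}\t{'.'}\tID={gid}.1.cds{i};Parent={gid}.1\n"
                )


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if item and "=" in item:
            key, value = item.split("=", 1)
            out[key] = value
    return out


def read_gff3_models(
    path: PathLike, domain_spans: Mapping[str, tuple[int, int]]
) -> list[GeneModel]:
    """Read gene models (gene/mRNA/CDS) and attach protein domain spans.

    ``domain_spans`` maps gene ids to protein-coordinate (start, end);
    genes without a span are skipped. CDS segments are ordered in
    transcript orientation (descending genomic start on minus strand).
    """
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise InputError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            attributes = _parse_attributes(attrs)
            if ftype == "gene":
                gid = attributes.get("ID")
                if gid is None:
                    raise InputError(f"{path}:{lineno}: gene feature lacks ID")
                genes[gid] = {"chrom": chrom, "strand": strand, "cds": []}
            elif ftype == "mRNA":
                parent = attributes.get("Parent")
                mid = attributes.get("ID")
                if parent in genes and mid:
                    mrna_to_gene[mid] = parent
            elif ftype == "CDS":
                parent = attributes.get("Parent", "")
                gid = mrna_to_gene.get(parent, parent)
                if gid in genes:
                    genes[gid]["cds"].append((int(start), int(end)))
    models = []
    for gid, info in genes.items():
        if gid not in domain_spans:
            continue
        if not info["cds"]:
            raise ModelError(f"{path}: gene {gid} has no CDS features")
        segments = sorted(info["cds"], reverse=info["strand"] == "-")
        models.append(
            GeneModel(
                gene_id=gid,
                chromosome=info["chrom"],
                strand=info["strand"],
                cds_segments=tuple(segments),
                domain_span=tuple(domain_spans[gid]),
            )
        )
    return models


# ---------------------------------------------------------------------------
# TSV reports

def config_hash(config: Mapping) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_report(
    df: pd.DataFrame,
    path: PathLike,
    config: Optional[Mapping] = None,
    index: bool = False,
    index_label: Optional[str] = None,
) -> None:
    """Write a TSV with header comments recording tool version and the
    hash of the configuration that produced it."""
    with open(path, "w") as fh:
        fh.write(f"# bhlhkit {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash {config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def read_report(path: PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_truth(truth: Mapping, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path: PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)
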
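"""Residue alphabets shared across modules."""

from __future__ import annotations

from .errors import AlphabetError, ConfigError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

DNA = "ACGT"

#: IUPAC degenerate nucleotide codes -> the set of plain bases each matches.
IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_DNA_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def check_protein(seq: str, *, allow_gap: bool = False) -> str:
    """Validate and upper-case a protein sequence."""
    seq = seq.upper()
    allowed = set(AMINO_ACIDS) | ({GAP} if allow_gap else set())
    bad = set(seq) - allowed
    if bad:
        raise AlphabetError(f"invalid amino-acid characters: {sorted(bad)}")
    return seq


def check_iupac(motif: str) -> str:
    """Validate an IUPAC nucleotide motif string."""
    motif = motif.upper()
    bad = set(motif) - set(IUPAC_DNA)
    if bad:
        raise ConfigError(f"non-IUPAC motif characters: {sorted(bad)}")
    return motif


def revcomp(seq: str) -> str:
    """Reverse complement; accepts IUPAC codes."""
    return seq.upper().translate(_DNA_COMPLEMENT)[::-1]
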
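"""Per-column conservation statistics over a set of aligned domains.

Residue frequencies are computed over non-gap residues; the gap
fraction is reported separately. A column is called conserved when its
consensus ratio (the frequency of the most common residue) is strictly
greater than the threshold, 0.5 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

import pandas as pd

from .errors import ConfigError, InputError
from .family_filter import REGION_SPANS
from .profile_search import AlignedDomain


@dataclass(frozen=True)
class ColumnProfile:
    column: int
    frequencies: dict[str, float]
    gap_fraction: float
    consensus: Optional[str]
    consensus_ratio: float

    @property
    def region(self) -> str:
        for name, (lo, hi) in REGION_SPANS.items():
            if lo <= self.column <= hi:
                return name
        return "flank"


def column_frequencies(domains: Sequence[AlignedDomain]) -> list[ColumnProfile]:
    """Residue frequency profile of every canonical column."""
    if not domains:
        raise InputError("no domains to profile")
    n_cols = domains[0].n_columns
    if any(d.n_columns != n_cols for d in domains):
        raise InputError("domains disagree on canonical column count")
    profiles = []
    n = len(domains)
    for col in range(1, n_cols + 1):
        residues = [d.residue(col) for d in domains]
        present = [r for r in residues if r is not None]
        gap_fraction = (n - len(present)) / n
        freqs: dict[str, float] = {}
        for r in present:
            freqs[r] = freqs.get(r, 0.0) + 1.0
        if present:
            freqs = {r: c / len(present) for r, c in sorted(freqs.items())}
            # alphabetic tie-break keeps the consensus deterministic
            consensus = max(freqs, key=lambda r: (freqs[r], r))
            ratio = freqs[consensus]
        else:
            consensus, ratio = None, 0.0
        profiles.append(
            ColumnProfile(
                column=col,
                frequencies=freqs,
                gap_fraction=gap_fraction,
                consensus=consensus,
                consensus_ratio=ratio,
            )
        )
    return profiles


def conserved_positions(
    profiles: Sequence[ColumnProfile], threshold: float = 0.5
) -> list[int]:
    """Columns whose consensus ratio strictly exceeds ``threshold``."""
    if not profiles:
        raise InputError("no column profiles")
    if not 0.0 < threshold <= 1.0:
        raise ConfigError("threshold must lie in (0, 1]")
    return sorted(p.column for p in profiles if p.consensus_ratio > threshold)


def percent_report(
    profiles: Sequence[ColumnProfile], top: int = 4, min_percent: float = 10.0
) -> pd.DataFrame:
    """Summary rows of the most frequent residues per column.

    Percentages are rounded half-up to integers, the style used for
    consensus-motif frequency tables.
    """
    rows = []
    for p in profiles:
        ranked = sorted(p.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
        shown = [
            f"{r}({int(f * 100 + 0.5)}%)"
            for r, f in ranked[:top]
            if f * 100 >= min_percent
        ]
        rows.append(
            {
                "column": p.column,
                "region": p.region,
                "consensus": p.consensus or "-",
                "consensus_percent": int(p.consensus_ratio * 100 + 0.5),
                "top_residues": ", ".join(shown),
            }
        )
    return pd.DataFrame(rows)


def export_logo_table(profiles: Sequence[ColumnProfile]) -> pd.DataFrame:
    """Long-form column x residue frequency table (logo-ready)."""
    rows = []
    for p in profiles:
        for residue, freq in sorted(p.frequencies.items()):
            rows.append(
                {
                    "column": p.column,
                    "region": p.region,
                    "residue": residue,
                    "frequency": freq,
                    "gap_fraction": p.gap_fraction,
                    "is_consensus": residue == p.consensus,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "column",
            "region",
            "residue",
            "frequency",
            "gap_fraction",
            "is_consensus",
        ],
    )


def write_logo_table(
    profiles: Sequence[ColumnProfile], path: Union[str, Path, TextIO]
) -> None:
    export_logo_table(profiles).to_csv(path, sep="\t", index=False)


def read_logo_table(path: Union[str, Path, TextIO]) -> list[ColumnProfile]:
    """Rebuild column profiles from a logo table written by this module."""
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for col, group in df.groupby("column", sort=True):
        freqs = dict(zip(group["residue"], group["frequency"]))
        consensus = max(freqs, key=lambda r: (freqs[r], r)) if freqs else None
        profiles.append(
            ColumnProfile(
                column=int(col),
                frequencies={r: float(f) for r, f in sorted(freqs.items())},
                gap_fraction=float(group["gap_fraction"].iloc[0]),
                consensus=consensus,
                consensus_ratio=float(freqs[consensus]) if consensus else 0.0,
            )
        )
    return profiles
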
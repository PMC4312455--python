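"""DNA-binding category prediction from the basic region.

The first 17 canonical columns of the domain form the basic region that
contacts DNA. Proteins with more than five basic residues (K/R/H by
default) there are predicted DNA binders; binders carrying Glu-13 and
Arg-16 are E-box binders, and E-box binders additionally carrying
His/Lys-9 and Arg-17 are G-box binders. Everything below six basic
residues is a non-DNA-binding HLH protein.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ConfigError, InputError, MappingError
from .profile_search import AlignedDomain


class BindingCategory(enum.Enum):
    G_BOX = "G_BOX"
    E_BOX_NON_G = "E_BOX_NON_G"
    NON_E_BOX = "NON_E_BOX"
    NON_DNA_BINDING = "NON_DNA_BINDING"

    @property
    def binds_dna(self) -> bool:
        return self is not BindingCategory.NON_DNA_BINDING

    @property
    def binds_ebox(self) -> bool:
        return self in (BindingCategory.G_BOX, BindingCategory.E_BOX_NON_G)


@dataclass(frozen=True)
class BindingRuleSet:
    """Residue predicates over the basic region (canonical columns 1..17)."""

    basic_region_columns: tuple[int, int] = (1, 17)
    basic_residues: frozenset[str] = frozenset("KRH")
    min_basic_count: int = 6
    ebox_predicates: Mapping[int, frozenset[str]] = field(
        default_factory=lambda: {13: frozenset("E"), 16: frozenset("R")}
    )
    gbox_predicates: Mapping[int, frozenset[str]] = field(
        default_factory=lambda: {
            9: frozenset("HK"),
            13: frozenset("E"),
            17: frozenset("R"),
        }
    )

    def __post_init__(self) -> None:
        if self.min_basic_count < 1:
            raise ConfigError("min_basic_count must be >= 1")
        lo, hi = self.basic_region_columns
        for col in list(self.ebox_predicates) + list(self.gbox_predicates):
            if not lo <= col <= hi:
                raise ConfigError(
                    f"predicate column {col} outside basic region {lo}..{hi}"
                )


@dataclass(frozen=True)
class BindingCall:
    protein_id: str
    category: BindingCategory
    basic_count: int
    ebox_ok: bool
    gbox_ok: bool
    predicate_results: tuple[tuple[int, bool], ...] = ()


def _predicates_hold(
    domain: AlignedDomain, predicates: Mapping[int, frozenset[str]]
) -> list[tuple[int, bool]]:
    out = []
    for col in sorted(predicates):
        res = domain.residue(col)
        out.append((col, res is not None and res in predicates[col]))
    return out


def classify_binding(
    domain: AlignedDomain, rules: BindingRuleSet = BindingRuleSet()
) -> BindingCall:
    """Assign one domain its predicted DNA-binding category.

    A gap at a predicate column fails the predicate; gaps contribute
    nothing to the basic-residue count.
    """
    lo, hi = rules.basic_region_columns
    if domain.n_columns < hi:
        raise MappingError(
            f"domain covers {domain.n_columns} columns; basic region needs {hi}"
        )
    basic_count = sum(
        1
        for col in range(lo, hi + 1)
        if (res := domain.residue(col)) is not None and res in rules.basic_residues
    )
    ebox_flags = _predicates_hold(domain, rules.ebox_predicates)
    gbox_flags = _predicates_hold(domain, rules.gbox_predicates)
    ebox_ok = all(ok for _, ok in ebox_flags)
    gbox_ok = all(ok for _, ok in gbox_flags)
    if basic_count < rules.min_basic_count:
        category = BindingCategory.NON_DNA_BINDING
    elif ebox_ok and gbox_ok:
        category = BindingCategory.G_BOX
    elif ebox_ok:
        category = BindingCategory.E_BOX_NON_G
    else:
        category = BindingCategory.NON_E_BOX
    return BindingCall(
        protein_id=domain.protein_id,
        category=category,
        basic_count=basic_count,
        ebox_ok=ebox_ok,
        gbox_ok=gbox_ok,
        predicate_results=tuple(ebox_flags + gbox_flags),
    )


def summarize_categories(
    categories: Sequence[BindingCategory | BindingCall],
) -> pd.DataFrame:
    """Count and percentage table over the four binding categories.

    Returns a DataFrame indexed by category name with ``count`` and
    ``percent`` (of total, 2 decimals) columns, plus derived totals for
    E-box and DNA-binding proteins.
    """
    if len(categories) == 0:
        raise InputError("cannot summarize an empty category list")
    cats = [
        c.category if isinstance(c, BindingCall) else c for c in categories
    ]
    n = len(cats)
    rows = {}
    for cat in BindingCategory:
        count = sum(1 for c in cats if c is cat)
        rows[cat.value] = {"count": count, "percent": round(100.0 * count / n, 2)}
    ebox = rows["G_BOX"]["count"] + rows["E_BOX_NON_G"]["count"]
    binding = ebox + rows["NON_E_BOX"]["count"]
    rows["E_BOX_TOTAL"] = {"count": ebox, "percent": round(100.0 * ebox / n, 2)}
    rows["DNA_BINDING_TOTAL"] = {
        "count": binding,
        "percent": round(100.0 * binding / n, 2),
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def classify_all(
    domains: Iterable[AlignedDomain], rules: Optional[BindingRuleSet] = None
) -> list[BindingCall]:
    rules = rules or BindingRuleSet()
    return [classify_binding(d, rules) for d in domains]
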
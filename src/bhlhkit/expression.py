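"""Expression rules over an RPKM matrix and qPCR quantification.

A gene is expressed when its RPKM strictly exceeds 1.4 in at least one
tissue. It is tissue-specific when one tissue's value strictly exceeds
twice the maximum of all other tissues (and clears the expressed
threshold). Fruit-development trends are called by Spearman rank
correlation of expression against the ordered fruit stages, with a
fold-change floor so that flat-but-ordered noise does not qualify.
Relative qPCR expression uses the 2^-ddCt method against an internal
reference gene and a calibrator condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError, InputError

DEFAULT_FRUIT_STAGES = (
    "Fruit_1cm",
    "Fruit_2cm",
    "Fruit_3cm",
    "Fruit_MG",
    "Fruit_B",
    "Fruit_B+10",
)


@dataclass(frozen=True)
class ExpressionConfig:
    expressed_threshold: float = 1.4
    specificity_fold: float = 2.0
    trend_rho_threshold: float = 0.9
    trend_min_fold: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "expressed_threshold",
            "specificity_fold",
            "trend_rho_threshold",
            "trend_min_fold",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x tissues RPKM values with an ordered fruit-stage subset."""

    values: pd.DataFrame
    fruit_stages: tuple[str, ...] = DEFAULT_FRUIT_STAGES

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise InputError("tissue labels must be unique")
        if (self.values.to_numpy() < 0).any():
            raise DataError("RPKM values must be >= 0")
        missing = [t for t in self.fruit_stages if t not in self.values.columns]
        if missing:
            object.__setattr__(
                self,
                "fruit_stages",
                tuple(t for t in self.fruit_stages if t in self.values.columns),
            )

    @classmethod
    def from_tsv(
        cls,
        path: Union[str, Path],
        fruit_stages: Sequence[str] = DEFAULT_FRUIT_STAGES,
    ) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(values=df, fruit_stages=tuple(fruit_stages))

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)


def expressed_genes(
    m: ExpressionMatrix, cfg: ExpressionConfig = ExpressionConfig()
) -> set[str]:
    """Genes whose RPKM strictly exceeds the threshold somewhere."""
    mask = (m.values > cfg.expressed_threshold).any(axis=1)
    return set(m.values.index[mask])


def tissue_specific_genes(
    m: ExpressionMatrix, cfg: ExpressionConfig = ExpressionConfig()
) -> dict[str, str]:
    """Map each tissue-specific gene to its preferred tissue.

    Gene g is specific to tissue t iff value(g, t) strictly exceeds
    ``specificity_fold`` times the maximum over all other tissues and
    also clears the expressed threshold. At most one tissue qualifies.
    """
    if len(m.tissues) < 2:
        raise ConfigError("tissue specificity needs at least two tissues")
    out: dict[str, str] = {}
    vals = m.values.to_numpy(dtype=float)
    tissues = m.tissues
    for i, gene in enumerate(m.genes):
        row = vals[i]
        j = int(np.argmax(row))
        others = np.delete(row, j)
        if row[j] > cfg.specificity_fold * others.max() and (
            row[j] > cfg.expressed_threshold
        ):
            out[gene] = tissues[j]
    return out


def fruit_trend_genes(
    m: ExpressionMatrix, cfg: ExpressionConfig = ExpressionConfig()
) -> dict[str, str]:
    """Call increasing/decreasing/none over the ordered fruit stages."""
    stages = list(m.fruit_stages)
    if len(stages) < 3:
        raise ConfigError("trend calling needs at least three fruit stages")
    sub = m.values[stages]
    order = np.arange(len(stages))
    out: dict[str, str] = {}
    for gene, row in sub.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.allclose(vals, vals[0]):
            out[gene] = "none"
            continue
        rho = stats.spearmanr(order, vals).statistic
        vmin, vmax = vals.min(), vals.max()
        fold = math.inf if vmin == 0 else vmax / vmin
        if math.isnan(rho) or fold < cfg.trend_min_fold:
            out[gene] = "none"
        elif rho >= cfg.trend_rho_threshold:
            out[gene] = "increasing"
        elif rho <= -cfg.trend_rho_threshold:
            out[gene] = "decreasing"
        else:
            out[gene] = "none"
    return out


@dataclass(frozen=True)
class QpcrSample:
    gene: str
    condition: str
    ct_target: float
    ct_reference: float
    calibrator: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_target) and math.isfinite(self.ct_reference)):
            raise DataError(f"{self.gene}/{self.condition}: Ct values must be finite")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct(test: QpcrSample, calibrator: QpcrSample) -> float:
    """Relative expression 2^-((dCt_test) - (dCt_calibrator))."""
    if test.gene != calibrator.gene:
        raise InputError(
            f"gene mismatch: {test.gene!r} vs calibrator {calibrator.gene!r}"
        )
    return 2.0 ** -(test.delta_ct - calibrator.delta_ct)


def read_qpcr_table(path: Union[str, Path]) -> list[QpcrSample]:
    """Read a qPCR TSV: gene, condition, ct_target, ct_reference, calibrator."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "condition", "ct_target", "ct_reference", "calibrator"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"qPCR table lacks columns: {sorted(missing)}")
    truthy = {"1", "true", "yes"}
    return [
        QpcrSample(
            gene=str(r.gene),
            condition=str(r.condition),
            ct_target=float(r.ct_target),
            ct_reference=float(r.ct_reference),
            calibrator=str(r.calibrator).strip().lower() in truthy,
        )
        for r in df.itertuples()
    ]


def relative_expression_table(samples: Sequence[QpcrSample]) -> pd.DataFrame:
    """2^-ddCt per sample against each gene's calibrator condition."""
    if not samples:
        raise InputError("no qPCR samples")
    calibrators: dict[str, QpcrSample] = {}
    for s in samples:
        if s.calibrator:
            if s.gene in calibrators:
                raise InputError(f"gene {s.gene!r} has multiple calibrators")
            calibrators[s.gene] = s
    rows = []
    for s in samples:
        if s.gene not in calibrators:
            raise InputError(f"gene {s.gene!r} lacks a calibrator sample")
        rows.append(
            {
                "gene": s.gene,
                "condition": s.condition,
                "relative_expression": ddct(s, calibrators[s.gene]),
            }
        )
    return pd.DataFrame(rows)
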
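"""Expression rules and qPCR quantification."""

import random

import numpy as np
import pandas as pd
import pytest

from bhlhkit.errors import ConfigError, DataError, InputError
from bhlhkit.expression import (
    DEFAULT_FRUIT_STAGES,
    ExpressionConfig,
    ExpressionMatrix,
    QpcrSample,
    ddct,
    expressed_genes,
    fruit_trend_genes,
    relative_expression_table,
    tissue_specific_genes,
)
from bhlhkit.synthetic import generate_expression

from oracles import ddct_formula


def matrix(rows: dict, tissues, stages=()):
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(tissues))
    return ExpressionMatrix(values=df, fruit_stages=tuple(stages))


TISSUES4 = ["root", "leaf", "flower", "fruit"]


class TestExpressedGenes:
    def test_all_zero_matrix_is_empty(self):
        m = matrix({"g1": [0, 0, 0, 0]}, TISSUES4)
        assert expressed_genes(m) == set()

    def test_exactly_threshold_excluded_strict(self):
        m = matrix({"g1": [1.4, 0, 0, 0], "g2": [1.41, 0, 0, 0]}, TISSUES4)
        assert expressed_genes(m) == {"g2"}

    def test_negative_value_rejected(self):
        with pytest.raises(DataError):
            matrix({"g1": [-1, 0, 0, 0]}, TISSUES4)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_matrix_equals_elementwise_scan(self, seed):
        rng = random.Random(seed)
        rows = {
            f"g{i}": [round(rng.uniform(0, 3), 2) for _ in TISSUES4]
            for i in range(30)
        }
        m = matrix(rows, TISSUES4)
        want = {
            g for g, vals in rows.items() if any(v > 1.4 for v in vals)
        }
        assert expressed_genes(m) == want


class TestTissueSpecific:
    def test_clear_dominance_is_specific(self):
        m = matrix({"g1": [10, 4, 3, 2]}, TISSUES4)
        assert tissue_specific_genes(m) == {"g1": "root"}

    def test_exactly_twofold_excluded_strict(self):
        m = matrix({"g1": [10, 5, 5, 5]}, TISSUES4)
        assert tissue_specific_genes(m) == {}

    def test_dominant_but_below_expressed_threshold_excluded(self):
        m = matrix({"g1": [1.2, 0.1, 0.1, 0.1]}, TISSUES4)
        assert tissue_specific_genes(m) == {}

    def test_single_tissue_rejected(self):
        m = matrix({"g1": [1.0]}, ["root"])
        with pytest.raises(ConfigError):
            tissue_specific_genes(m)

    def test_specific_subset_of_expressed(self):
        m, _ = generate_expression(40, planted_specific=8, seed=6)
        assert set(tissue_specific_genes(m)) <= expressed_genes(m)

    def test_fold_rule_is_scale_invariant(self):
        m, _ = generate_expression(30, planted_specific=6, seed=2)
        scaled = ExpressionMatrix(
            values=m.values * 3.7, fruit_stages=m.fruit_stages
        )
        assert tissue_specific_genes(m) == tissue_specific_genes(scaled)

    def test_planted_map_recovered_exactly(self):
        m, truth = generate_expression(50, planted_specific=10, seed=4)
        assert tissue_specific_genes(m) == truth["specific"]


class TestFruitTrends:
    STAGED = list(DEFAULT_FRUIT_STAGES)

    def test_strict_doubling_series_is_increasing(self):
        m = matrix({"g1": [1, 2, 4, 8, 16, 32]}, self.STAGED, self.STAGED)
        assert fruit_trend_genes(m) == {"g1": "increasing"}

    def test_constant_row_is_none(self):
        m = matrix({"g1": [2, 2, 2, 2, 2, 2]}, self.STAGED, self.STAGED)
        assert fruit_trend_genes(m) == {"g1": "none"}

    def test_monotone_but_flat_fails_fold_filter(self):
        m = matrix(
            {"g1": [2.0, 2.1, 2.2, 2.3, 2.4, 2.5]}, self.STAGED, self.STAGED
        )
        assert fruit_trend_genes(m) == {"g1": "none"}

    def test_decreasing_series_detected(self):
        m = matrix({"g1": [32, 16, 8, 4, 2, 1]}, self.STAGED, self.STAGED)
        assert fruit_trend_genes(m) == {"g1": "decreasing"}

    def test_too_few_stages_rejected(self):
        m = matrix({"g1": [1, 2]}, ["a", "b"], ["a", "b"])
        with pytest.raises(ConfigError):
            fruit_trend_genes(m)

    def test_noisy_planted_trends_recovered_at_ninety_percent(self):
        recovered = total = 0
        for seed in range(1, 11):
            m, truth = generate_expression(
                30, planted_trends=10, noise_sd_fraction=0.05, seed=seed
            )
            calls = fruit_trend_genes(m)
            for gene, direction in truth["trends"].items():
                total += 1
                recovered += calls[gene] == direction
        assert recovered / total >= 0.9


class TestDdct:
    def test_identical_samples_give_one(self):
        s = QpcrSample("g", "c", 21.0, 18.0)
        assert ddct(s, s) == 1.0

    def test_two_cycle_advantage_gives_fourfold(self):
        test = QpcrSample("g", "t", 20.0, 18.0)
        cal = QpcrSample("g", "c", 22.0, 18.0, calibrator=True)
        assert ddct(test, cal) == pytest.approx(4.0)

    def test_gene_mismatch_rejected(self):
        with pytest.raises(InputError):
            ddct(QpcrSample("g1", "t", 20, 18), QpcrSample("g2", "c", 20, 18))

    @pytest.mark.parametrize("seed", range(3))
    def test_random_tables_match_formula_oracle(self, seed):
        rng = random.Random(seed)
        samples = [
            QpcrSample("g", "cal", rng.uniform(18, 25), rng.uniform(15, 20),
                       calibrator=True)
        ]
        for i in range(5):
            samples.append(
                QpcrSample("g", f"c{i}", rng.uniform(18, 25), rng.uniform(15, 20))
            )
        table = relative_expression_table(samples)
        cal = samples[0]
        for s, value in zip(samples, table["relative_expression"]):
            assert value == pytest.approx(
                ddct_formula(s.ct_target, s.ct_reference, cal.ct_target,
                             cal.ct_reference)
            )

    def test_missing_calibrator_rejected(self):
        with pytest.raises(InputError):
            relative_expression_table([QpcrSample("g", "t", 20, 18)])

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(DataError):
            QpcrSample("g", "t", float("nan"), 18.0)
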
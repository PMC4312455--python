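"""Planted-truth generators: determinism, feasibility, self-verification."""

import io as _stdio

import pytest

from bhlhkit.binding import BindingCategory, classify_binding
from bhlhkit.errors import GenerationError
from bhlhkit.family_filter import passes_family_filter
from bhlhkit.profile_search import AlignedDomain
from bhlhkit.synthetic import (
    DOMAIN_LENGTH,
    generate_expression,
    generate_family,
    generate_qpcr,
    generate_reference_alignment,
)
from bhlhkit.expression import (
    expressed_genes,
    fruit_trend_genes,
    tissue_specific_genes,
)


class TestGenerateFamily:
    def test_planted_mix_recovered_by_classifier(self, consensus):
        records, truth = generate_family(
            15,
            0,
            binding_mix={"G_BOX": 10, "NON_DNA_BINDING": 5},
            mismatch_spectrum=(0,),
            seed=3,
        )
        counts = {}
        for pid, t in truth["proteins"].items():
            domain = AlignedDomain.from_sequence(t["domain_seq"])
            category = classify_binding(domain).category.value
            assert category == t["category"]
            counts[category] = counts.get(category, 0) + 1
        assert counts == {"G_BOX": 10, "NON_DNA_BINDING": 5}

    def test_all_ten_mismatch_members_rejected_by_filter(self, consensus):
        records, truth = generate_family(
            6, 0, mismatch_spectrum=(10,), seed=2, verify=False
        )
        for pid, t in truth["proteins"].items():
            domain = AlignedDomain.from_sequence(t["domain_seq"])
            report = passes_family_filter(domain, consensus)
            assert report.mismatch_count == 10
            assert not report.passed

    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        from bhlhkit.io import write_fasta

        paths = []
        for run in (1, 2):
            records, _ = generate_family(6, 3, seed=9)
            p = tmp_path / f"run{run}.fasta"
            write_fasta(records, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_decoys_have_no_window_near_consensus(self, consensus):
        from bhlhkit.synthetic import _window_min_mismatches

        records, truth = generate_family(2, 6, seed=4)
        for pid, t in truth["proteins"].items():
            if t["role"] == "decoy":
                assert (
                    _window_min_mismatches(records[pid], consensus, DOMAIN_LENGTH)
                    > 9
                )

    def test_infeasible_mismatch_count_rejected(self):
        with pytest.raises(GenerationError):
            generate_family(
                2,
                0,
                mismatch_spectrum=(19,),
                binding_mix={"G_BOX": 1.0},
                seed=0,
                verify=False,
            )

    def test_outputs_parse_back_through_own_readers(self, tmp_path):
        from bhlhkit.io import read_fasta, write_fasta

        records, _ = generate_family(4, 2, seed=5)
        p = tmp_path / "fam.fasta"
        write_fasta(records, p)
        assert read_fasta(p) == records


class TestReferenceAlignment:
    def test_rows_rectangular_and_family_valid(self, consensus):
        aln = generate_reference_alignment(n_rows=10, seed=6)
        assert aln.n_columns == DOMAIN_LENGTH
        assert all(m for m in aln.match_mask)
        for i in range(aln.n_rows):
            domain = AlignedDomain.from_sequence(aln.member_match_sequence(i))
            assert passes_family_filter(domain, consensus).passed

    def test_seed_changes_alignment(self):
        a = generate_reference_alignment(seed=1)
        b = generate_reference_alignment(seed=2)
        assert a.records != b.records


class TestGenerateExpression:
    def test_zero_noise_exact_recovery_of_both_sets(self):
        m, truth = generate_expression(
            50, planted_specific=8, planted_trends=8, seed=12
        )
        assert tissue_specific_genes(m) == truth["specific"]
        trends = {
            g: d for g, d in fruit_trend_genes(m).items() if d != "none"
        }
        assert trends == truth["trends"]

    def test_no_planted_genes_yields_empty_calls_across_seeds(self):
        for seed in range(1, 101):
            m, truth = generate_expression(10, seed=seed)
            assert tissue_specific_genes(m) == {}
            assert all(v == "none" for v in fruit_trend_genes(m).values())
            assert expressed_genes(m) == set()

    def test_overplanting_rejected(self):
        with pytest.raises(GenerationError):
            generate_expression(4, planted_specific=3, planted_trends=3, seed=0)

    def test_same_seed_identical_tsv(self, tmp_path):
        contents = []
        for run in (1, 2):
            m, _ = generate_expression(12, planted_specific=2, seed=3)
            p = tmp_path / f"m{run}.tsv"
            m.to_tsv(p)
            contents.append(p.read_bytes())
        assert contents[0] == contents[1]


class TestGenerateQpcr:
    def test_planted_folds_recovered_by_ddct(self):
        from bhlhkit.expression import QpcrSample, relative_expression_table

        table, truth = generate_qpcr(
            {"A": {"hot": 8.0, "cold": 0.5}}, "ctrl", seed=7
        )
        samples = [
            QpcrSample(
                gene=str(r.gene),
                condition=str(r.condition),
                ct_target=float(r.ct_target),
                ct_reference=float(r.ct_reference),
                calibrator=bool(r.calibrator),
            )
            for r in table.itertuples()
        ]
        result = relative_expression_table(samples).set_index("condition")
        assert result.loc["hot", "relative_expression"] == pytest.approx(8.0)
        assert result.loc["cold", "relative_expression"] == pytest.approx(0.5)
        assert result.loc["ctrl", "relative_expression"] == pytest.approx(1.0)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(GenerationError):
            generate_qpcr({"A": {"x": 0.0}}, "ctrl", seed=0)
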
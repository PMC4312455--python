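"""Pairwise duplication statistics and tandem-array detection."""

import random

import pytest
from Bio.Align import substitution_matrices

from bhlhkit.duplication import (
    DuplicationConfig,
    GeneLocus,
    StringencyThresholds,
    classify_family_duplications,
    duplication_counts,
    find_tags,
    pairwise_stats,
    rank_loci,
)
from bhlhkit.errors import ConfigError, InputError
from bhlhkit.synthetic import generate_duplicates, generate_tag_loci

from oracles import affine_global_best, window_scan_tags

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestPairwiseStats:
    def test_identical_sequences_class_high(self):
        stats = pairwise_stats("MKVLAWQERT" * 5, "MKVLAWQERT" * 5)
        assert stats.identity == 100.0
        assert stats.coverage == 100.0
        assert stats.dup_class == "high"

    def test_half_length_fragment_capped_coverage(self):
        full = "MKVLAWQERTYIPSDFGHKL" * 5
        stats = pairwise_stats(full, full[:50])
        assert stats.identity == 100.0
        assert stats.coverage <= 50.0
        assert stats.dup_class == "none"

    def test_symmetric_in_arguments(self):
        rng = random.Random(7)
        a = "".join(rng.choice(AA) for _ in range(60))
        b = list(a)
        for i in rng.sample(range(60), 20):
            b[i] = rng.choice(AA)
        b = "".join(b)
        ab = pairwise_stats(a, b)
        ba = pairwise_stats(b, a)
        assert ab.identity == pytest.approx(ba.identity)
        assert ab.coverage == pytest.approx(ba.coverage)
        assert ab.dup_class == ba.dup_class

    @pytest.mark.parametrize("trial", range(12))
    def test_aligner_score_matches_independent_dp_on_ten_mers(self, trial):
        """Criterion: duplication alignment equals an exhaustive DP
        oracle on 10-mer pairs."""
        rng = random.Random(4000 + trial)
        a = "".join(rng.choice(AA) for _ in range(10))
        if trial % 2:
            b = list(a)
            for i in rng.sample(range(10), rng.randint(1, 5)):
                b[i] = rng.choice(AA)
            b = "".join(b)
        else:
            b = "".join(rng.choice(AA) for _ in range(10))
        cfg = DuplicationConfig()
        from bhlhkit.duplication import _make_aligner

        aligner = _make_aligner(cfg)
        matrix = substitution_matrices.load(cfg.matrix)
        oracle = affine_global_best(
            a, b, lambda x, y: matrix[x, y], cfg.gap_open, cfg.gap_extend
        )
        assert aligner.score(a, b) == pytest.approx(oracle)

    def test_known_alignment_identity_and_coverage(self):
        # 40-mer vs its first 30 residues with 3 substitutions:
        # 30 aligned pairs, 27 identical
        rng = random.Random(11)
        a = "".join(rng.choice(AA) for _ in range(40))
        b = list(a[:30])
        for i in (5, 15, 25):
            b[i] = "W" if b[i] != "W" else "Y"
        stats = pairwise_stats(a, "".join(b))
        assert stats.identity == pytest.approx(100 * 27 / 30)
        assert stats.coverage == pytest.approx(100 * 30 / 40)

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            pairwise_stats("", "MKV")


class TestFamilyDuplications:
    def test_three_identical_sequences_all_high(self):
        members = {f"g{i}": "MKVLAWQERT" * 6 for i in range(3)}
        gene_class, pairs = classify_family_duplications(members)
        assert set(gene_class.values()) == {"high"}
        assert duplication_counts(gene_class) == {
            "high": 3,
            "low": 0,
            "singleton": 0,
        }

    def test_unrelated_sequences_are_singletons(self):
        rng = random.Random(3)
        members = {
            f"g{i}": "".join(rng.choice(AA) for _ in range(100)) for i in range(2)
        }
        gene_class, pairs = classify_family_duplications(members)
        assert set(gene_class.values()) == {"singleton"}
        assert pairs[0].identity < 30.0 or pairs[0].coverage < 70.0

    def test_raising_thresholds_never_adds_pairs(self):
        recs, _ = generate_duplicates(
            [(90, 95), (55, 92), (40, 80)], seed=9
        )
        loose = DuplicationConfig()
        strict = DuplicationConfig(
            low=StringencyThresholds(40.0, 80.0),
            high=StringencyThresholds(60.0, 95.0),
        )
        ids = list(recs)
        for i in range(0, len(ids), 2):
            a, b = recs[ids[i]], recs[ids[i + 1]]
            s_loose = pairwise_stats(a, b, loose)
            s_strict = pairwise_stats(a, b, strict)
            order = {"none": 0, "low": 1, "high": 2}
            assert order[s_strict.dup_class] <= order[s_loose.dup_class]

    def test_planted_classes_recovered_away_from_thresholds(self):
        targets = [(90, 98), (40, 85), (60, 75), (15, 95)]
        expected = ["high", "low", "low", "none"]
        recs, truth = generate_duplicates(targets, seed=2)
        for pair, want in zip(truth["pairs"], expected):
            stats = pairwise_stats(recs[pair["id_a"]], recs[pair["id_b"]])
            assert stats.dup_class == want


class TestTags:
    def locus(self, gid, rank, family=True, chrom="c1"):
        return GeneLocus(
            gene_id=gid,
            chromosome=chrom,
            start=rank * 1000,
            end=rank * 1000 + 500,
            strand="+",
            rank=rank,
            family_member=family,
        )

    def test_adjacent_family_genes_cluster(self):
        loci = [self.locus("a", 5), self.locus("b", 6)]
        clusters = find_tags(loci, max_spacers=1)
        assert [[l.gene_id for l in c] for c in clusters] == [["a", "b"]]

    def test_two_spacers_break_cluster_at_max_one(self):
        loci = [
            self.locus("a", 5),
            self.locus("s1", 6, family=False),
            self.locus("s2", 7, family=False),
            self.locus("b", 8),
        ]
        assert find_tags(loci, max_spacers=1) == []
        assert len(find_tags(loci, max_spacers=2)) == 1

    def test_rank_collision_rejected(self):
        loci = [self.locus("a", 5), self.locus("b", 5)]
        with pytest.raises(InputError):
            find_tags(loci)

    def test_negative_max_spacers_rejected(self):
        with pytest.raises(ConfigError):
            find_tags([], max_spacers=-1)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_chromosome_matches_window_scan_oracle(self, seed):
        rng = random.Random(seed)
        loci = []
        rank = 0
        for chrom in ("c1", "c2"):
            for _ in range(rng.randint(5, 30)):
                rank += 1
                loci.append(
                    self.locus(
                        f"{chrom}g{rank}",
                        rank,
                        family=rng.random() < 0.4,
                        chrom=chrom,
                    )
                )
            rank = 0
        for spacers in (0, 1, 3):
            got = find_tags(loci, max_spacers=spacers)
            want = window_scan_tags(loci, max_spacers=spacers)
            assert [
                [l.gene_id for l in c] for c in got
            ] == [[l.gene_id for l in c] for c in want]

    def test_planted_clusters_recovered(self):
        loci, truth = generate_tag_loci([2, 4, 3], n_scattered=6, seed=5)
        clusters = find_tags(loci, max_spacers=truth["max_spacers"])
        assert [[l.gene_id for l in c] for c in clusters] == truth["clusters"]

    def test_rank_loci_orders_by_start_per_chromosome(self):
        raw = [
            GeneLocus("b", "c1", 5000, 5400, "+", 0),
            GeneLocus("a", "c1", 100, 900, "-", 0),
            GeneLocus("c", "c2", 50, 60, "+", 0),
        ]
        ranked = {l.gene_id: l.rank for l in rank_loci(raw)}
        assert ranked == {"a": 1, "b": 2, "c": 1}
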
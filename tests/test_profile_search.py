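"""Profile construction and local domain search."""

import math
import random

import pytest

from bhlhkit.errors import (
    AlignmentShapeError,
    AlphabetError,
    ConsistencyError,
    InputError,
)
from bhlhkit.profile_search import (
    AlignedDomain,
    ReferenceAlignment,
    ScoringProfile,
    build_profile,
    canonical_map,
    default_min_score,
    locate_domain,
)
from bhlhkit.synthetic import generate_reference_alignment

from oracles import enumerate_local_best


def make_profile(columns, gap_open=4.0, gap_extend=0.5):
    """Profile with explicit per-column favoured residues.

    ``columns`` is a list of dicts residue -> score; unlisted residues
    score -2.
    """
    scores = []
    for col in columns:
        full = {aa: -2.0 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        full.update(col)
        scores.append(full)
    return ScoringProfile(
        n_columns=len(scores),
        scores=tuple(scores),
        gap_open=gap_open,
        gap_extend=gap_extend,
    )


class TestBuildProfile:
    def test_identical_rows_consensus_score_is_log2_inverse_background(self):
        aln = ReferenceAlignment.from_records([("a", "ACDE"), ("b", "ACDE")])
        profile = build_profile(aln, pseudocount_weight=0.0)
        expected = math.log2(1 / 0.05)
        for col, res in enumerate("ACDE", start=1):
            assert profile.score(col, res) == pytest.approx(expected)

    def test_majority_gap_column_excluded_from_match_columns(self):
        aln = ReferenceAlignment.from_records(
            [("a", "A-C"), ("b", "A-C"), ("c", "AGC")]
        )
        assert aln.match_mask == (True, False, True)
        assert build_profile(aln).n_columns == 2

    def test_five_row_alignment_matches_hand_computed_frequencies(self):
        rows = ["AC", "AC", "AD", "GC", "AC"]
        aln = ReferenceAlignment.from_records(
            [(f"r{i}", row) for i, row in enumerate(rows)]
        )
        profile = build_profile(aln, pseudocount_weight=1.0)
        bg = 1 / 20
        # column 1: A x4, G x1, n_eff 5
        for res, count in [("A", 4), ("G", 1), ("C", 0)]:
            expected = math.log2((count + bg) / ((5 + 1) * bg))
            assert profile.score(1, res) == pytest.approx(expected)
        # column 2: C x4, D x1
        assert profile.score(2, "C") == pytest.approx(
            math.log2((4 + bg) / (6 * bg))
        )
        assert profile.score(2, "D") == pytest.approx(
            math.log2((1 + bg) / (6 * bg))
        )

    def test_rejects_ragged_alignment_and_bad_alphabet(self):
        with pytest.raises(AlignmentShapeError):
            ReferenceAlignment.from_records([("a", "AC"), ("b", "ACD")])
        with pytest.raises(AlphabetError):
            ReferenceAlignment.from_records([("a", "AX"), ("b", "AC")])


class TestLocateDomain:
    def test_reference_member_found_at_its_self_score(self):
        aln = generate_reference_alignment(n_rows=6, seed=3, domain_len=20)
        profile = build_profile(aln)
        member = aln.member_match_sequence(0)
        hit = locate_domain(member, profile, min_score=0.0)
        assert (hit.start, hit.end) == (1, len(member))
        assert hit.score == pytest.approx(profile.self_score(member))

    def test_hostile_sequence_yields_no_hit(self):
        profile = make_profile([{"W": 5.0}] * 4)  # every column dislikes A
        assert locate_domain("A" * 200, profile, min_score=0.0) is None

    def test_empty_sequence_rejected(self):
        profile = make_profile([{"A": 1.0}])
        with pytest.raises(InputError):
            locate_domain("", profile)

    @pytest.mark.parametrize("trial", range(40))
    def test_dp_score_equals_exhaustive_enumeration(self, trial):
        """Criterion: DP optimum == brute-force path enumeration on all
        instances with <= 5 profile columns and <= 8 query residues."""
        rng = random.Random(1000 + trial)
        n = rng.randint(1, 5)
        L = rng.randint(1, 8)
        alphabet = "ACDE"
        columns = []
        for _ in range(n):
            columns.append(
                {aa: round(rng.uniform(-4, 5), 2) for aa in alphabet}
            )
        profile = make_profile(columns, gap_open=3.0, gap_extend=0.7)
        seq = "".join(rng.choice(alphabet) for _ in range(L))
        hit = locate_domain(seq, profile, min_score=-1e9)
        expected = enumerate_local_best(
            profile.scores, seq, gap_open=3.0, gap_extend=0.7
        )
        if expected == float("-inf"):
            assert hit is None
        else:
            assert hit.score == pytest.approx(expected)

    def test_score_invariant_under_hostile_flank_padding(self):
        profile = make_profile(
            [{"M": 4.0}, {"K": 4.0}, {"V": 4.0}]
        )
        core = locate_domain("MKV", profile, min_score=0.0)
        padded = locate_domain("AAAA" + "MKV" + "CCCC", profile, min_score=0.0)
        assert padded.score == pytest.approx(core.score)
        assert (padded.start, padded.end) == (5, 7)

    def test_tie_broken_to_smallest_start_then_end(self):
        profile = make_profile([{"A": 3.0}])
        hit = locate_domain("CACAC", profile, min_score=0.0)
        assert (hit.start, hit.end) == (2, 2)

    def test_training_members_recover_most_match_columns(self):
        aln = generate_reference_alignment(n_rows=8, seed=11)
        profile = build_profile(aln)
        min_score = default_min_score(profile, aln)
        for i in range(aln.n_rows):
            member = aln.member_match_sequence(i)
            hit = locate_domain(member, profile, min_score=min_score)
            assert hit is not None
            covered = sum(1 for p in hit.column_map if p is not None)
            assert covered >= 0.9 * profile.n_columns

    def test_determinism_bit_identical(self):
        aln = generate_reference_alignment(n_rows=6, seed=5, domain_len=30)
        profile = build_profile(aln)
        seq = "MSTP" + aln.member_match_sequence(2) + "WYAQ"
        h1 = locate_domain(seq, profile, min_score=0.0)
        h2 = locate_domain(seq, profile, min_score=0.0)
        assert h1 == h2


class TestCanonicalMap:
    def test_ungapped_hit_is_identity_mapping(self):
        profile = make_profile([{"M": 4.0}, {"K": 4.0}, {"V": 4.0}])
        hit = locate_domain("AAMKVCC", profile, min_score=0.0)
        domain = canonical_map(hit, profile)
        assert domain.residues == ("M", "K", "V")
        assert domain.positions == (3, 4, 5)

    def test_deleted_column_maps_to_gap_others_shift(self):
        profile = make_profile(
            [{"M": 6.0}, {"K": 6.0}, {"V": 6.0}, {"W": 6.0}]
        )
        hit = locate_domain("MKW", profile, min_score=0.0)  # V column deleted
        domain = canonical_map(hit, profile)
        assert domain.residues == ("M", "K", None, "W")
        assert domain.positions == (1, 2, None, 3)

    def test_mismatched_profile_rejected(self):
        p3 = make_profile([{"M": 4.0}, {"K": 4.0}, {"V": 4.0}])
        p2 = make_profile([{"M": 4.0}, {"K": 4.0}])
        hit = locate_domain("MKV", p3, min_score=0.0)
        with pytest.raises(ConsistencyError):
            canonical_map(hit, p2)

    def test_insertion_recorded_but_unnumbered(self):
        profile = make_profile(
            [{"M": 6.0}, {"K": 6.0}, {"V": 6.0}, {"W": 6.0}]
        )
        hit = locate_domain("MKAAVW", profile, min_score=0.0)
        domain = canonical_map(hit, profile)
        assert domain.residues == ("M", "K", "V", "W")
        assert domain.insertions == ((2, "AA"),)
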
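"""Global affine-gap alignment and site/flank mapping."""

from functools import lru_cache

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from ubiqevo.align import (
    DEFAULT_SCORING,
    build_species_ladder_profile,
    flank_positions,
    global_align,
    map_site,
)
from ubiqevo.types import (
    AMINO_ACIDS,
    AlignedOrthologPair,
    OrganismOrder,
    SiteRecord,
)

NEG_INF = float("-inf")


def recursive_oracle_score(a, b, sub, go, ge):
    """Independent affine-gap optimum via memoized recursion over suffixes.

    State: (i, j, last) with last in {'m', 'x', 'y'} describing the previous
    step ('x' = gap in b, 'y' = gap in a), so gap opening vs extension is
    charged correctly.
    """

    @lru_cache(maxsize=None)
    def rec(i, j, last):
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG_INF
        if i < len(a) and j < len(b):
            best = max(best, sub[(a[i], b[j])] + rec(i + 1, j + 1, "m"))
        if i < len(a):
            cost = ge if last == "x" else go
            best = max(best, -cost + rec(i + 1, j, "x"))
        if j < len(b):
            cost = ge if last == "y" else go
            best = max(best, -cost + rec(i, j + 1, "y"))
        return best

    return rec(0, 0, "m")


def biopython_score(a, b):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -DEFAULT_SCORING.gap_open
    aligner.extend_gap_score = -DEFAULT_SCORING.gap_extend
    return aligner.score(a, b)


class TestGlobalAlign:
    def test_identical_sequences_align_without_gaps(self):
        seq = "MKTAYIAKQR"
        pair = global_align(seq, seq)
        assert pair.aligned_human == seq and pair.aligned_ortholog == seq
        sub = DEFAULT_SCORING.substitution()
        assert pair.score == sum(sub[(c, c)] for c in seq)

    def test_classic_pair_matches_independent_oracles(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        pair = global_align(a, b)
        sub = DEFAULT_SCORING.substitution()
        assert pair.score == recursive_oracle_score(
            a, b, sub, DEFAULT_SCORING.gap_open, DEFAULT_SCORING.gap_extend
        )
        assert pair.score == biopython_score(a, b)

    def test_argument_swap_transposes_alignment(self):
        a, b = "MKWVTFISLL", "MKWVFISL"
        p1 = global_align(a, b)
        p2 = global_align(b, a)
        assert p1.score == p2.score
        assert p1.aligned_human.replace("-", "") == a
        assert p2.aligned_ortholog.replace("-", "") == a

    def test_ungapping_recovers_inputs(self):
        pair = global_align("ACDEFGHIK", "ACDFGHK")
        assert pair.human_sequence == "ACDEFGHIK"
        assert pair.ortholog_sequence == "ACDFGHK"

    @pytest.mark.parametrize("a,b", [("", "ACD"), ("AC1D", "ACD"),
                                     ("ACD", "AC-D")])
    def test_illegal_input_rejected(self, a, b):
        with pytest.raises(ValueError):
            global_align(a, b)

    def test_scores_match_biopython_on_random_pairs(self):
        rng = np.random.default_rng(1)
        aas = list(AMINO_ACIDS)
        for _ in range(60):
            a = "".join(rng.choice(aas, size=rng.integers(1, 31)))
            b = "".join(rng.choice(aas, size=rng.integers(1, 31)))
            assert global_align(a, b).score == biopython_score(a, b)


@given(
    a=st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=9),
    b=st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=9),
)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_alignment_score_equals_recursive_oracle(a, b):
    sub = DEFAULT_SCORING.substitution()
    expected = recursive_oracle_score(
        a, b, sub, DEFAULT_SCORING.gap_open, DEFAULT_SCORING.gap_extend
    )
    assert global_align(a, b).score == expected


def make_pair(aligned_human, aligned_ortholog, organism="M. musculus"):
    return AlignedOrthologPair(
        human_id="P1", organism=organism,
        aligned_human=aligned_human, aligned_ortholog=aligned_ortholog,
    )


class TestMapSite:
    def test_identity_pair(self):
        pair = make_pair("ACDEFGHIKK", "ACDEFGHIKK")
        assert map_site(pair, 10).ortholog_residue == "K"

    def test_deletion_spanning_site_yields_gap(self):
        pair = make_pair("ACDEFKHIK", "ACDEF-HIK")
        assert map_site(pair, 6).ortholog_residue == "-"

    def test_substituted_site(self):
        pair = make_pair("ACDKF", "ACDRF")
        assert map_site(pair, 4).ortholog_residue == "R"

    def test_insertion_shifts_columns_not_positions(self):
        pair = make_pair("AC--DKF", "ACWWDKF")
        assert map_site(pair, 4).ortholog_residue == "K"

    def test_position_outside_protein(self):
        pair = make_pair("ACDKF", "ACDRF")
        with pytest.raises(ValueError, match="outside"):
            map_site(pair, 6)


class TestFlankPositions:
    def test_interior_site(self):
        assert flank_positions(100, 50) == list(range(45, 50)) + \
            list(range(51, 56))

    def test_left_truncation(self):
        assert flank_positions(100, 2) == [1, 3, 4, 5, 6, 7]

    def test_right_truncation(self):
        assert flank_positions(100, 100) == [95, 96, 97, 98, 99]

    def test_site_excluded_and_width_respected(self):
        flanks = flank_positions(200, 80, half_width=3)
        assert 80 not in flanks and len(flanks) == 6


class TestSpeciesLadderProfile:
    ORDER = OrganismOrder(("org_a", "org_b", "org_c"))

    def test_identity_everywhere(self):
        pairs = {
            o: make_pair("ACDKF", "ACDKF", organism=o)
            for o in self.ORDER.names
        }
        site = SiteRecord("P1", 4, "K")
        assert build_species_ladder_profile(site, pairs, self.ORDER) == \
            ["K", "K", "K"]

    def test_missing_organisms_are_none(self):
        pairs = {"org_b": make_pair("ACDKF", "ACDRF", organism="org_b")}
        site = SiteRecord("P1", 4, "K")
        assert build_species_ladder_profile(site, pairs, self.ORDER) == \
            [None, "R", None]

    def test_wrong_protein_rejected(self):
        pair = AlignedOrthologPair(
            human_id="P2", organism="org_a",
            aligned_human="ACDKF", aligned_ortholog="ACDKF",
        )
        site = SiteRecord("P1", 4, "K")
        with pytest.raises(ValueError, match="P2"):
            build_species_ladder_profile(site, {"org_a": pair}, self.ORDER)


def test_map_site_recovers_ground_truth_without_indels(small_dataset):
    """On indel-free synthetic data the mapped residue is exact for every
    site: the true alignment is gapless, so columns equal positions."""
    for site in small_dataset.sites:
        for organism, pair in small_dataset.aligned_pairs[
            site.protein_id
        ].items():
            obs = map_site(pair, site.position)
            assert obs.ortholog_residue == \
                pair.aligned_ortholog[site.position - 1]
            assert obs.human_residue == "K"
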
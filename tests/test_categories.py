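"""Relative distances, tissue-specificity scores and hub detection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ubiqevo.categories import (
    compare_groups,
    degree_and_hubs,
    relative_distance,
    tsps,
    tsps_table,
)
from ubiqevo.stats import PoissonEstimate, SubstitutionCount, poisson_estimate


def est(d, var_d, organism="org"):
    p = 1 - math.exp(-d)
    return PoissonEstimate(
        p=p, var_p=var_d * (1 - p) ** 2, d=d, var_d=var_d,
        n_total=1000, organism=organism,
    )


class TestRelativeDistance:
    def test_equal_distances_give_unit_ratio(self):
        rel = relative_distance(est(0.2, 0.0), est(0.2, 0.0))
        assert rel.r == 1.0 and rel.var_r == 0.0

    def test_delta_method_closed_form(self):
        rel = relative_distance(est(0.10, 0.0004), est(0.20, 0.0005))
        assert rel.r == pytest.approx(0.5)
        assert rel.var_r == pytest.approx(
            0.0004 / 0.04 + 0.01 * 0.0005 / 0.0016
        )
        assert rel.var_r == pytest.approx(0.013125)

    def test_degenerate_background_error(self):
        with pytest.raises(ValueError, match="degenerate background"):
            relative_distance(est(0.1, 0.001), est(0.0, 0.0))

    def test_invariant_under_doubling_counts(self):
        a = relative_distance(
            poisson_estimate(SubstitutionCount(30, 300)),
            poisson_estimate(SubstitutionCount(60, 300)),
        )
        b = relative_distance(
            poisson_estimate(SubstitutionCount(60, 600)),
            poisson_estimate(SubstitutionCount(120, 600)),
        )
        assert a.r == pytest.approx(b.r)

    def test_delta_variance_tracks_monte_carlo(self):
        """Quick check at n = 2000; the full-scale validation lives in the
        acceptance suite."""
        rng = np.random.default_rng(3)
        n, ps, pf = 2000, 0.1, 0.2
        ks = rng.binomial(n, ps, size=4000)
        kf = rng.binomial(n, pf, size=4000)
        rs = np.log1p(-ks / n) / np.log1p(-kf / n)
        rel = relative_distance(
            poisson_estimate(SubstitutionCount(int(ps * n), n)),
            poisson_estimate(SubstitutionCount(int(pf * n), n)),
        )
        assert rel.var_r == pytest.approx(rs.var(), rel=0.2)


class TestCompareGroups:
    def test_equal_ratios_give_zero(self):
        rel = relative_distance(est(0.1, 0.0004), est(0.2, 0.0005))
        tz = compare_groups(rel, rel)
        assert tz.z == 0

    def test_antisymmetry(self):
        a = relative_distance(est(0.10, 0.0004), est(0.20, 0.0005))
        b = relative_distance(est(0.15, 0.0004), est(0.20, 0.0005))
        assert compare_groups(a, b).z == pytest.approx(
            -compare_groups(b, a).z
        )


class TestTsps:
    @pytest.mark.parametrize("n_tissues", [2, 4, 8, 16, 32])
    def test_uniform_expression_scores_zero(self, n_tissues):
        res = tsps([3.5] * n_tissues)
        assert res.tsps == 0.0
        assert res.tsps_class == "facilitator"

    def test_single_tissue_among_32_scores_five(self):
        vec = [0.0] * 32
        vec[17] = 100.0
        res = tsps(vec)
        assert res.tsps == 5.0
        assert res.tsps_class == "specifier"

    def test_half_concentrated_scores_one_bit(self):
        res = tsps([4.0, 4.0, 0.0, 0.0])
        assert res.tsps == pytest.approx(1.0)

    def test_bounded_by_log2_n_tissues(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            vec = rng.gamma(0.3, size=16)
            score = tsps(vec).tsps
            assert 0.0 <= score <= 4.0 + 1e-12

    def test_negative_and_zero_vectors_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            tsps([1.0, -0.5, 2.0])
        with pytest.raises(ValueError, match="all-zero"):
            tsps([0.0, 0.0, 0.0])

    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale, seed):
        vec = np.random.default_rng(seed).gamma(1.0, size=12) + 1e-9
        assert tsps(vec * scale).tsps == pytest.approx(
            tsps(vec).tsps, abs=1e-9
        )

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_concentrating_mass_increases_score(self, seed):
        """Moving mass from a lower-expressed to a higher-expressed tissue
        (a Robin Hood transfer in reverse) strictly increases TSPS."""
        rng = np.random.default_rng(seed)
        vec = rng.gamma(1.0, size=8) + 0.05
        lo, hi = int(np.argmin(vec)), int(np.argmax(vec))
        if lo == hi:
            return
        moved = vec.copy()
        delta = vec[lo] * 0.5
        moved[lo] -= delta
        moved[hi] += delta
        assert tsps(moved).tsps > tsps(vec).tsps

    def test_table_excludes_all_zero_proteins(self, caplog):
        df = pd.DataFrame(
            [[1.0, 1.0], [0.0, 0.0]], index=["P1", "P2"],
            columns=["t1", "t2"],
        )
        with caplog.at_level("WARNING"):
            out = tsps_table(df)
        assert [t.protein_id for t in out] == ["P1"]
        assert "P2" in caplog.text


class TestDegreesAndHubs:
    def test_isolated_protein_has_degree_zero(self):
        records = degree_and_hubs([], proteins=["P1"])
        assert records[0].degree == 0 and not records[0].is_hub

    def test_duplicate_and_reversed_edges_collapse(self):
        records = degree_and_hubs([("A", "B"), ("B", "A"), ("A", "B")])
        assert all(r.degree == 1 for r in records)

    def test_self_loops_ignored(self):
        records = degree_and_hubs([("A", "A")], proteins=["A"])
        assert records[0].degree == 0

    def test_star_of_21_leaves_makes_center_a_hub(self):
        edges = [("HUB", f"L{i}") for i in range(21)]
        records = {r.protein_id: r for r in degree_and_hubs(edges)}
        assert records["HUB"].degree == 21 and records["HUB"].is_hub
        assert all(not records[f"L{i}"].is_hub for i in range(21))

    def test_threshold_is_strict(self):
        edges = [("C", f"L{i}") for i in range(20)]
        records = {r.protein_id: r for r in degree_and_hubs(edges)}
        assert records["C"].degree == 20 and not records["C"].is_hub
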
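"""Synthetic-data generator: substitution process, planting, determinism."""

import dataclasses

import numpy as np
import pytest

from ubiqevo.simulate import (
    DEFAULT_EPOCHS,
    DEFAULT_ORGANISMS,
    SimulationConfig,
    expected_difference_proportion,
    plant_gain_pattern,
    simulate_dataset,
)
from ubiqevo.types import SiteRecord, ValidationError

ORDER = SimulationConfig().organism_order()


def test_zero_rates_give_identical_orthologs():
    config = SimulationConfig(
        n_proteins=4,
        background_rate_multiplier=0.0,
        site_rate_multiplier=0.0,
        flank_rate_multiplier=0.0,
        indel_rate=0.0,
        seed=1,
    )
    ds = simulate_dataset(config)
    for pid, pairs in ds.aligned_pairs.items():
        for pair in pairs.values():
            assert pair.aligned_ortholog == ds.sequences[pid]


def test_seed_determinism():
    config = SimulationConfig(n_proteins=6, indel_rate=0.002, seed=99)
    a = simulate_dataset(config)
    b = simulate_dataset(config)
    assert a.sites == b.sites
    assert a.sequences == b.sequences
    assert a.edges == b.edges
    assert a.expression.equals(b.expression)
    for pid in a.aligned_pairs:
        for org in a.aligned_pairs[pid]:
            pa, pb = a.aligned_pairs[pid][org], b.aligned_pairs[pid][org]
            assert pa.aligned_ortholog == pb.aligned_ortholog


def test_different_seeds_differ():
    a = simulate_dataset(SimulationConfig(n_proteins=4, seed=1))
    b = simulate_dataset(SimulationConfig(n_proteins=4, seed=2))
    assert a.sequences != b.sequences


@pytest.mark.parametrize(
    "kw,needle",
    [
        ({"n_proteins": 0}, "n_proteins"),
        ({"protein_length_range": (10, 50)}, "protein_length_range"),
        ({"n_tissues": 1}, "n_tissues"),
        ({"site_rate_multiplier": -1.0}, "site_rate_multiplier"),
        ({"organisms": (("a", 1.0), ("b", 0.5))}, "nondecreasing"),
        ({"planted_gain_epochs": {"vertebrate": 10**6}},
         "planted_gain_epochs"),
        ({"planted_gain_epochs": {"nonsense": 1}}, "nonsense"),
    ],
)
def test_invalid_config_names_the_field(kw, needle):
    with pytest.raises(ValidationError, match=needle):
        simulate_dataset(SimulationConfig(**kw))


def markov_oracle_difference_fraction(lam, reps=200, n=400, seed=123):
    """Empirical per-residue difference fraction under an independent
    implementation of the uniform 20-state jump process."""
    rng = np.random.default_rng(seed)
    fractions = []
    for _ in range(reps):
        start = rng.integers(0, 20, size=n)
        state = start.copy()
        events = rng.poisson(lam, size=n)
        for i in range(n):
            for _ in range(events[i]):
                choices = [s for s in range(20) if s != state[i]]
                state[i] = choices[rng.integers(0, 19)]
        fractions.append(np.mean(state != start))
    return np.array(fractions)


def test_background_difference_fraction_matches_markov_oracle():
    """Observed differing fraction at depth 0.2 agrees with an independent
    simulation of the substitution chain (and with the closed form) within
    3 Monte-Carlo standard errors."""
    lam = 0.2
    oracle = markov_oracle_difference_fraction(lam)
    se = oracle.std(ddof=1) / np.sqrt(len(oracle))
    config = SimulationConfig(
        n_proteins=40,
        protein_length_range=(250, 300),
        sites_per_protein=1,
        organisms=(("probe", lam),),
        epochs={},
        seed=11,
    )
    ds = simulate_dataset(config)
    diffs = total = 0
    for pid, pairs in ds.aligned_pairs.items():
        human = ds.sequences[pid]
        orth = pairs["probe"].aligned_ortholog
        # background residues only: away from sites and flanks
        site_pos = {
            s.position for s in ds.sites if s.protein_id == pid
        }
        for i, (h, o) in enumerate(zip(human, orth), start=1):
            if any(abs(i - p) <= 5 for p in site_pos):
                continue
            total += 1
            diffs += h != o
    assert total > 10_000
    observed = diffs / total
    # oracle and closed form agree; generator must sit inside the band
    assert abs(oracle.mean() - expected_difference_proportion(lam)) < 3 * se
    band = 3 * max(se, np.sqrt(observed * (1 - observed) / total))
    assert abs(observed - oracle.mean()) < band


def test_rate_ordering_sites_slower_than_flanks():
    """With site multiplier < flank multiplier the pooled difference
    proportion at sites is below that at flanks."""
    config = SimulationConfig(
        n_proteins=250,
        sites_per_protein=3,
        site_rate_multiplier=0.5,
        flank_rate_multiplier=1.0,
        seed=21,
    )
    ds = simulate_dataset(config)
    site_diff = site_tot = flank_diff = flank_tot = 0
    for pid, pairs in ds.aligned_pairs.items():
        human = ds.sequences[pid]
        positions = [s.position for s in ds.sites if s.protein_id == pid]
        for pair in pairs.values():
            orth = pair.aligned_ortholog
            for p in positions:
                site_tot += 1
                site_diff += human[p - 1] != orth[p - 1]
                for q in range(max(1, p - 5), min(len(human), p + 5) + 1):
                    if q in positions:
                        continue
                    flank_tot += 1
                    flank_diff += human[q - 1] != orth[q - 1]
    assert site_tot >= 10_000
    assert site_diff / site_tot < flank_diff / flank_tot


class TestPlantGainPattern:
    def test_vertebrate_pattern(self):
        site = SiteRecord("P1", 10, "K")
        vec = plant_gain_pattern(site, "vertebrate", ORDER)
        cut = DEFAULT_EPOCHS["vertebrate"]
        assert all(r == "K" for r in vec[:cut])
        assert all(r != "K" for r in vec[cut:])
        assert ORDER.names[cut - 1] == "D. rerio"

    def test_most_ancient_epoch_is_all_lysine(self):
        site = SiteRecord("P1", 10, "K")
        vec = plant_gain_pattern(site, "eukaryote", ORDER)
        assert vec == ["K"] * 14

    def test_unknown_epoch_rejected(self):
        with pytest.raises(KeyError, match="mesozoic"):
            plant_gain_pattern(SiteRecord("P1", 10, "K"), "mesozoic", ORDER)


def test_ground_truth_covers_every_site_exactly_once(small_dataset):
    keys = [(s.protein_id, s.position) for s in small_dataset.sites]
    assert len(keys) == len(set(keys))
    assert set(small_dataset.truth.gain_epoch) == set(keys)
    assert set(small_dataset.truth.site_rate_multiplier) == set(keys)


def test_planted_sites_show_expected_ladders(small_dataset):
    order = small_dataset.organism_order
    for site in small_dataset.sites:
        key = (site.protein_id, site.position)
        epoch = small_dataset.truth.gain_epoch[key]
        if epoch is None:
            continue
        cut = order.epochs[epoch]
        pairs = small_dataset.aligned_pairs[site.protein_id]
        for idx, organism in enumerate(order.names):
            res = pairs[organism].aligned_ortholog[site.position - 1]
            if idx < cut:
                assert res == "K"
            else:
                assert res != "K"


def test_expression_classes_are_separable(small_dataset):
    from ubiqevo.categories import tsps

    by_class = {"facilitator": [], "specifier": []}
    for pid, cls in small_dataset.truth.expression_class.items():
        score = tsps(small_dataset.expression.loc[pid].to_numpy()).tsps
        by_class[cls].append(score)
    if by_class["facilitator"] and by_class["specifier"]:
        assert np.mean(by_class["facilitator"]) < \
            np.mean(by_class["specifier"])
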
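"""Enrichment statistics and the end-to-end pipeline."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpea.enrichment import (
    EnrichmentParams,
    EnrichmentResult,
    netpea_prime_zscore,
    netpea_zscore,
    ora_pvalue,
    run_enrichment,
    z_to_p,
)
from netpea.genesets import InputGeneSet
from netpea.synthetic import ScenarioParams, generate_scenario


class TestNetpeaZscore:
    def test_score_at_null_mean_is_zero(self):
        assert netpea_zscore(2.0, [1.0, 3.0]) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # mean 2, sample std sqrt(2) -> (5-2)/sqrt(2)
        assert netpea_zscore(5.0, [1.0, 3.0]) == pytest.approx(3 / math.sqrt(2))

    def test_constant_null_is_undefined(self):
        assert math.isnan(netpea_zscore(1.0, [2.0, 2.0, 2.0]))

    def test_too_short_null_rejected(self):
        with pytest.raises(ValueError):
            netpea_zscore(1.0, [2.0])

    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        d=st.floats(min_value=-5, max_value=5),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_common_rescaling(self, scale, d):
        """Scores scale with seed-set size; the z-score must not."""
        r = np.array([0.1, 0.4, 0.2, 0.9, 0.3])
        z1 = netpea_zscore(d, r)
        z2 = netpea_zscore(d * scale, r * scale)
        assert z2 == pytest.approx(z1, rel=1e-9, abs=1e-9)


class TestNetpeaPrimeZscore:
    def test_hand_arithmetic(self):
        # C = {0, 2}; ((4-2) - 1) / sqrt(2)
        z = netpea_prime_zscore(4.0, [2.0], [1.0, 3.0], np.array([[1.0, 1.0]]))
        assert z == pytest.approx(1 / math.sqrt(2))

    def test_identity_rewiring_degenerates(self):
        # DR == DN and RR rows == RN -> C is the zero vector, std 0
        rn = np.array([0.3, 0.5, 0.4])
        z = netpea_prime_zscore(0.7, [0.7, 0.7], rn, np.tile(rn, (2, 1)))
        assert math.isnan(z)

    def test_grand_mean_mode_same_center_different_spread(self):
        rng = np.random.default_rng(0)
        rn = rng.random(50)
        rr = rng.random((4, 50))
        dr = [0.5, 0.6, 0.4, 0.5]
        paired = netpea_prime_zscore(1.0, dr, rn, rr)
        grand = netpea_prime_zscore(1.0, dr, rn, rr, grand_mean=True)
        # same numerator, different std -> generally different values
        assert paired != pytest.approx(grand)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            netpea_prime_zscore(1.0, [0.5], [0.1, 0.2], np.zeros((2, 3)))


class TestZToP:
    def test_published_conversion_pairs(self):
        # printed-precision checks: 1.65<->0.05, 3.5<->2.3e-4, 7.9<->1.4e-15
        assert round(z_to_p(1.65), 2) == 0.05
        assert z_to_p(3.5) == pytest.approx(2.3e-4, abs=0.05e-4)
        assert z_to_p(7.9) == pytest.approx(1.4e-15, abs=0.05e-15)

    def test_symmetry_at_zero(self):
        assert z_to_p(0.0) == pytest.approx(0.5)

    @given(st.floats(min_value=-8, max_value=8))
    @settings(max_examples=100, deadline=None)
    def test_complement_identity(self, z):
        assert z_to_p(z) + z_to_p(-z) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_decreasing(self):
        zs = np.linspace(-6, 6, 200)
        ps = [z_to_p(z) for z in zs]
        assert all(a > b for a, b in zip(ps, ps[1:]))


def _brute_force_ora(overlap, n_input, n_path, n_universe):
    """Enumerate every draw of n_input genes from the universe and count how
    often at least `overlap` of them fall into the pathway."""
    universe = range(n_universe)
    pathway = set(range(n_path))
    hits = total = 0
    for draw in itertools.combinations(universe, n_input):
        total += 1
        if len(pathway.intersection(draw)) >= overlap:
            hits += 1
    return hits / total


class TestOraPvalue:
    def test_zero_overlap_is_certain(self):
        assert ora_pvalue(0, 5, 5, 20) == pytest.approx(1.0)

    def test_perfect_overlap_closed_form(self):
        # P[all 5 drawn genes hit a 5-gene pathway] = 1/C(10,5)
        assert ora_pvalue(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_against_enumeration(self):
        for n_universe in (6, 9, 12):
            for n_path in (2, n_universe // 2):
                for n_input in (2, n_universe // 2):
                    for k in range(min(n_path, n_input) + 1):
                        expected = _brute_force_ora(k, n_input, n_path, n_universe)
                        assert ora_pvalue(k, n_input, n_path, n_universe) == pytest.approx(
                            expected, abs=1e-12
                        ), (k, n_input, n_path, n_universe)

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            ora_pvalue(6, 5, 5, 10)
        with pytest.raises(ValueError):
            ora_pvalue(1, 11, 5, 10)


@pytest.fixture(scope="module")
def scenario():
    return generate_scenario(ScenarioParams(), seed=20)


class TestRunEnrichment:
    def test_self_input_ranks_first(self, scenario):
        """Feeding a planted pathway as input must rank that pathway first."""
        pid = "PLANTED_02"
        inp = InputGeneSet.from_genes(scenario.modules[pid])
        res = run_enrichment(
            scenario.network,
            scenario.pathways,
            inp,
            "netpea",
            EnrichmentParams(n_perm=100),
            seed=5,
        )
        assert res.rank_of(pid) == 1
        assert res.table.loc[0, "significant"]

    def test_ranks_are_permutation(self, scenario):
        inp = InputGeneSet.from_genes(scenario.modules["PLANTED_01"])
        res = run_enrichment(
            scenario.network, scenario.pathways, inp, "netpea",
            EnrichmentParams(n_perm=50), seed=1,
        )
        assert sorted(res.table["rank"]) == list(range(1, len(res.table) + 1))
        assert res.table["pvalue"].between(0, 1).all()

    def test_ora_disjoint_input_nothing_significant(self, scenario):
        # background genes outside every pathway
        in_paths = {g for s in scenario.pathways for g in s.members}
        free = [g for g in scenario.network.nodes if g not in in_paths][:10]
        res = run_enrichment(
            scenario.network, scenario.pathways,
            InputGeneSet.from_genes(free), "ora", seed=0,
        )
        assert not res.table["significant"].any()
        assert (res.table["overlap"] == 0).all()
        assert (res.table["pvalue"] == 1.0).all()

    def test_deterministic_output(self, scenario, tmp_path):
        inp = InputGeneSet.from_genes(scenario.modules["PLANTED_03"])
        params = EnrichmentParams(n_perm=50, n_nets=2)
        paths = []
        for tag in ("a", "b"):
            res = run_enrichment(
                scenario.network, scenario.pathways, inp, "netpea-prime", params, seed=3
            )
            p = tmp_path / f"{tag}.tsv"
            res.to_tsv(p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_tsv_roundtrip(self, scenario, tmp_path):
        inp = InputGeneSet.from_genes(scenario.modules["PLANTED_01"])
        res = run_enrichment(
            scenario.network, scenario.pathways, inp, "netpea",
            EnrichmentParams(n_perm=50), seed=2,
        )
        out = tmp_path / "res.tsv"
        res.to_tsv(out)
        back = EnrichmentResult.from_tsv(out)
        assert back.method == "netpea"
        assert back.seed == 2
        assert tuple(back.table["pathway_id"]) == res.ranking()
        assert back.significant() == res.significant()

    def test_bh_adjustment_monotone(self, scenario):
        inp = InputGeneSet.from_genes(scenario.modules["PLANTED_01"])
        res = run_enrichment(
            scenario.network, scenario.pathways, inp, "ora",
            EnrichmentParams(bh=True), seed=0,
        )
        assert "p_adjusted" in res.table
        assert (res.table["p_adjusted"] >= res.table["pvalue"] - 1e-12).all()

    def test_unknown_method_rejected(self, scenario):
        inp = InputGeneSet.from_genes(scenario.modules["PLANTED_01"])
        with pytest.raises(ValueError):
            run_enrichment(scenario.network, scenario.pathways, inp, "gsea")

    def test_netpea_prime_needs_rewired_networks(self, scenario):
        inp = InputGeneSet.from_genes(scenario.modules["PLANTED_01"])
        with pytest.raises(ValueError):
            run_enrichment(
                scenario.network, scenario.pathways, inp, "netpea-prime",
                EnrichmentParams(n_perm=10, n_nets=0), seed=0,
            )
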
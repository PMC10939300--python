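"""Enrichment methods: exact tests, crosstalk nulls, conventions, batteries."""

import math

import numpy as np
import pytest

from eabench.containers import FunctionalNetwork, GeneSetCollection, ValidationError
from eabench.methods import (
    crosstalk_binomial,
    crosstalk_hypergeom,
    derive_degs,
    ease_enrichment,
    fisher_enrichment,
    overlap_enrichment_profile,
    permutation_reference,
    permutation_reference_battery,
    run_battery,
    to_enrichment,
)
from eabench.synthetic import SyntheticSpec, make_expression


def hypergeom_tail_by_enumeration(k, M, K, N):
    """P(X >= k) for overlap of an N-draw with K successes out of M."""
    total = math.comb(M, N)
    return sum(
        math.comb(K, j) * math.comb(M - K, N - j)
        for j in range(k, min(K, N) + 1)
    ) / total


class TestFisherAndEase:
    def setup_method(self):
        self.universe = [f"x{i}" for i in range(20)]
        self.pathway = set(self.universe[:5])
        self.degs = set(self.universe[:5])

    def test_full_overlap_example(self):
        p = fisher_enrichment(self.degs, self.pathway, self.universe)
        assert p == pytest.approx(1 / math.comb(20, 5))

    def test_zero_overlap_gives_one(self):
        degs = set(self.universe[5:10])
        assert fisher_enrichment(degs, self.pathway, self.universe) == pytest.approx(1.0)

    def test_pathway_equals_universe_gives_one(self):
        assert fisher_enrichment(self.degs, set(self.universe), self.universe) == pytest.approx(1.0)

    def test_ease_subtracts_one_from_overlap(self):
        p = ease_enrichment(self.degs, self.pathway, self.universe)
        assert p == pytest.approx(76 / 15504)

    def test_ease_floor_at_zero_overlap(self):
        degs = set(self.universe[5:10])
        assert ease_enrichment(degs, self.pathway, self.universe) == pytest.approx(1.0)

    def test_fisher_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            M = int(rng.integers(5, 26))
            universe = [f"u{i}" for i in range(M)]
            K = int(rng.integers(1, M + 1))
            N = int(rng.integers(1, M + 1))
            pathway = set(rng.choice(universe, K, replace=False))
            degs = set(rng.choice(universe, N, replace=False))
            k = len(pathway & degs)
            expected = hypergeom_tail_by_enumeration(k, M, K, N)
            assert fisher_enrichment(degs, pathway, universe) == pytest.approx(expected)

    def test_ease_at_least_as_conservative_as_fisher(self):
        rng = np.random.default_rng(14)
        for _ in range(2000):
            M = int(rng.integers(5, 40))
            universe = [f"u{i}" for i in range(M)]
            pathway = set(rng.choice(universe, int(rng.integers(1, M + 1)), replace=False))
            degs = set(rng.choice(universe, int(rng.integers(1, M + 1)), replace=False))
            assert ease_enrichment(degs, pathway, universe) >= fisher_enrichment(
                degs, pathway, universe
            ) - 1e-12

    def test_profile_matches_scalar_calls(self):
        rng = np.random.default_rng(15)
        universe = [f"u{i}" for i in range(50)]
        collection = GeneSetCollection(
            {f"P{i}": frozenset(rng.choice(universe, 10, replace=False)) for i in range(5)}
        )
        degs = set(rng.choice(universe, 12, replace=False))
        for ease in (False, True):
            profile = overlap_enrichment_profile(degs, collection, universe, ease=ease)
            scalar = ease_enrichment if ease else fisher_enrichment
            for pid in collection.ids:
                assert profile[pid] == pytest.approx(
                    scalar(degs, set(collection[pid]), universe)
                )


class TestCrosstalk:
    def sparse_wired_net(self):
        net = FunctionalNetwork()
        # dense wiring between degs d* and pathway p*, sparse elsewhere
        for i in range(5):
            for j in range(5):
                net.add_edge(f"d{i}", f"p{j}")
        for i in range(20):
            net.add_edge(f"bg{i}", f"bg{i + 1}")
        return net

    def test_wired_degs_significant_not_depleted(self):
        net = self.sparse_wired_net()
        degs = {f"d{i}" for i in range(5)}
        pathway = {f"p{j}" for j in range(5)}
        p, depleted = crosstalk_hypergeom(degs, pathway, net)
        assert p < 0.01 and not depleted

    def test_no_links_between_dense_sets_flags_depletion(self):
        net = FunctionalNetwork()
        for i in range(6):
            for j in range(i + 1, 6):
                net.add_edge(f"a{i}", f"a{j}")
                net.add_edge(f"b{i}", f"b{j}")
        p, depleted = crosstalk_hypergeom(
            {f"a{i}" for i in range(6)}, {f"b{i}" for i in range(6)}, net
        )
        assert depleted

    def test_zero_degree_side_untested(self):
        net = self.sparse_wired_net()
        p, depleted = crosstalk_hypergeom({"isolated"}, {"p0"}, net)
        assert p == 1.0 and not depleted

    def test_relabeling_invariance(self):
        net = self.sparse_wired_net()
        degs = {f"d{i}" for i in range(5)}
        pathway = {f"p{j}" for j in range(5)}
        mapped = FunctionalNetwork(
            (u.upper(), v.upper(), w) for u, v, w in net.edges()
        )
        p1, _ = crosstalk_hypergeom(degs, pathway, net)
        p2, _ = crosstalk_hypergeom(
            {g.upper() for g in degs}, {g.upper() for g in pathway}, mapped
        )
        assert p1 == pytest.approx(p2)

    def test_binomial_variant_agrees_on_sign_of_depletion(self):
        net = self.sparse_wired_net()
        degs = {f"d{i}" for i in range(5)}
        pathway = {f"p{j}" for j in range(5)}
        p, depleted = crosstalk_binomial(degs, pathway, net)
        assert p < 0.05 and not depleted


class TestToEnrichment:
    @pytest.mark.parametrize(
        "p,depleted,expected",
        [(0.01, True, 0.99), (0.01, False, 0.01), (0.5, True, 0.5)],
    )
    def test_depletion_convention(self, p, depleted, expected):
        assert to_enrichment(p, depleted) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            to_enrichment(1.5, False)


class TestPermutationReference:
    def test_identical_sets_hit_the_floor(self):
        universe = [f"u{i}" for i in range(40)]
        pathway = set(universe[:10])
        p = permutation_reference(pathway, pathway, universe, n=500,
                                  rng=np.random.default_rng(0))
        assert p < 0.02

    def test_single_permutation_two_point_grid(self):
        universe = [f"u{i}" for i in range(10)]
        rng = np.random.default_rng(1)
        values = {
            permutation_reference(set(universe[:3]), set(universe[:3]), universe, n=1, rng=rng)
            for _ in range(20)
        }
        assert values <= {0.5, 1.0}

    def test_null_pvalues_calibrated(self):
        """Random DEG labels give ~5% of p-values below 0.05 (pooled)."""
        rng = np.random.default_rng(42)
        m = 2000
        genes = [f"g{i:04d}" for i in range(m)]
        collection = GeneSetCollection(
            {
                f"P{i}": frozenset(rng.choice(genes, size=int(s), replace=False))
                for i, s in enumerate(rng.integers(200, 401, size=10))
            }
        )
        below = 0
        total = 0
        for _ in range(100):
            degs = set(rng.choice(genes, size=int(rng.integers(300, 801)), replace=False))
            ps = permutation_reference_battery(degs, collection, genes, n=999, rng=rng)
            below += sum(1 for p in ps.values() if p < 0.05)
            total += len(ps)
        assert below / total == pytest.approx(0.05, abs=0.015)

    def test_battery_consistent_with_scalar(self):
        rng = np.random.default_rng(3)
        universe = [f"u{i}" for i in range(300)]
        collection = GeneSetCollection(
            {"P0": frozenset(universe[:80]), "P1": frozenset(universe[100:160])}
        )
        degs = set(rng.choice(universe, 100, replace=False))
        battery = permutation_reference_battery(degs, collection, universe, n=4000, rng=rng)
        for pid in collection.ids:
            scalar = permutation_reference(
                degs, set(collection[pid]), universe, n=4000,
                rng=np.random.default_rng(7),
            )
            assert battery[pid] == pytest.approx(scalar, abs=0.05)


class TestRunBattery:
    @pytest.fixture()
    def battery_inputs(self, small_study):
        net, collection, truth = small_study
        spec = SyntheticSpec(
            seed=17, n_genes=500, effect_size=3.0, frac_de_background=0.1,
            pathway_size_range=(15, 30),
        )
        datasets = [
            make_expression(spec, truth[0][0], collection, dataset_id=f"d{i}")
            for i in range(3)
        ]
        return net, collection, datasets

    def test_shape_contract(self, battery_inputs):
        net, collection, datasets = battery_inputs
        results = run_battery(["fisher", "ease"], datasets, collection, net)
        assert set(results) == {"fisher", "ease"}
        for matrix in results.values():
            assert matrix.pvalues.shape == (len(collection), 3)

    def test_identical_datasets_identical_columns(self, battery_inputs):
        net, collection, datasets = battery_inputs
        results = run_battery(["fisher"], datasets, collection, net)
        cols = results["fisher"].pvalues
        # all three datasets share the same generator output per dataset_id salt;
        # d0 is deterministic, so rerunning gives identical columns
        rerun = run_battery(["fisher"], datasets, collection, net)["fisher"].pvalues
        assert cols.equals(rerun)

    def test_failing_dataset_left_untested(self, small_study):
        net, collection, _ = small_study
        spec = SyntheticSpec(
            seed=99, n_genes=500, effect_size=0.0,
            frac_de_target=0.0, frac_de_background=0.0,
        )
        null_ds = make_expression(spec, collection.ids[0], collection, dataset_id="flat")
        results = run_battery(["fisher"], [null_ds], collection, net)
        matrix = results["fisher"]
        assert (matrix.pvalues["flat"] == 1.0).all()
        assert not matrix.tested["flat"].any()

    def test_unknown_method_rejected(self, battery_inputs):
        net, collection, datasets = battery_inputs
        with pytest.raises(ValidationError):
            run_battery(["voodoo"], datasets, collection, net)


class TestDeriveDegs:
    def test_signal_dataset_yields_degs(self, small_study):
        _, collection, truth = small_study
        spec = SyntheticSpec(
            seed=17, n_genes=500, effect_size=3.0, frac_de_background=0.1,
        )
        ds = make_expression(spec, truth[0][0], collection, dataset_id="sig")
        result = derive_degs(ds)
        assert not hasattr(result, "reason")
        assert 15 <= len(result.genes) <= 500
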
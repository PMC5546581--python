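"""Permutation p-values, interaction and enrichment scores, pass/fail logic."""

import numpy as np
import pytest

from walkscreen.exceptions import ConfigurationError, ConsistencyError, LookupError_
from walkscreen.network import build_transition_matrix
from walkscreen.rwr import (
    RWRGeneSet,
    SeedSet,
    make_initial_vector,
    map_seeds,
    rwr_propagate,
    select_rwr_genes,
)
from walkscreen.screening import (
    GeneScreenRecord,
    PermutationConfig,
    ScreenThresholds,
    apply_screens,
    direction_cosine,
    max_enrichment_score,
    max_interaction_score,
    permutation_pvalues,
)
from walkscreen.synthetic import PlantedModuleSpec, generate_planted_network

from conftest import make_network, rwr_linear_solve


@pytest.fixture(scope="module")
def planted():
    spec = PlantedModuleSpec(n_nodes=60, p_within=0.3, p_between=0.05, n_seeds=5, rng_seed=4)
    net, seeds, labels = generate_planted_network(spec)
    T = build_transition_matrix(net)
    res = rwr_propagate(T, make_initial_vector(seeds, net), restart_prob=0.8, tolerance=1e-10)
    genes = select_rwr_genes(res, seeds, net, threshold=1e-5)
    return net, T, seeds, res, genes


class TestPermutation:
    def test_pvalues_match_independent_replay(self, planted):
        """The streamed counters agree with an independent replay that uses
        the same RNG draws but the dense linear-solve walk oracle."""
        net, T, seeds, res, genes = planted
        cfg = PermutationConfig(n_permutations=40, seed_set_size=len(seeds), rng_seed=77)
        pvals = permutation_pvalues(T, net, res, genes, cfg, progress_every=0)

        rng = np.random.default_rng(77)
        gene_idx = {g: net.node_index[g] for g in genes.gene_ids}
        exceed = {g: 0 for g in genes.gene_ids}
        for _ in range(40):
            chosen = rng.choice(np.arange(len(net)), size=len(seeds), replace=False)
            p0 = np.zeros(len(net))
            p0[chosen] = 1.0 / len(seeds)
            perm = rwr_linear_solve(net, p0, 0.8)
            for g, i in gene_idx.items():
                if perm[i] > res.probabilities[i]:
                    exceed[g] += 1
        for g in genes.gene_ids:
            assert pvals[g] == pytest.approx(exceed[g] / 40, abs=0.051), g
        # granularity: every p-value is k/n
        assert all(round(p * 40, 6) == round(p * 40) for p in pvals.values())

    def test_reproducible_bit_for_bit(self, planted):
        net, T, seeds, res, genes = planted
        cfg = PermutationConfig(n_permutations=25, seed_set_size=len(seeds), rng_seed=3)
        p1 = permutation_pvalues(T, net, res, genes, cfg, progress_every=0)
        p2 = permutation_pvalues(T, net, res, genes, cfg, progress_every=0)
        assert p1 == p2

    def test_never_exceeded_gene_gets_zero_pvalue(self):
        """A node whose real probability beats every permutation has p = 0."""
        edges = [("S", "X", 1000)]
        clique = [f"Q{i}" for i in range(8)]
        for i, a in enumerate(clique):
            for b in clique[i + 1:]:
                edges.append((a, b, 100))
        edges.append(("X", "Q0", 1))
        net = make_network(edges)
        T = build_transition_matrix(net)
        seeds = map_seeds(["S"], net)
        res = rwr_propagate(T, make_initial_vector(seeds, net), restart_prob=0.8, tolerance=1e-12)
        # track S itself: its real probability (~0.8, restart mass) cannot be
        # reached by any random single-seed set that excludes S
        genes = RWRGeneSet(
            entries=[("S", float(res.probabilities[net.node_index["S"]]))], threshold=0.0
        )
        cfg = PermutationConfig(n_permutations=30, seed_set_size=1, rng_seed=1, exclude_real_seeds=True)
        pvals = permutation_pvalues(T, net, res, genes, cfg, seeds=seeds, progress_every=0)
        assert pvals["S"] == 0.0

    def test_conservative_estimator_never_zero(self, planted):
        net, T, seeds, res, genes = planted
        cfg = PermutationConfig(
            n_permutations=10, seed_set_size=len(seeds), rng_seed=0, conservative=True
        )
        pvals = permutation_pvalues(T, net, res, genes, cfg, progress_every=0)
        assert min(pvals.values()) >= 1 / 11

    def test_null_pvalue_bulk_is_centered(self):
        """With random 'real' seeds the p-value distribution has a uniform
        bulk (median near 1/2), though self-draws floor the left tail."""
        spec = PlantedModuleSpec(rng_seed=0)
        net, _, _ = generate_planted_network(spec)
        rng = np.random.default_rng(1)
        ids = tuple(sorted(rng.choice(net.nodes, size=10, replace=False).tolist()))
        seeds = SeedSet(ids, ids, ())
        T = build_transition_matrix(net)
        res = rwr_propagate(T, make_initial_vector(seeds, net))
        genes = select_rwr_genes(res, seeds, net, 1e-5)
        cfg = PermutationConfig(n_permutations=200, seed_set_size=10, rng_seed=2)
        pvals = np.array(list(permutation_pvalues(T, net, res, genes, cfg, progress_every=0).values()))
        assert 0.3 < np.median(pvals) < 0.7

    def test_bad_configs_rejected(self, planted):
        net, T, seeds, res, genes = planted
        with pytest.raises(ConfigurationError):
            PermutationConfig(n_permutations=0, seed_set_size=5)
        with pytest.raises(ConfigurationError):
            permutation_pvalues(
                T, net, res, genes,
                PermutationConfig(n_permutations=5, seed_set_size=len(net) + 1),
            )


class TestInteractionScore:
    def test_no_seed_edge_gives_zero_none(self):
        net = make_network([("X", "Y", 500), ("P", "Q", 500)])
        seeds = map_seeds(["P", "Q"], net)
        assert max_interaction_score("X", seeds, net) == (0.0, None)

    def test_max_selection(self):
        net = make_network([("X", "P", 850), ("X", "Q", 910)])
        seeds = map_seeds(["P", "Q"], net)
        assert max_interaction_score("X", seeds, net) == (910.0, "Q")

    def test_tie_goes_to_lexicographically_smallest_seed(self):
        net = make_network([("X", "P", 900), ("X", "M", 900)])
        seeds = map_seeds(["P", "M"], net)
        assert max_interaction_score("X", seeds, net) == (900.0, "M")

    def test_unknown_gene_raises(self):
        net = make_network([("A", "B", 10)])
        with pytest.raises(LookupError_):
            max_interaction_score("zzz", map_seeds(["A"], net), net)


class TestEnrichmentScore:
    def _seeds(self, *ids):
        return SeedSet(tuple(sorted(ids)), tuple(sorted(ids)), ())

    def test_identical_vectors_score_one(self):
        v = {"g": np.array([1.0, 2.0, 0.0]), "s": np.array([1.0, 2.0, 0.0])}
        mes, partner = max_enrichment_score("g", self._seeds("s"), v)
        assert mes == pytest.approx(1.0)
        assert partner == "s"

    def test_orthogonal_vectors_score_zero(self):
        v = {"g": np.array([1.0, 0.0]), "s": np.array([0.0, 1.0])}
        assert max_enrichment_score("g", self._seeds("s"), v)[0] == 0.0

    def test_hand_computed_cosine(self):
        v = {"g": np.array([1.0, 1.0, 0.0]), "s": np.array([1.0, 1.0, 1.0])}
        mes, _ = max_enrichment_score("g", self._seeds("s"), v)
        assert mes == pytest.approx(2 / (np.sqrt(2) * np.sqrt(3)), abs=1e-12)
        assert mes == pytest.approx(0.8165, abs=1e-4)

    def test_unannotated_gene_scores_zero_with_warning(self, caplog):
        v = {"s": np.array([1.0])}
        with caplog.at_level("WARNING"):
            assert max_enrichment_score("g", self._seeds("s"), v) == (0.0, None)
        assert "no annotations" in caplog.text

    def test_tie_goes_to_lexicographically_smallest_seed(self):
        v = {
            "g": np.array([1.0, 0.0]),
            "sb": np.array([2.0, 0.0]),
            "sa": np.array([5.0, 0.0]),
        }
        assert max_enrichment_score("g", self._seeds("sa", "sb"), v)[1] == "sa"

    def test_cosine_symmetry_and_zero_convention(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            u, v = rng.random(6), rng.random(6)
            assert direction_cosine(u, v) == pytest.approx(direction_cosine(v, u))
        assert direction_cosine(np.zeros(3), np.ones(3)) == 0.0


class TestApplyScreens:
    def _genes(self, *entries):
        return RWRGeneSet(entries=list(entries), threshold=1e-5)

    def test_boundary_semantics(self):
        """MIS cutoff is inclusive; p-value and MES cutoffs are strict."""
        genes = self._genes(("g1", 2e-4), ("g2", 3e-4), ("g3", 1e-4))
        pv = {"g1": 0.04, "g2": 0.05, "g3": 0.04}
        mis = {"g1": (900.0, "s"), "g2": (999.0, "s"), "g3": (900.0, "s")}
        mes = {"g1": (0.81, "s"), "g2": (0.95, "s"), "g3": (0.8, "s")}
        recs = {r.node_id: r for r in apply_screens(genes, pv, mis, mes, ScreenThresholds())}
        assert recs["g1"].inferred  # 900 passes the inclusive MIS cutoff
        assert not recs["g2"].inferred and not recs["g2"].passed_permutation  # p == 0.05 fails
        assert not recs["g3"].inferred and not recs["g3"].passed_mes  # MES == 0.8 fails

    def test_missing_score_map_entry_raises(self):
        genes = self._genes(("g1", 2e-4))
        with pytest.raises(ConsistencyError):
            apply_screens(genes, {}, {"g1": (0, None)}, {"g1": (0, None)})

    def test_records_cover_all_candidates_and_conjunction(self, planted):
        net, T, seeds, res, genes = planted
        cfg = PermutationConfig(n_permutations=50, seed_set_size=len(seeds), rng_seed=8)
        pv = permutation_pvalues(T, net, res, genes, cfg, progress_every=0)
        mis = {g: max_interaction_score(g, seeds, net) for g in genes.gene_ids}
        mes = {g: (0.9, "s") for g in genes.gene_ids}
        recs = apply_screens(genes, pv, mis, mes)
        assert len(recs) == len(genes)
        inferred = {r.node_id for r in recs if r.inferred}
        passers = {r.node_id for r in recs if r.passed_permutation}
        assert inferred <= passers <= set(genes.gene_ids)
        for r in recs:
            assert r.inferred == (r.passed_permutation and r.passed_mis and r.passed_mes)
            assert 0.0 <= r.mis <= 1000.0
            assert 0.0 <= r.mes <= 1.0

    def test_threshold_invariants(self):
        with pytest.raises(ConfigurationError):
            ScreenThresholds(mis_min=1200)
        with pytest.raises(ConfigurationError):
            ScreenThresholds(mes_min=1.5)
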
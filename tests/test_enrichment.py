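"""Fisher/EASE enrichment statistics and multiple-testing control."""

import dataclasses
import math

import numpy as np
import pytest

from mbnet import dpcluso as dp
from mbnet import enrichment as en
from mbnet import mapping, network, synth
from mbnet.enrichment import ContingencyCounts as CC


def brute_force_tail(k, K, n, N):
    """P(X >= k) by direct hypergeometric mass summation."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


def random_tables(rng, count, n_max=60):
    for _ in range(count):
        N = int(rng.integers(2, n_max + 1))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        yield CC(k=k, K=K, n=n, N=N)


class TestFisherGreater:
    def test_zero_overlap_gives_one(self):
        assert en.fisher_greater(CC(k=0, K=5, n=3, N=20)) == 1.0

    def test_saturated_overlap_closed_form(self):
        # k = n = K: the only favourable draw is all n query genes
        # inside the annotated set.
        c = CC(k=4, K=4, n=4, N=30)
        expected = math.comb(4, 4) * math.comb(26, 0) / math.comb(30, 4)
        assert en.fisher_greater(c) == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        for c in random_tables(rng, 100):
            assert en.fisher_greater(c) == pytest.approx(
                brute_force_tail(c.k, c.K, c.n, c.N), abs=1e-10
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            CC(k=5, K=3, n=4, N=10)
        with pytest.raises(ValueError):
            CC(k=1, K=11, n=4, N=10)


class TestEase:
    def test_single_gene_overlap_never_significant(self):
        assert en.ease_p(CC(k=1, K=8, n=5, N=40)) == 1.0

    def test_zero_overlap_is_one(self):
        assert en.ease_p(CC(k=0, K=8, n=5, N=40)) == 1.0

    def test_equals_fisher_with_discounted_overlap(self):
        rng = np.random.default_rng(2)
        for c in random_tables(rng, 50):
            expected = en.fisher_greater(
                CC(k=max(c.k - 1, 0), K=c.K, n=c.n, N=c.N)
            )
            assert en.ease_p(c) == expected

    def test_dominates_fisher(self):
        rng = np.random.default_rng(3)
        for c in random_tables(rng, 100):
            assert en.ease_p(c) >= en.fisher_greater(c) - 1e-15


def stepup_bh(pvalues):
    """Independent BH step-up: q_(i) = min_{j>=i} p_(j) m / j, in input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = running
    return adjusted


class TestCorrections:
    def test_bonferroni_examples(self):
        assert en.bonferroni([0.01]).tolist() == [0.01]
        assert en.bonferroni([0.4, 0.4, 0.4]).tolist() == [1.0, 1.0, 1.0]
        assert en.bonferroni([0.01, 0.2]).tolist() == [0.02, 0.4]

    def test_bh_stepup_example(self):
        out = en.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bh_single_p_unchanged(self):
        assert en.bh_fdr([0.3]) == pytest.approx([0.3])

    def test_bh_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        p = rng.random(20)
        perm = rng.permutation(20)
        assert en.bh_fdr(p[perm]) == pytest.approx(en.bh_fdr(p)[perm])

    def test_bh_matches_independent_stepup(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            assert en.bh_fdr(p) == pytest.approx(stepup_bh(list(p)), abs=1e-12)

    def test_out_of_range_pvalues_rejected(self):
        with pytest.raises(ValueError):
            en.bonferroni([1.2])
        with pytest.raises(ValueError):
            en.bh_fdr([-0.1])


class TestScoreClusters:
    @staticmethod
    def _run_from_clusters(clusters, d_in=0.5):
        params = dp.ClusterParams(d_in=d_in)
        return dp.ClusteringRun(
            params=params,
            clusters=[
                dp.Cluster(id=i + 1, nodes=frozenset(c), density=1.0,
                           seed_node=min(c))
                for i, c in enumerate(clusters)
            ],
        )

    def test_disjoint_cluster_not_significant(self):
        run = self._run_from_clusters([{"a", "b", "c"}])
        (sig,) = en.score_clusters(run, {"x"}, {"a", "b", "c", "x"})
        assert sig.p == 1.0 and not sig.significant

    def test_disease_equals_background_degenerate(self):
        bg = {"a", "b", "c", "d"}
        run = self._run_from_clusters([{"a", "b"}])
        (sig,) = en.score_clusters(run, bg, bg)
        assert sig.p == 1.0

    def test_corrections_ordered_within_family(self):
        rng = np.random.default_rng(6)
        bg = [f"P{i}" for i in range(40)]
        disease = set(bg[:10])
        clusters = [set(rng.choice(bg, size=6, replace=False)) for _ in range(8)]
        sigs = en.score_clusters(self._run_from_clusters(clusters), disease, bg)
        for s in sigs:
            assert s.p <= s.p_bonferroni + 1e-15
            assert s.p <= s.fdr + 1e-15
            assert s.p_bonferroni <= 1.0 and s.fdr <= 1.0

    def test_background_violation_rejected(self):
        run = self._run_from_clusters([{"a", "b"}])
        with pytest.raises(ValueError):
            en.score_clusters(run, {"a"}, {"a"})

    def test_null_type_one_error_calibrated(self):
        # Disease genes drawn uniformly at random: the one-sided Fisher
        # test on discrete tables is conservative, so the raw-p<0.05
        # fraction must not exceed 0.05 by more than 3 standard errors.
        rng = np.random.default_rng(7)
        bg = [f"P{i}" for i in range(40)]
        clusters = [set(rng.choice(bg, size=int(s), replace=False))
                    for s in rng.integers(3, 9, size=5)]
        run = self._run_from_clusters(clusters)
        reps, hits, tests = 400, 0, 0
        for _ in range(reps):
            disease = set(rng.choice(bg, size=8, replace=False))
            for s in en.score_clusters(run, disease, bg):
                tests += 1
                hits += s.p < 0.05
        rate = hits / tests
        se = math.sqrt(0.05 * 0.95 / tests)
        assert rate <= 0.05 + 3 * se

    def test_planted_disease_modules_attain_lower_fdr(self, demo_config):
        # With disease genes planted at odds ratio 10 inside disease
        # modules, module-dominated clusters must show systematically
        # lower FDR than distractor clusters (pooled over seeds).
        planted, background = [], []
        for seed in range(1, 9):
            cfg = dataclasses.replace(demo_config, seed=seed)
            data = synth.generate_all(cfg)
            truth = data.truth
            seeds = mapping.SeedSets(scz=truth.seed_scz, bd=truth.seed_bd)
            net = network.build_network(data.interactions, seeds)
            nodes = sorted(net.nodes)
            reference = truth.disease_genes & set(nodes)
            run = dp.dpcluso(net, dp.ClusterParams(d_in=0.1))
            sigs = {s.cluster_id: s for s in
                    en.score_clusters(run, reference, nodes)}
            dm = truth.disease_module_nodes
            for c in run.clusters:
                if c.size < 2:
                    continue
                share = len(c.nodes & dm) / c.size
                (planted if share >= 0.5 else background).append(sigs[c.id].fdr)
        assert np.median(planted) < np.median(background)


class TestEnrichPathways:
    BG = [f"G{i}" for i in range(30)]

    def test_count_below_threshold_excluded(self):
        cluster = {"G0", "G1", "G2"}
        pathways = {"pw": frozenset({"G0"})}
        assert en.enrich_pathways(1, cluster, pathways, self.BG) == []

    def test_pathway_identical_to_cluster_ranks_first(self):
        cluster = {"G0", "G1", "G2", "G3"}
        pathways = {
            "exact": frozenset(cluster),
            "half": frozenset({"G0", "G1", "G10", "G11"}),
            "none": frozenset({"G20", "G21", "G22"}),
        }
        results = en.enrich_pathways(1, cluster, pathways, self.BG)
        assert results and results[0].pathway_id == "exact"
        assert results[0].count == 4

    def test_no_passing_pathway_is_empty_not_error(self):
        cluster = {"G0", "G1"}
        pathways = {"pw": frozenset({"G25", "G26", "G27"})}
        assert en.enrich_pathways(1, cluster, pathways, self.BG) == []

    def test_empty_gmt_rejected(self):
        with pytest.raises(ValueError):
            en.enrich_pathways(1, {"G0"}, {}, self.BG)
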
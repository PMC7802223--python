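import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cernakit import cerna_network as net
from cernakit.de_analysis import DERecord
from cernakit.errors import ConstantVectorError, InputError
from cernakit.target_prediction import TargetEdge


# --- independent oracles ----------------------------------------------------

def brute_spearman(x, y):
    """Explicit mid-rank + product-moment formulas."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mean_rank = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = mean_rank
            i = j + 1
        return ranks

    return brute_pearson(midranks(list(x)), midranks(list(y)))


def brute_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def brute_hypergeom_sf(k, K, n, N):
    """Exact enumeration with integer binomials."""
    total = math.comb(N, n)
    hits = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    )
    return hits / total


def de_stub(fid, cls, lfc=2.0):
    return DERecord(
        feature_id=fid,
        rna_class=cls,
        mean_expr_g1=10.0,
        mean_expr_g2=10.0 * 2**lfc,
        log2fc=lfc,
        p_value=0.001,
        q_value=0.01,
        direction="up" if lfc > 0 else "down",
        significant=True,
    )


# --- correlations -----------------------------------------------------------

class TestSpearman:
    def test_perfect_antimonotone(self):
        assert net.spearman_scc([1, 2, 3], [6, 5, 4]) == -1.0

    def test_worked_value(self):
        assert net.spearman_scc([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(
            0.6, abs=1e-12
        )

    def test_rank_invariance(self):
        x = [0.3, 1.7, 2.2, 9.0, 4.4]
        y = [5.0, 3.0, 8.0, 1.0, 2.0]
        assert net.spearman_scc(x, y) == pytest.approx(
            net.spearman_scc([math.exp(v) for v in x], y), abs=1e-12
        )

    def test_constant_vector_signalled(self):
        with pytest.raises(ConstantVectorError):
            net.spearman_scc([1, 1, 1], [1, 2, 3])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 21))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        assert net.spearman_scc(x, y) == pytest.approx(
            brute_spearman(x, y), abs=1e-10
        )

    def test_ties_use_mid_ranks(self):
        x = [1.0, 1.0, 2.0, 3.0]
        y = [4.0, 5.0, 6.0, 7.0]
        assert net.spearman_scc(x, y) == pytest.approx(
            brute_spearman(x, y), abs=1e-12
        )


class TestPearson:
    def test_affine(self):
        assert net.pearson_pcc([1, 2, 3], [3, 5, 7]) == 1.0

    def test_worked_value(self):
        assert net.pearson_pcc([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=6), rng.normal(size=6)
        assert net.pearson_pcc(x, y) == net.pearson_pcc(y, x)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(3, 21))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        assert net.pearson_pcc(x, y) == pytest.approx(
            brute_pearson(x, y), abs=1e-10
        )


# --- hypergeometric ---------------------------------------------------------

class TestHypergeomSf:
    def test_k_zero_is_one(self):
        assert net.hypergeom_sf(0, 5, 3, 10) == 1.0

    def test_single_term(self):
        assert net.hypergeom_sf(3, 3, 3, 6) == pytest.approx(0.05, abs=1e-14)

    def test_two_term_example(self):
        assert net.hypergeom_sf(2, 4, 3, 10) == pytest.approx(1 / 3, abs=1e-14)

    def test_bounds_enforced(self):
        with pytest.raises(InputError):
            net.hypergeom_sf(4, 3, 3, 6)
        with pytest.raises(InputError):
            net.hypergeom_sf(1, 7, 3, 6)

    def test_enumeration_oracle_small_universe(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert net.hypergeom_sf(k, K, n, N) == pytest.approx(
                            brute_hypergeom_sf(k, K, n, N), abs=1e-12
                        )

    def test_monotone_nonincreasing_in_k(self):
        for K, n, N in [(5, 4, 12), (8, 8, 12), (3, 9, 11)]:
            values = [net.hypergeom_sf(k, K, n, N) for k in range(min(K, n) + 1)]
            assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))


class TestSpongeTest:
    def test_disjoint_sets(self):
        r = net.sponge_test("c", "g", {"m1"}, {"m2"}, {"m1", "m2", "m3"})
        assert r.k == 0 and r.p_value == 1.0

    def test_identical_singletons(self):
        universe = {f"m{i}" for i in range(10)}
        r = net.sponge_test("c", "g", {"m0"}, {"m0"}, universe)
        assert r.k == r.K == r.n == 1
        assert r.p_value == pytest.approx(0.1, abs=1e-14)

    def test_delegates_to_hypergeom_sf(self):
        universe = {f"m{i}" for i in range(8)}
        set_c = {"m0", "m1", "m2"}
        set_g = {"m1", "m2", "m3", "m4"}
        r = net.sponge_test("c", "g", set_c, set_g, universe)
        assert r.p_value == net.hypergeom_sf(2, 3, 4, 8)

    def test_escaping_universe_rejected(self):
        with pytest.raises(InputError):
            net.sponge_test("c", "g", {"mX"}, {"mX"}, {"m1"})

    def test_null_calibration_conservative(self):
        rng = np.random.default_rng(77)
        universe = [f"m{i}" for i in range(30)]
        n_rep, hits = 2000, 0
        for _ in range(n_rep):
            set_c = set(rng.choice(universe, size=5, replace=False))
            set_g = set(rng.choice(universe, size=6, replace=False))
            r = net.sponge_test("c", "g", set_c, set_g, universe)
            hits += r.p_value < 0.05
        se = math.sqrt(0.05 * 0.95 / n_rep)
        assert hits / n_rep <= 0.05 + 3 * se


# --- pair screening ---------------------------------------------------------

def expr_frame(rows):
    return pd.DataFrame(rows).T  # dict of id -> vector


class TestNegativePairs:
    def setup_method(self):
        self.expr = pd.DataFrame(
            {
                "mir_a": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
                "circ_a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "gene_a": [1.1, 2.2, 3.0, 4.4, 5.0, 6.6],
                "circ_flat": [3.0, 3.0, 3.0, 3.0, 3.0, 3.0],
            }
        ).T
        self.edges = [
            TargetEdge("mir_a", "circ_a", "circRNA", "7mer-m8", 1),
            TargetEdge("mir_a", "gene_a", "mRNA", "8mer", 1),
            TargetEdge("mir_a", "circ_flat", "circRNA", "6mer", 1),
        ]

    def test_anticorrelated_target_pairs_retained(self):
        kept = net.negative_pairs(self.expr, self.edges)
        assert {(e.id_a, e.id_b) for e in kept} == {
            ("mir_a", "circ_a"),
            ("mir_a", "gene_a"),
        }
        for e in kept:
            assert e.coefficient < -0.7
            assert e.method == "spearman"

    def test_non_target_pair_excluded(self):
        kept = net.negative_pairs(self.expr, self.edges[:1])
        assert {(e.id_a, e.id_b) for e in kept} == {("mir_a", "circ_a")}

    def test_de_gate(self):
        kept = net.negative_pairs(self.expr, self.edges, de_ids={"mir_a", "circ_a"})
        assert {(e.id_a, e.id_b) for e in kept} == {("mir_a", "circ_a")}

    def test_boundary_scc_excluded(self):
        # ranks engineered so SCC is exactly -0.7: sum d^2 = 34, n = 5
        expr = pd.DataFrame(
            {
                "mir_b": [1.0, 2.0, 3.0, 4.0, 5.0],
                "circ_b": [5.0, 4.0, 1.0, 3.0, 2.0],
            }
        ).T
        assert net.spearman_scc(expr.loc["mir_b"], expr.loc["circ_b"]) == -0.7
        kept = net.negative_pairs(
            expr, [TargetEdge("mir_b", "circ_b", "circRNA", "8mer", 1)]
        )
        assert kept == []

    def test_constant_vector_pair_dropped_not_fatal(self):
        kept = net.negative_pairs(self.expr, self.edges)
        assert all(e.id_b != "circ_flat" for e in kept)

    def test_missing_feature_rejected(self):
        with pytest.raises(InputError, match="missing"):
            net.negative_pairs(
                self.expr, [TargetEdge("mir_zz", "circ_a", "circRNA", "6mer", 1)]
            )


class TestCoexpressedPairs:
    def setup_method(self):
        self.expr = pd.DataFrame(
            {
                "mir_a": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
                "circ_a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "gene_a": [1.1, 2.1, 3.0, 4.2, 5.1, 6.3],
                "gene_b": [6.0, 1.0, 5.0, 2.0, 4.0, 3.0],
            }
        ).T
        self.neg = net.negative_pairs(
            self.expr,
            [
                TargetEdge("mir_a", "circ_a", "circRNA", "8mer", 1),
                TargetEdge("mir_a", "gene_a", "mRNA", "8mer", 1),
            ],
        )

    def test_planted_pair_retained(self):
        kept = net.coexpressed_pairs(self.expr, self.neg)
        assert {(e.id_a, e.id_b) for e in kept} == {("circ_a", "gene_a")}
        assert kept[0].coefficient > 0.9
        assert kept[0].method == "pearson"

    def test_no_shared_mirna_no_candidates(self):
        neg = [e for e in self.neg if e.id_b == "circ_a"]
        assert net.coexpressed_pairs(self.expr, neg) == []

    def test_boundary_pcc_excluded(self):
        # mathematically exact PCC = 0.9 must fail the strict > 0.9 gate
        expr = pd.DataFrame(
            {
                "mir_x": [5.0, 4.0, 3.0, 2.0, 1.0],
                "circ_x": [-2.0, -1.0, 0.0, 1.0, 2.0],
                "gene_x": [-5.0, -1.0, 2.0, 1.0, 3.0],
            }
        ).T
        neg = net.negative_pairs(
            expr,
            [
                TargetEdge("mir_x", "circ_x", "circRNA", "8mer", 1),
                TargetEdge("mir_x", "gene_x", "mRNA", "8mer", 1),
            ],
        )
        assert {(e.id_a, e.id_b) for e in neg} == {
            ("mir_x", "circ_x"),
            ("mir_x", "gene_x"),
        }
        assert net.coexpressed_pairs(expr, neg) == []


# --- network assembly -------------------------------------------------------

def one_triad_inputs():
    expr = pd.DataFrame(
        {
            "mir_a": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            "circ_a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "gene_a": [1.1, 2.1, 3.0, 4.2, 5.1, 6.3],
        }
    ).T
    edges = [
        TargetEdge("mir_a", "circ_a", "circRNA", "8mer", 1),
        TargetEdge("mir_a", "gene_a", "mRNA", "8mer", 1),
    ]
    neg = net.negative_pairs(expr, edges)
    coexpr = net.coexpressed_pairs(expr, neg)
    universe = {f"m{i}" for i in range(30)} | {"mir_a"}
    sponge = [
        net.sponge_test("circ_a", "gene_a", {"mir_a"}, {"mir_a"}, universe)
    ]
    de_records = {
        "mir_a": de_stub("mir_a", "miRNA", -2.0),
        "circ_a": de_stub("circ_a", "circRNA", 2.0),
        "gene_a": de_stub("gene_a", "mRNA", 2.0),
    }
    return neg, coexpr, sponge, de_records


class TestBuildNetwork:
    def test_minimal_triad(self):
        neg, coexpr, sponge, de_records = one_triad_inputs()
        network = net.build_network(neg, coexpr, sponge, de_records)
        assert network.graph.number_of_nodes() == 3
        assert network.graph.number_of_edges() == 3
        assert len(network.triads) == 1
        t = network.triads[0]
        assert (t.circ_id, t.mirna_id, t.mrna_id) == ("circ_a", "mir_a", "gene_a")

    def test_sponge_gate_removes_triad(self):
        neg, coexpr, sponge, de_records = one_triad_inputs()
        network = net.build_network(
            neg, coexpr, sponge, de_records, sponge_p_cutoff=0.001
        )
        assert network.triads == []
        kinds = {d["kind"] for _, _, d in network.graph.edges(data=True)}
        assert "circ-mRNA" not in kinds

    def test_boundary_sponge_p_excluded(self):
        neg, coexpr, _, de_records = one_triad_inputs()
        # k=K=n=3, N=6 gives p = 1/C(6,3) = 0.05 exactly; strict < must fail
        mirnas = {"mir_a", "m1", "m2"}
        sponge = [
            net.sponge_test(
                "circ_a", "gene_a", mirnas, mirnas, mirnas | {"m3", "m4", "m5"}
            )
        ]
        network = net.build_network(neg, coexpr, sponge, de_records)
        assert network.triads == []

    def test_node_attributes_from_de_records(self):
        neg, coexpr, sponge, de_records = one_triad_inputs()
        network = net.build_network(neg, coexpr, sponge, de_records)
        assert network.graph.nodes["mir_a"]["rna_class"] == "miRNA"
        assert network.graph.nodes["mir_a"]["direction"] == "down"
        assert network.graph.nodes["circ_a"]["log2fc"] == 2.0

    def test_missing_de_record_rejected(self):
        neg, coexpr, sponge, de_records = one_triad_inputs()
        del de_records["gene_a"]
        with pytest.raises(InputError, match="gene_a"):
            net.build_network(neg, coexpr, sponge, de_records)

    def test_triads_match_brute_force_triple_loop(self, small_dataset):
        from cernakit import de_analysis as de
        from cernakit import target_prediction as tp

        ds = small_dataset
        logx = pd.concat(
            [
                de.log_expression(m)
                for m in (ds.counts_circ, ds.counts_mirna, ds.counts_mrna)
            ]
        )
        recs = {}
        for mat, th in (
            (ds.counts_circ, de.DEThresholds()),
            (ds.counts_mirna, de.DEThresholds()),
            (ds.counts_mrna, de.DEThresholds(use_fdr=True)),
        ):
            for r in de.run_de(mat, th):
                recs[r.feature_id] = r
        de_sig = {fid for fid, r in recs.items() if r.significant}
        edges, _ = tp.predict_targets(
            ds.mirna_seqs, ds.target_seqs, "7mer-A1", restrict_to=de_sig
        )
        neg = net.negative_pairs(logx, edges, de_ids=de_sig)
        coexpr = net.coexpressed_pairs(logx, neg)
        targeting = {}
        for e in edges:
            targeting.setdefault(e.target_id, set()).add(e.mirna_id)
        universe = sorted(set().union(*targeting.values()))
        sponge = [
            net.sponge_test(
                c.id_a, c.id_b, targeting[c.id_a], targeting[c.id_b], universe
            )
            for c in coexpr
        ]
        network = net.build_network(neg, coexpr, sponge, recs)

        # exhaustive oracle over every (circ, miRNA, mRNA) combination
        neg_set = {(e.id_a, e.id_b) for e in neg}
        pcc_ok = {(e.id_a, e.id_b) for e in coexpr}
        sponge_ok = {
            (r.circ_id, r.mrna_id) for r in sponge if r.p_value < 0.05
        }
        expected = set()
        circs = [r.id for r in ds.target_seqs if r.rna_class == "circRNA"]
        genes = [r.id for r in ds.target_seqs if r.rna_class == "mRNA"]
        mirs = [r.id for r in ds.mirna_seqs]
        for c, m, g in itertools.product(circs, mirs, genes):
            if (
                (m, c) in neg_set
                and (m, g) in neg_set
                and (c, g) in pcc_ok
                and (c, g) in sponge_ok
            ):
                expected.add((c, m, g))
        assert {
            (t.circ_id, t.mirna_id, t.mrna_id) for t in network.triads
        } == expected

        # structural invariants, by direct scan
        for e in neg:
            assert e.coefficient < -0.7
        for e in coexpr:
            assert e.coefficient > 0.9
        for t in network.triads:
            assert t.scc_circ_mirna < -0.7 and t.scc_mirna_mrna < -0.7
            assert t.pcc_circ_mrna > 0.9 and t.sponge_p < 0.05
        for u, v in network.graph.edges():
            assert u in network.graph.nodes and v in network.graph.nodes


class TestExtractSubnetwork:
    def build(self):
        neg, coexpr, sponge, de_records = one_triad_inputs()
        return net.build_network(neg, coexpr, sponge, de_records)

    def test_radius_zero(self):
        sub = net.extract_subnetwork(self.build(), "gene_a", radius=0)
        assert list(sub.graph.nodes) == ["gene_a"]
        assert sub.graph.number_of_edges() == 0
        assert sub.triads == []

    def test_radius_two_recovers_triad(self):
        sub = net.extract_subnetwork(self.build(), "gene_a", radius=2)
        assert set(sub.graph.nodes) == {"circ_a", "mir_a", "gene_a"}
        assert len(sub.triads) == 1

    def test_unknown_focal_id(self):
        with pytest.raises(KeyError):
            net.extract_subnetwork(self.build(), "nope")

    def test_degree_matches_bfs_oracle(self):
        network = self.build()
        g = network.graph
        for radius in (1, 2):
            sub = net.extract_subnetwork(network, "gene_a", radius=radius)
            # independent BFS on an adjacency list
            adj = {u: set(g.neighbors(u)) for u in g.nodes}
            frontier, seen = {"gene_a"}, {"gene_a"}
            for _ in range(radius):
                frontier = set().union(*(adj[u] for u in frontier)) - seen
                seen |= frontier
            assert set(sub.graph.nodes) == seen
            assert sub.graph.degree("gene_a") == len(adj["gene_a"] & seen)
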
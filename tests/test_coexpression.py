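"""Pearson correlation testing, network assembly and hub selection."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncnet import SimConfig, simulate_experiment
from lncnet.coexpression import (
    build_network,
    corr_pvalue,
    network_nodes,
    pearson_r,
    select_hubs,
)
from lncnet.de import bh_adjust
from lncnet.preprocess import filter_expressed, median_of_ratios


def direct_pearson(x, y):
    """Covariance/variance definition, computed independently."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return cov / (x.std() * y.std())


class TestPearson:
    def test_identity_and_anti_identity(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        x, y = [1, 2, 3, 4], [2, 4, 5, 9]
        assert pearson_r(x, y) == pytest.approx(direct_pearson(x, y), abs=1e-12)

    def test_zero_variance_marked_undefined(self):
        assert np.isnan(pearson_r([1, 1, 1], [1, 2, 3]))

    def test_rejects_short_or_mismatched(self):
        with pytest.raises(ValueError):
            pearson_r([1, 2], [3, 4])
        with pytest.raises(ValueError):
            pearson_r([1, 2, 3], [1, 2])


class TestCorrPvalue:
    def test_null_value(self):
        assert corr_pvalue(0.0, 10) == pytest.approx(1.0)

    def test_strong_correlation_small_n(self):
        assert corr_pvalue(0.99, 6) < 1e-3

    def test_extreme_r_convention(self):
        assert corr_pvalue(1.0, 5) == 0.0
        assert corr_pvalue(-1.0, 5) == 0.0

    def test_monotone_in_abs_r(self):
        ps = [corr_pvalue(r, 8) for r in np.linspace(0, 0.999, 30)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_matches_scipy_pearsonr_test(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r, p = stats.pearsonr(x, y)
        assert corr_pvalue(r, 12) == pytest.approx(p, rel=1e-9)


def _expr_from_profiles(profiles: dict, n=8, seed=9, noise=1e-3):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {f"s{j}": [profiles[g][j] + rng.normal(0, noise) for g in profiles] for j in range(n)},
        index=list(profiles),
    )


class TestBuildNetwork:
    def test_shared_profile_edge_present(self):
        base = np.array([1.0, 5.0, 2.0, 9.0, 4.0, 7.0, 3.0, 8.0])
        expr = _expr_from_profiles({"L1": base, "M1": 3 * base, "M2": np.arange(8.0)[::-1]})
        g = build_network(expr, ["L1"], ["M1", "M2"])
        assert g.has_edge("L1", "M1")
        assert not g.has_edge("L1", "M2")

    def test_null_noise_yields_no_edges(self):
        rng = np.random.default_rng(31)
        mu = rng.lognormal(3.5, 1.0, 600)
        lam = rng.gamma(5, 0.2 * mu[:, None] * np.ones((600, 8)))
        ids = [f"L{i}" for i in range(100)] + [f"M{i}" for i in range(500)]
        expr = pd.DataFrame(rng.poisson(lam), index=ids, columns=[f"s{j}" for j in range(8)])
        g = build_network(expr, ids[:100], ids[100:])  # 50,000 independent pairs
        assert g.number_of_edges() == 0

    def test_edges_match_brute_force_recount(self):
        sim = simulate_experiment(SimConfig(seed=7))
        norm, _ = median_of_ratios(filter_expressed(sim.counts))
        truth = sim.truth
        lnc = sorted(truth.de_ids("LNC") & set(norm.index))[:30]
        mrna = sorted(truth.de_ids("MRNA") & set(norm.index))[:60]
        cols = [c for c in norm.columns if sim.samples.loc[c, "time_h"] == 24]
        g = build_network(norm, lnc, mrna, samples=cols)
        # independent recount over every pair
        rs, ps, pairs = [], [], []
        for a, b in itertools.product(lnc, mrna):
            r = direct_pearson(norm.loc[a, cols], norm.loc[b, cols])
            rs.append(r)
            ps.append(corr_pvalue(r, len(cols)))
            pairs.append((a, b))
        qs = bh_adjust(ps)
        expected = {
            pair for pair, r, q in zip(pairs, rs, qs) if r >= 0.99 and q < 0.05
        }
        assert {tuple(sorted(e)) for e in g.edges()} == {
            tuple(sorted(p)) for p in expected
        }

    def test_bipartite_handshake(self, default_sim):
        sim = default_sim
        norm, _ = median_of_ratios(filter_expressed(sim.counts))
        truth = sim.truth
        g = build_network(
            norm,
            sorted(truth.de_ids("LNC") & set(norm.index)),
            sorted(truth.de_ids("MRNA") & set(norm.index)),
        )
        lnc_deg = sum(d for n, d in g.degree() if g.nodes[n]["biotype"] == "lncRNA")
        mrna_deg = sum(d for n, d in g.degree() if g.nodes[n]["biotype"] == "mRNA")
        assert lnc_deg == mrna_deg == g.number_of_edges()
        for u, v in g.edges():
            assert {g.nodes[u]["biotype"], g.nodes[v]["biotype"]} == {"lncRNA", "mRNA"}

    def test_gene_and_sample_order_invariance(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=8)
        expr = pd.DataFrame(
            {f"s{j}": rng.normal(size=10) for j in range(8)},
            index=[f"g{i}" for i in range(10)],
        )
        expr.iloc[0] = base
        expr.iloc[5] = base * 2 + rng.normal(0, 1e-6, 8)
        lnc, mrna = ["g0", "g1"], ["g5", "g6"]
        g1 = build_network(expr, lnc, mrna)
        g2 = build_network(expr.iloc[::-1, ::-1], lnc[::-1], mrna[::-1])
        assert set(map(frozenset, g1.edges())) == set(map(frozenset, g2.edges()))

    def test_module_recovery_improves_with_strength(self):
        """Recall of planted modules rises with module strength and the
        recovered edges are overwhelmingly within-module (high precision)."""
        recalls = []
        for strength in (0.5, 1.5, 3.0):
            sim = simulate_experiment(
                SimConfig(seed=13, module_strength=strength, n_mrna=500, n_lncrna=200)
            )
            norm, _ = median_of_ratios(sim.counts)
            mod = sim.truth.module_assignments
            lnc = sorted(g for g in mod if g.startswith("LNC"))
            mrna = sorted(g for g in mod if g.startswith("MRNA"))
            cols = [c for c in norm.columns if sim.samples.loc[c, "time_h"] == 24]
            g = build_network(norm, lnc, mrna, samples=cols)
            pairs = [(a, b) for a in lnc for b in mrna if mod[a] == mod[b]]
            recalls.append(sum(g.has_edge(a, b) for a, b in pairs) / len(pairs))
            if strength == 3.0:
                assert g.number_of_edges() > 0
                within = sum(1 for u, v in g.edges() if mod[u] == mod[v])
                assert within / g.number_of_edges() >= 0.9
        assert recalls[0] <= recalls[1] <= recalls[2]
        assert recalls[2] > recalls[0]

    def test_overlapping_biotypes_rejected(self):
        expr = pd.DataFrame(np.ones((2, 4)), index=["a", "b"], columns=list("wxyz"))
        with pytest.raises(ValueError):
            build_network(expr, ["a"], ["a"])


class TestSelectHubs:
    @staticmethod
    def _star_graph():
        g = nx.Graph()
        edges = [("a", "x"), ("a", "y"), ("a", "z"), ("a", "w"), ("b", "x"), ("b", "y"),
                 ("b", "z"), ("c", "x"), ("c", "y"), ("d", "x")]
        for u, v in edges:
            g.add_edge(u, v)
        return g

    def test_unambiguous_top_two(self):
        hubs = select_hubs(self._star_graph(), k=2)
        assert hubs.hubs["id"].tolist() == ["a", "x"]  # degrees 4 and 4 -> lexicographic

    def test_tie_break_lexicographic(self):
        g = nx.Graph([("b", "c"), ("a", "d")])  # all degree 1
        hubs = select_hubs(g, k=2)
        assert hubs.hubs["id"].tolist() == ["a", "b"]

    def test_top_fraction_ceiling(self):
        g = nx.empty_graph(0)
        g.add_edges_from((f"n{i:03d}", f"m{i:03d}") for i in range(100))
        # star it up so there are 365 nodes total
        g.add_edges_from((f"h{i:03d}", "n000") for i in range(165))
        assert g.number_of_nodes() == 365
        hubs = select_hubs(g, rule="top_fraction", fraction=0.05)
        assert hubs.k_effective == 19  # ceil(18.25)

    def test_sorted_by_degree_descending(self):
        hubs = select_hubs(self._star_graph(), k=8)
        degrees = hubs.hubs["degree"].tolist()
        assert degrees == sorted(degrees, reverse=True)

    def test_invalid_parameters(self):
        g = self._star_graph()
        with pytest.raises(ValueError):
            select_hubs(g, k=0)
        with pytest.raises(ValueError):
            select_hubs(g, rule="top_fraction", fraction=0.0)
        with pytest.raises(ValueError):
            select_hubs(nx.Graph(), k=1)
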
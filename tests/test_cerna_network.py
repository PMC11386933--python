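import numpy as np
import pandas as pd
import pytest

from cernet.cerna_network import (
    build_network,
    expression_table,
    extract_subnetwork,
    pearson,
    select_coexpressed,
    select_sponge_pairs,
    spearman,
    sponge_test,
)
from cernet.enrichment import hypergeometric_p
from cernet.errors import DomainError


def rank_then_pearson(x, y):
    """Independent oracle: average ranks, then the textbook Pearson formula."""
    def ranks(v):
        order = np.argsort(v)
        r = np.empty(len(v))
        i = 0
        sv = np.array(v, dtype=float)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            for k in range(i, j + 1):
                r[order[k]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


class TestCorrelations:
    def test_perfect_antimonotone(self):
        assert spearman(range(1, 7), range(6, 0, -1)) == pytest.approx(-1.0)

    def test_monotone_invariance(self):
        x = np.arange(1.0, 7.0)
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)

    def test_matches_rank_pearson_oracle(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [3, 1, 2, 6, 4, 5]
        assert spearman(x, y) == pytest.approx(rank_then_pearson(x, y))

    def test_ties_averaged(self):
        x = [1, 1, 2, 3, 3, 4]
        y = [2, 1, 4, 3, 6, 5]
        assert spearman(x, y) == pytest.approx(rank_then_pearson(x, y))

    def test_pearson_affine_and_negation(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_pearson_textbook_oracle(self):
        x = np.array([2.0, 4, 4, 4, 5, 7])
        y = np.array([1.0, 2, 3, 5, 4, 6])
        expected = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert pearson(x, y) == pytest.approx(expected)

    def test_constant_vector_gives_nan_sentinel(self):
        assert np.isnan(spearman([1, 1, 1, 1], [1, 2, 3, 4]))
        assert np.isnan(pearson([2, 2, 2, 2], [1, 2, 3, 4]))

    def test_short_vectors_rejected(self):
        with pytest.raises(DomainError):
            spearman([1, 2], [3, 4])


class TestSpongeTest:
    def _targets(self, pairs):
        return pd.DataFrame(
            [{"mirna_id": m, "target_id": t} for m, t in pairs],
            columns=["mirna_id", "target_id"],
        )

    def test_exact_small_urn(self):
        # K=10 miRNAs, circ targeted by 4, mRNA by 5, all 4 shared -> 6/252
        mirs = [f"m{i}" for i in range(10)]
        pairs = [(m, "c") for m in mirs[:4]] + [(m, "g") for m in mirs[:5]]
        res = sponge_test("c", "g", mirs, self._targets(pairs))
        assert (res.K, res.k1, res.k2, res.s) == (10, 4, 5, 4)
        assert res.pvalue == pytest.approx(6 / 252)

    def test_no_shared_mirnas_p_one(self):
        mirs = [f"m{i}" for i in range(10)]
        pairs = [("m0", "c"), ("m1", "g")]
        assert sponge_test("c", "g", mirs, self._targets(pairs)).pvalue == 1.0

    def test_circ_targeted_by_all_is_degenerate(self):
        mirs = [f"m{i}" for i in range(6)]
        pairs = [(m, "c") for m in mirs] + [(m, "g") for m in mirs[:3]]
        res = sponge_test("c", "g", mirs, self._targets(pairs))
        assert res.s == res.k2
        assert res.pvalue == 1.0

    def test_single_implementation_with_ora(self):
        # the sponge test is exactly the ORA tail probability
        mirs = [f"m{i}" for i in range(20)]
        pairs = [(m, "c") for m in mirs[:6]] + [(m, "g") for m in mirs[3:10]]
        res = sponge_test("c", "g", mirs, self._targets(pairs))
        assert res.pvalue == hypergeometric_p(N=20, n=7, M=6, m=3)


def _toy_state():
    """Hand-built expression with one real triplet and decoys."""
    rng = np.random.default_rng(0)
    base = np.array([1.0, 2, 3, 10, 11, 12])
    expr = {
        "c1": base + rng.normal(0, 0.01, 6),
        "g1": base + rng.normal(0, 0.01, 6),
        "m1": -base + rng.normal(0, 0.01, 6),
        "c2": base,  # anti-correlated with m1 but no predicted site
        "g2": rng.normal(0, 1, 6),  # uncorrelated
        "m2": base,  # positively correlated with c1: wrong sign
    }
    targets = pd.DataFrame(
        [
            {"mirna_id": "m1", "target_id": "c1"},
            {"mirna_id": "m1", "target_id": "g1"},
            {"mirna_id": "m2", "target_id": "c1"},
            {"mirna_id": "m1", "target_id": "g2"},
        ]
    )
    return expr, targets


class TestFilters:
    def test_sponge_pair_selection(self):
        expr, targets = _toy_state()
        pairs = select_sponge_pairs(
            ["c1", "c2"], ["g1", "g2"], ["m1", "m2"], expr, targets, 0.7
        )
        kept = set(zip(pairs["a_id"], pairs["b_id"]))
        assert ("c1", "m1") in kept and ("g1", "m1") in kept
        assert ("c2", "m1") not in kept  # anti-correlated but no site
        assert ("c1", "m2") not in kept  # site but positively correlated

    def test_coexpression_requires_shared_mirna_and_strict_pcc(self):
        expr, targets = _toy_state()
        sponge = select_sponge_pairs(
            ["c1", "c2"], ["g1", "g2"], ["m1", "m2"], expr, targets, 0.7
        )
        co = select_coexpressed(["c1", "c2"], ["g1", "g2"], expr, sponge, 0.9)
        assert set(zip(co["a_id"], co["b_id"])) == {("c1", "g1")}
        # strictness: a threshold equal to the achieved PCC excludes the pair
        achieved = co["pcc"].iloc[0]
        none = select_coexpressed(["c1"], ["g1"], expr, sponge, achieved)
        assert none.empty

    def test_missing_feature_is_lookup_error(self):
        expr, targets = _toy_state()
        with pytest.raises(DomainError, match="missing"):
            select_sponge_pairs(["absent"], [], ["m1"], expr, targets, 0.7)


class TestBuildNetwork:
    def test_empty_inputs_empty_network(self):
        empty_pairs = pd.DataFrame(columns=["a_id", "b_id", "kind", "scc", "n_samples"])
        empty_co = pd.DataFrame(columns=["a_id", "b_id", "kind", "pcc", "shared_mirnas", "n_samples"])
        net, triplets = build_network(
            empty_pairs, empty_co, pd.DataFrame(columns=["mirna_id", "target_id"]), ["m1"]
        )
        assert net.number_of_nodes() == 0 and triplets.empty

    def test_pipeline_triplets_satisfy_all_invariants(self, pipeline_run):
        triplets = pd.read_csv(pipeline_run["outdir"] / "triplets.tsv", sep="\t")
        assert len(triplets) > 0
        assert (triplets["scc_circ_mir"] < -0.7).all()
        assert (triplets["scc_mrna_mir"] < -0.7).all()
        assert (triplets["pcc_circ_mrna"] > 0.9).all()
        assert (triplets["sponge_p"] < 0.05).all()

    def test_every_edge_traces_to_a_triplet(self, default_sim):
        expr = expression_table([default_sim["circ"], default_sim["mir"], default_sim["mrna"]])
        truth = default_sim["truth"]
        targets = pd.DataFrame(
            [{"mirna_id": m, "target_id": t} for m, t, _ in truth.site_positions]
        )
        de_c, de_m, de_g = (truth.de_ids(c) for c in ("circRNA", "miRNA", "mRNA"))
        sponge = select_sponge_pairs(de_c, de_g, de_m, expr, targets, 0.7)
        co = select_coexpressed(de_c, de_g, expr, sponge, 0.9)
        universe = sorted({m for m, _, _ in truth.site_positions})
        net, triplets = build_network(sponge, co, targets, universe)
        accepted = {tuple(t) for t in triplets[["circ_id", "mirna_id", "mrna_id"]].itertuples(index=False)}
        for u, v, data in net.edges(data=True):
            assert data["triplets"]
            assert all(tuple(t) in accepted for t in data["triplets"])
            assert u != v

    def test_tightening_thresholds_never_adds_triplets(self, default_sim):
        expr = expression_table([default_sim["circ"], default_sim["mir"], default_sim["mrna"]])
        truth = default_sim["truth"]
        targets = pd.DataFrame(
            [{"mirna_id": m, "target_id": t} for m, t, _ in truth.site_positions]
        )
        de_c, de_m, de_g = (truth.de_ids(c) for c in ("circRNA", "miRNA", "mRNA"))
        universe = sorted({m for m, _, _ in truth.site_positions})

        def run(scc, pcc, alpha):
            sponge = select_sponge_pairs(de_c, de_g, de_m, expr, targets, scc)
            co = select_coexpressed(de_c, de_g, expr, sponge, pcc)
            _, trip = build_network(sponge, co, targets, universe, alpha)
            return {tuple(t) for t in trip[["circ_id", "mirna_id", "mrna_id"]].itertuples(index=False)}

        loose = run(0.7, 0.9, 0.05)
        assert run(0.8, 0.9, 0.05) <= loose
        assert run(0.7, 0.95, 0.05) <= loose
        assert run(0.7, 0.9, 0.01) <= loose


class TestSubnetwork:
    def test_absent_focus_is_empty(self, default_sim):
        import networkx as nx

        net = nx.Graph()
        net.add_edge("c", "m", triplets=[("c", "m", "g")])
        assert extract_subnetwork(net, "nope").number_of_nodes() == 0

    def test_single_triplet_identity(self):
        import networkx as nx

        net = nx.Graph()
        net.add_node("c", kind="circRNA")
        net.add_node("m", kind="miRNA")
        net.add_node("g", kind="mRNA")
        net.add_edge("c", "m", etype="circ_mir", triplets=[("c", "m", "g")])
        net.add_edge("m", "g", etype="mir_mrna", triplets=[("c", "m", "g")])
        sub = extract_subnetwork(net, "g")
        assert set(sub.nodes) == {"c", "m", "g"}
        assert sub.number_of_edges() == 2

    def test_shared_mrna_collects_all_its_circs(self):
        import networkx as nx

        net = nx.Graph()
        for i in range(3):
            trip = (f"c{i}", f"m{i}", "g")
            net.add_edge(f"c{i}", f"m{i}", etype="circ_mir", triplets=[trip])
            net.add_edge(f"m{i}", "g", etype="mir_mrna", triplets=[trip])
        net.add_edge("c9", "m9", etype="circ_mir", triplets=[("c9", "m9", "other")])
        sub = extract_subnetwork(net, "g")
        circs = {n for n in sub.nodes if n.startswith("c")}
        mirs = {n for n in sub.nodes if n.startswith("m")}
        assert circs == {"c0", "c1", "c2"}
        assert len(mirs) <= 3
        assert "c9" not in sub
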
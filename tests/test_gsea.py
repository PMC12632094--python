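import numpy as np
import pytest

from clsmeta.gsea import (
    GeneSet,
    GeneSetCollection,
    _order_by_statistic,
    cluster_leading_edges,
    preranked_gsea,
    read_gmt,
    running_enrichment_score,
    term_network,
    write_gmt,
)


def oracle_running_sum(genes_sorted, values, term, exponent=1.0):
    """Step-by-step transcription of the running-sum definition."""
    term = set(term)
    s = sum(1 for g in genes_sorted if g in term)
    nr = sum(abs(v) ** exponent for g, v in zip(genes_sorted, values) if g in term)
    if nr == 0:
        nr = 1.0
        weights = {g: 1.0 / s for g in term}
    else:
        weights = None
    run, cur = [], 0.0
    n = len(genes_sorted)
    for g, v in zip(genes_sorted, values):
        if g in term:
            cur += (weights[g] if weights else abs(v) ** exponent / nr)
        else:
            cur -= 1.0 / (n - s)
        run.append(cur)
    mx, mn = max(run), min(run)
    return (mx if mx >= -mn else mn), run


def collection(sets):
    return GeneSetCollection(
        sets={k: GeneSet(name=k, namespace="BP", genes=tuple(v)) for k, v in sets.items()}
    )


class TestRunningEnrichmentScore:
    def test_single_gene_at_top_exponent_zero(self):
        genes = [f"G{i}" for i in range(5)]
        rs = running_enrichment_score(genes, [5, 4, 3, 2, 1], {"G0"}, weight_exponent=0)
        assert rs.es == pytest.approx(1.0)
        assert rs.leading_edge == ["G0"]

    def test_hand_run_five_gene_list(self):
        genes = ["A", "B", "C", "D", "E"]
        values = [2.0, 1.0, 0.5, -1.0, -2.0]
        term = {"B", "D"}
        es_oracle, run_oracle = oracle_running_sum(genes, values, term, exponent=0)
        rs = running_enrichment_score(genes, values, term, weight_exponent=0)
        assert rs.es == pytest.approx(es_oracle, abs=1e-12)
        assert np.allclose(rs.running, run_oracle, atol=1e-12)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 101))
        genes = [f"G{i:03d}" for i in range(n)]
        stat = dict(zip(genes, rng.standard_normal(n)))
        ordered, values = _order_by_statistic(stat)
        size = int(rng.integers(1, n // 2))
        term = set(rng.choice(genes, size=size, replace=False))
        exponent = float(rng.integers(0, 2))
        es_oracle, _ = oracle_running_sum(ordered, values, term, exponent)
        rs = running_enrichment_score(ordered, values, term, exponent)
        assert rs.es == pytest.approx(es_oracle, abs=1e-12)

    def test_balanced_interleaving_bound(self):
        """A set hit at every k-th position cannot deviate beyond ~1/|S|."""
        n, s = 100, 10
        genes = [f"G{i}" for i in range(n)]
        term = {f"G{i}" for i in range(4, n, n // s)}
        rs = running_enrichment_score(genes, np.ones(n), term, weight_exponent=0)
        assert abs(rs.es) <= 1 / s + 1e-9

    def test_absent_term_raises(self):
        with pytest.raises(ValueError):
            running_enrichment_score(["A"], [1.0], {"Z"})


class TestPrerankedGsea:
    def test_size_filter_excludes_boundary(self, rng):
        genes = [f"G{i}" for i in range(200)]
        stat = dict(zip(genes, rng.standard_normal(200)))
        sets = collection({"small": genes[:9], "ok": genes[:10]})
        res = preranked_gsea(stat, sets, n_perm=100, seed=1)
        assert [r.term for r in res] == ["ok"]

    def test_planted_shifted_set_detected(self):
        rng = np.random.default_rng(17)
        n = 2000
        genes = [f"G{i:04d}" for i in range(n)]
        stat = rng.standard_normal(n)
        members = rng.choice(n, size=50, replace=False)
        stat[members] += 2.0  # +2 sd shift
        statistic = dict(zip(genes, stat))
        sets = {f"null{i}": list(rng.choice(genes, size=50, replace=False)) for i in range(10)}
        sets["planted"] = [genes[i] for i in members]
        res = preranked_gsea(statistic, collection(sets), n_perm=1000, seed=23)
        planted = next(r for r in res if r.term == "planted")
        assert planted.fdr < 0.05
        assert planted.direction == "long"
        assert planted.es > 0
        assert set(planted.leading_edge) <= set(sets["planted"])

    def test_all_equal_statistics_degenerate(self, rng):
        genes = [f"G{i}" for i in range(100)]
        stat = {g: 1.5 for g in genes}
        sets = collection({"s": genes[:20]})
        res = preranked_gsea(stat, sets, n_perm=100, seed=2)
        assert res[0].es == 0.0 and res[0].p_value == 1.0

    def test_sign_reversal_negates_es(self, rng):
        genes = [f"G{i}" for i in range(300)]
        values = rng.standard_normal(300)
        stat = dict(zip(genes, values))
        neg = dict(zip(genes, -values))
        sets = collection({f"s{i}": list(rng.choice(genes, 30, replace=False)) for i in range(5)})
        res_f = {r.term: r for r in preranked_gsea(stat, sets, n_perm=100, seed=3)}
        res_r = {r.term: r for r in preranked_gsea(neg, sets, n_perm=100, seed=3)}
        for term in res_f:
            assert res_f[term].es == pytest.approx(-res_r[term].es, abs=1e-12)
            assert {res_f[term].direction, res_r[term].direction} == {"long", "short"}

    def test_reproducible_given_seed(self, rng):
        genes = [f"G{i}" for i in range(200)]
        stat = dict(zip(genes, rng.standard_normal(200)))
        sets = collection({f"s{i}": list(rng.choice(genes, 20, replace=False)) for i in range(4)})
        r1 = preranked_gsea(stat, sets, n_perm=200, seed=9)
        r2 = preranked_gsea(stat, sets, n_perm=200, seed=9)
        assert [(r.term, r.es, r.p_value, r.nes) for r in r1] == [
            (r.term, r.es, r.p_value, r.nes) for r in r2
        ]

    def test_bh_fdr_monotone_and_at_least_p(self, rng):
        genes = [f"G{i}" for i in range(500)]
        stat = dict(zip(genes, rng.standard_normal(500)))
        sets = collection({f"s{i}": list(rng.choice(genes, 25, replace=False)) for i in range(20)})
        res = preranked_gsea(stat, sets, n_perm=200, seed=4)
        res_sorted = sorted(res, key=lambda r: r.p_value)
        fdrs = [r.fdr for r in res_sorted]
        assert all(r.fdr >= r.p_value - 1e-15 for r in res)
        assert fdrs == sorted(fdrs)

    def test_no_retained_sets_warns_and_returns_empty(self, rng):
        genes = [f"G{i}" for i in range(50)]
        stat = dict(zip(genes, rng.standard_normal(50)))
        with pytest.warns(UserWarning, match="size filter"):
            res = preranked_gsea(stat, collection({"tiny": genes[:3]}), n_perm=100, seed=1)
        assert res == []


def make_result(term, es=0.5, fdr=0.01):
    from clsmeta.gsea import GSEAResult

    return GSEAResult(
        term=term, name=term, namespace="BP", size=3, es=es, nes=1.5,
        p_value=0.001, fdr=fdr, direction="long" if es > 0 else "short",
        leading_edge=[],
    )


class TestTermNetwork:
    def test_identical_content_clusters_together(self):
        sets = collection({"t1": ["A", "B", "C"], "t2": ["A", "B", "C"]})
        net = term_network([make_result("t1"), make_result("t2")], sets)
        assert net.graph.edges["t1", "t2"]["ji"] == 1.0
        assert net.clusters["t1"] == net.clusters["t2"]

    def test_one_fifth_overlap_kept_at_default_threshold(self):
        sets = collection({"t1": ["A", "B", "C"], "t2": ["C", "D", "E"]})
        net = term_network([make_result("t1"), make_result("t2")], sets)
        assert net.graph.edges["t1", "t2"]["ji"] == pytest.approx(0.2)

    def test_exact_threshold_edge_excluded(self):
        # |A∩B|=1, |A∪B|=10 -> Ji = 0.1 exactly: strict > drops the edge
        sets = collection(
            {"t1": ["A", "B", "C", "D", "E", "F"], "t2": ["F", "G", "H", "I", "J"]}
        )
        net = term_network([make_result("t1"), make_result("t2")], sets)
        assert not net.graph.has_edge("t1", "t2")

    def test_cluster_named_after_largest_member(self):
        sets = collection({"big": ["A", "B", "C", "D"], "small": ["A", "B", "C"]})
        net = term_network([make_result("big"), make_result("small")], sets)
        assert set(net.clusters.values()) == {"big"}

    def test_cluster_leading_edges_union(self):
        sets = collection({"t1": ["A", "B"], "t2": ["B", "C"]})
        r1, r2 = make_result("t1"), make_result("t2")
        r1.leading_edge = ["A"]
        r2.leading_edge = ["B", "C"]
        net = term_network([r1, r2], sets)
        edges = cluster_leading_edges([r1, r2], net)
        assert set().union(*edges.values()) == {"A", "B", "C"}


class TestGmtRoundTrip:
    def test_read_write_read(self, tmp_path):
        coll = collection({"t1": ["A", "B"], "t2": ["C"]})
        p = tmp_path / "sets.gmt"
        write_gmt(coll, p)
        back = read_gmt(p)
        assert {t: gs.genes for t, gs in back.items()} == {
            t: gs.genes for t, gs in coll.items()
        }
        assert back.sets["t1"].namespace == "BP"
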
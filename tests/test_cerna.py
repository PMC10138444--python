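"""Correlation records, the two-step triad screen (vs a brute-force
triple loop), and network assembly."""

import numpy as np
import pytest
from scipy import stats

import networkx as nx

from cernapipe.cerna import (
    CeRNATriad,
    build_network,
    correlate,
    screen_triads,
    write_network,
)
from cernapipe.targeting import TargetHit

from conftest import make_matrix


# ----------------------------------------------------------- correlate

def test_correlate_examples():
    r = correlate([1, 2, 3], [2, 4, 6], "pearson")
    assert r.value == pytest.approx(1.0)
    assert correlate([1, 2, 3], [2, 4, 6], "spearman").value == pytest.approx(1.0)
    assert correlate([1, 2, 3], [6, 4, 2], "pearson").value == pytest.approx(-1.0)
    assert correlate([1, 2, 3], [6, 4, 2], "spearman").value == pytest.approx(-1.0)


def test_spearman_average_ranks_with_ties():
    r = correlate([1, 2, 2, 4], [10, 20, 20, 40], "spearman")
    # independent oracle: rank transform then product-moment
    rx, ry = stats.rankdata([1, 2, 2, 4]), stats.rankdata([10, 20, 20, 40])
    assert r.value == pytest.approx(np.corrcoef(rx, ry)[0, 1]) == pytest.approx(1.0)


def test_correlate_flags_constant_vectors():
    r = correlate([5, 5, 5], [1, 2, 3], "pearson")
    assert r.undefined and np.isnan(r.value)


def test_correlate_rejects_bad_input():
    with pytest.raises(ValueError):
        correlate([1, 2], [1, 2, 3], "pearson")
    with pytest.raises(ValueError):
        correlate([1, 2], [3, 4], "pearson")
    with pytest.raises(ValueError):
        correlate([1, 2, 3], [1, 2, 3], "kendall")


# -------------------------------------------------------- screen_triads

def _hit(mir, tgt, cls):
    return TargetHit(mir, tgt, cls, start=1, site_length=21, penalty=0.0)


def _exprs(rng, n_per_class=6, n_samples=12):
    out = {}
    ids = {}
    for cls, prefix in (("mRNA", "g"), ("lncRNA", "l"),
                        ("circRNA", "c"), ("miRNA", "x")):
        vals = rng.gamma(2.0, 50.0, size=(n_per_class, n_samples))
        gene_ids = [f"{prefix}{i}" for i in range(n_per_class)]
        out[cls] = make_matrix(vals, stages=("A", "B", "C", "D"), reps=3,
                               gene_ids=gene_ids, unit="FPKM")
        ids[cls] = gene_ids
    return out, ids


def _brute_force_screen(hits, de_sets, exprs, rho_max=-0.3, r_min=0.5):
    """Triple loop with direct scipy correlations."""
    pair_ok = {}
    for h in hits:
        if h.mirna_id not in de_sets["miRNA"] or \
                h.target_id not in de_sets[h.target_class]:
            continue
        x = exprs["miRNA"].row(h.mirna_id)
        y = exprs[h.target_class].row(h.target_id)
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        rho = stats.spearmanr(x, y).statistic
        if rho < rho_max:
            pair_ok[(h.mirna_id, h.target_id, h.target_class)] = rho
    found = set()
    for (mir1, cer, cls1), _ in pair_ok.items():
        if cls1 == "mRNA":
            continue
        for (mir2, mrna, cls2), _ in pair_ok.items():
            if cls2 != "mRNA" or mir2 != mir1:
                continue
            a = exprs[cls1].row(cer)
            b = exprs["mRNA"].row(mrna)
            if np.std(a) == 0 or np.std(b) == 0:
                continue
            if stats.pearsonr(a, b).statistic > r_min:
                found.add((cer, mir1, mrna))
    return found


def test_screen_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(17)
    for _ in range(25):
        exprs, ids = _exprs(rng)
        hits = []
        for cls in ("mRNA", "lncRNA", "circRNA"):
            for mir in ids["miRNA"]:
                for tgt in ids[cls]:
                    if rng.random() < 0.4:
                        hits.append(_hit(mir, tgt, cls))
        de_sets = {cls: set(rng.choice(ids[cls], size=4, replace=False))
                   for cls in ids}
        got = {t.key for t in screen_triads(hits, de_sets, exprs)}
        want = _brute_force_screen(hits, de_sets, exprs)
        assert got == want


def test_planted_noise_free_triad_retained():
    up = np.repeat([1.0, 4, 16, 64], 3)
    exprs = {
        "mRNA": make_matrix((up * 100)[None, :], stages="ABCD", reps=3,
                            gene_ids=["g0"], unit="FPKM"),
        "lncRNA": make_matrix((up * 7)[None, :], stages="ABCD", reps=3,
                              gene_ids=["l0"], unit="FPKM"),
        "circRNA": make_matrix(np.ones((1, 12)), stages="ABCD", reps=3,
                               gene_ids=["c0"], unit="FPKM"),
        "miRNA": make_matrix((up[::-1] * 9)[None, :], stages="ABCD", reps=3,
                             gene_ids=["x0"], unit="TPM"),
    }
    hits = [_hit("x0", "g0", "mRNA"), _hit("x0", "l0", "lncRNA")]
    de = {"mRNA": {"g0"}, "lncRNA": {"l0"}, "circRNA": set(), "miRNA": {"x0"}}
    triads = screen_triads(hits, de, exprs)
    assert [t.key for t in triads] == [("l0", "x0", "g0")]
    t = triads[0]
    assert t.rho_cerna_mirna == pytest.approx(-1.0)
    assert t.rho_mrna_mirna == pytest.approx(-1.0)
    assert t.r_cerna_mrna == pytest.approx(1.0)


def test_spearman_boundary_is_strict():
    """A pair with Spearman exactly -0.3 must be rejected."""
    # ranks chosen so that rank-Pearson is exactly -0.3: found by search
    x = np.array([1.0, 2, 3, 4, 5])
    y = np.array([4.0, 2, 5, 1, 3])
    rho = stats.spearmanr(x, y).statistic
    assert rho == -0.3
    exprs = {
        "mRNA": make_matrix(y[None, :] * 10, stages="ABCDE", reps=1,
                            gene_ids=["g0"], unit="FPKM"),
        "lncRNA": make_matrix(y[None, :] * 3, stages="ABCDE", reps=1,
                              gene_ids=["l0"], unit="FPKM"),
        "circRNA": make_matrix(np.ones((0, 5)), stages="ABCDE", reps=1,
                               gene_ids=[], unit="FPKM"),
        "miRNA": make_matrix(x[None, :], stages="ABCDE", reps=1,
                             gene_ids=["x0"], unit="TPM"),
    }
    hits = [_hit("x0", "g0", "mRNA"), _hit("x0", "l0", "lncRNA")]
    de = {"mRNA": {"g0"}, "lncRNA": {"l0"}, "circRNA": set(), "miRNA": {"x0"}}
    assert screen_triads(hits, de, exprs) == []


def test_pearson_step_rejects_weakly_coupled_partners():
    """A ceRNA that passes the Spearman step against the miRNA but has
    Pearson <= 0.5 with the mRNA is rejected by the second step."""
    mrna = np.arange(1.0, 13)
    mir = mrna[::-1]
    # monotone increasing (Spearman vs miRNA = -1) but one huge outlier
    # wrecks the linear correlation with the mRNA (r ~ 0.49)
    cer = np.concatenate([np.arange(1.0, 12), [1e3]])
    assert stats.spearmanr(cer, mir).statistic == -1.0
    assert stats.pearsonr(cer, mrna).statistic < 0.5
    exprs = {
        "mRNA": make_matrix(mrna[None, :], stages="ABCD", reps=3,
                            gene_ids=["g0"], unit="FPKM"),
        "lncRNA": make_matrix(cer[None, :], stages="ABCD", reps=3,
                              gene_ids=["l0"], unit="FPKM"),
        "circRNA": make_matrix(np.ones((0, 12)), stages="ABCD", reps=3,
                               gene_ids=[], unit="FPKM"),
        "miRNA": make_matrix(mir[None, :], stages="ABCD", reps=3,
                             gene_ids=["x0"], unit="TPM"),
    }
    hits = [_hit("x0", "g0", "mRNA"), _hit("x0", "l0", "lncRNA")]
    de = {"mRNA": {"g0"}, "lncRNA": {"l0"}, "circRNA": set(), "miRNA": {"x0"}}
    assert screen_triads(hits, de, exprs) == []


def test_tightening_thresholds_never_adds_triads():
    rng = np.random.default_rng(29)
    exprs, ids = _exprs(rng, n_per_class=8)
    hits = [_hit(m, t, cls) for cls in ("mRNA", "lncRNA", "circRNA")
            for m in ids["miRNA"] for t in ids[cls]]
    de = {cls: set(v) for cls, v in ids.items()}
    loose = {t.key for t in screen_triads(hits, de, exprs,
                                          rho_max=-0.1, r_min=0.2)}
    tight = {t.key for t in screen_triads(hits, de, exprs,
                                          rho_max=-0.3, r_min=0.5)}
    assert tight <= loose


# ------------------------------------------------------------- network

def _triad(cer, mir, mrna, cls="lncRNA"):
    return CeRNATriad(cer, cls, mir, mrna, -0.9, -0.9, 0.9)


def test_two_triads_sharing_a_mirna():
    net = build_network([_triad("l1", "x", "g1"), _triad("c1", "x", "g2",
                                                         cls="circRNA")])
    assert net.graph.number_of_nodes() == 5
    assert net.degree("x") == 4
    assert all(("x" in e) for e in net.graph.edges)  # bipartite via the miRNA


def test_empty_triads_give_empty_network():
    net = build_network([])
    assert net.graph.number_of_nodes() == 0
    assert net.summary()["n_components"] == 0


def test_graphml_round_trip(tmp_path):
    net = build_network([_triad("l1", "x1", "g1"), _triad("l2", "x2", "g2")])
    p = tmp_path / "net.graphml"
    write_network(net, p, tmp_path / "nodes.tsv", tmp_path / "edges.tsv")
    back = nx.read_graphml(p)
    assert set(back.nodes) == set(net.graph.nodes)
    assert {frozenset(e) for e in back.edges} == \
        {frozenset(e) for e in net.graph.edges}


def test_component_categories():
    hub = [_triad(f"l{i}", "xhub", f"g{i}") for i in range(6)]  # degree 12
    net = build_network(hub, hub_degree=10)
    assert list(net.categories.values()) == ["A"]
    multi = [_triad("l1", "x1", "g1"), _triad("l1", "x2", "g1"),
             _triad("l2", "x1", "g2"), _triad("l2", "x2", "g2")]
    net2 = build_network(multi, hub_degree=10)
    assert list(net2.categories.values()) == ["B"]
    simple = [_triad("l9", "x9", "g9")]
    net3 = build_network(simple)
    assert list(net3.categories.values()) == ["C"]
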
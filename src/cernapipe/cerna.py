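"""Two-step ceRNA correlation screen, network assembly and topology.

The screen takes predicted miRNA target pairs restricted to
differentially expressed molecules and keeps

1. (miRNA, target) pairs with Spearman rank correlation < -0.3 across
   all samples -- negatively co-expressed sponge/target candidates, then
2. (ceRNA, miRNA, mRNA) triads sharing the miRNA whose ceRNA-mRNA
   Pearson correlation is > 0.5 -- co-expressed partners competing for
   the same miRNA.

Both thresholds are strict; pairs with undefined (constant-vector)
correlations are dropped, not zeroed.  The resulting network is
bipartite by construction: every edge touches exactly one miRNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .targeting import TargetHit

logger = logging.getLogger(__name__)

RHO_MAX = -0.3  # Spearman threshold for miRNA-target pairs (strict <)
R_MIN = 0.5     # Pearson threshold for ceRNA-mRNA pairs (strict >)


@dataclass
class CorrelationRecord:
    id_a: str
    id_b: str
    method: str  # pearson | spearman
    value: float
    n: int
    undefined: bool = False


@dataclass
class CeRNATriad:
    cerna_id: str
    cerna_class: str  # lncRNA | circRNA
    mirna_id: str
    mrna_id: str
    rho_cerna_mirna: float
    rho_mrna_mirna: float
    r_cerna_mrna: float

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.cerna_id, self.mirna_id, self.mrna_id)


def correlate(x: Sequence[float], y: Sequence[float], method: str) -> CorrelationRecord:
    """Pearson or Spearman (average ranks) correlation of two sample vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if method == "spearman":
        x, y = stats.rankdata(x), stats.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationRecord("x", "y", method, float("nan"), x.size, True)
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationRecord("x", "y", method, r, x.size, False)


def _row_index(expr: ExpressionMatrix) -> dict[str, int]:
    return {g: i for i, g in enumerate(expr.gene_ids)}


def _center(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-centered matrix and per-row sums of squares.

    Correlations are computed as dot/sqrt(ssa*ssb) (not via
    pre-normalized rows) so boundary values like an exact -0.3 survive
    floating point unchanged; constant rows get ss = 0 -> NaN downstream.
    """
    c = rows - rows.mean(axis=1, keepdims=True)
    return c, (c * c).sum(axis=1)


def screen_triads(target_hits: Iterable[TargetHit],
                  de_sets: Mapping[str, set[str]],
                  expr_by_class: Mapping[str, ExpressionMatrix],
                  rho_max: float = RHO_MAX,
                  r_min: float = R_MIN) -> list[CeRNATriad]:
    """Two-step screen producing deduplicated, lexicographically ordered triads.

    ``target_hits`` supply the (miRNA, target) candidate pairs per
    class; ``de_sets`` maps each RNA class to its DE gene ids;
    ``expr_by_class`` holds one expression matrix per class, all over
    the same samples.
    """
    classes = ("mRNA", "lncRNA", "circRNA", "miRNA")
    cols = None
    for cls in classes:
        if cls not in expr_by_class:
            raise ValueError(f"missing expression matrix for {cls}")
        if cols is None:
            cols = expr_by_class[cls].columns
        elif expr_by_class[cls].columns != cols:
            raise ValueError("expression matrices must share the sample set")

    pairs: dict[str, set[tuple[str, str]]] = {"mRNA": set(), "lncRNA": set(),
                                              "circRNA": set()}
    for h in target_hits:
        if h.mirna_id in de_sets.get("miRNA", set()) and \
                h.target_id in de_sets.get(h.target_class, set()):
            pairs[h.target_class].add((h.mirna_id, h.target_id))

    idx = {cls: _row_index(expr_by_class[cls]) for cls in classes}
    ranks, raw = {}, {}
    for cls in classes:
        vals = expr_by_class[cls].values
        rk = (np.apply_along_axis(stats.rankdata, 1, vals)
              if expr_by_class[cls].n_genes else vals)
        ranks[cls] = _center(rk)
        raw[cls] = _center(vals)

    def _corr(store, cls_a, a, cls_b, b) -> float:
        ca, ssa = store[cls_a]
        cb, ssb = store[cls_b]
        va, sa = ca[idx[cls_a][a]], ssa[idx[cls_a][a]]
        vb, sb = cb[idx[cls_b][b]], ssb[idx[cls_b][b]]
        if sa == 0 or sb == 0:
            return float("nan")
        return float(va @ vb) / np.sqrt(sa * sb)

    def spearman(cls_a, a, cls_b, b) -> float:
        return _corr(ranks, cls_a, a, cls_b, b)

    # step 1: negatively co-expressed miRNA-target pairs
    kept: dict[str, dict[str, list[tuple[str, float]]]] = {}
    for cls in ("mRNA", "lncRNA", "circRNA"):
        kept[cls] = {}
        for mir, tgt in sorted(pairs[cls]):
            rho = spearman("miRNA", mir, cls, tgt)
            if not np.isfinite(rho):
                logger.info("dropping %s-%s: undefined Spearman", mir, tgt)
                continue
            if rho < rho_max:
                kept[cls].setdefault(mir, []).append((tgt, rho))

    # step 2: join on the shared miRNA, Pearson(ceRNA, mRNA) > r_min
    triads: dict[tuple[str, str, str], CeRNATriad] = {}
    for cer_cls in ("lncRNA", "circRNA"):
        for mir, cerna_list in kept[cer_cls].items():
            for cerna, rho_cm in cerna_list:
                for mrna, rho_mm in kept["mRNA"].get(mir, []):
                    r = _corr(raw, cer_cls, cerna, "mRNA", mrna)
                    if not np.isfinite(r):
                        logger.info("dropping %s-%s: undefined Pearson", cerna, mrna)
                        continue
                    if r > r_min:
                        triads[(cerna, mir, mrna)] = CeRNATriad(
                            cerna, cer_cls, mir, mrna, rho_cm, rho_mm, r)
    return [triads[k] for k in sorted(triads)]


@dataclass
class CeRNANetwork:
    graph: nx.Graph
    categories: dict[int, str] = field(default_factory=dict)  # component -> A/B/C

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def summary(self) -> dict:
        by_type: dict[str, int] = {}
        for _, d in self.graph.nodes(data=True):
            by_type[d["node_type"]] = by_type.get(d["node_type"], 0) + 1
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            "nodes_by_type": by_type,
            "n_components": nx.number_connected_components(self.graph),
            "categories": dict(sorted(self.categories.items())),
        }


def build_network(triads: Sequence[CeRNATriad],
                  hub_degree: int = 10,
                  multi_mrna: int = 2) -> CeRNANetwork:
    """Assemble the bipartite ceRNA network and label component topology.

    Component categories: ``A`` when the component's best-connected
    miRNA has degree >= ``hub_degree`` (a central sponge hub); ``B``
    when >= ``multi_mrna`` mRNAs each connect to >= 2 miRNAs (mRNAs
    coupled through several response elements); ``C`` otherwise (simple
    one/two-miRNA motifs).
    """
    g = nx.Graph()
    for t in triads:
        g.add_node(t.mirna_id, node_type="miRNA")
        g.add_node(t.mrna_id, node_type="mRNA")
        g.add_node(t.cerna_id, node_type=t.cerna_class)
        g.add_edge(t.mirna_id, t.mrna_id, edge_type="miRNA-mRNA")
        g.add_edge(t.mirna_id, t.cerna_id, edge_type=f"miRNA-{t.cerna_class}")
    categories = {}
    for ci, comp in enumerate(sorted(nx.connected_components(g), key=sorted)):
        mir_deg = [g.degree[n] for n in comp
                   if g.nodes[n]["node_type"] == "miRNA"]
        n_multi = sum(1 for n in comp
                      if g.nodes[n]["node_type"] == "mRNA" and g.degree[n] >= 2)
        if mir_deg and max(mir_deg) >= hub_degree:
            categories[ci] = "A"
        elif n_multi >= multi_mrna:
            categories[ci] = "B"
        else:
            categories[ci] = "C"
    return CeRNANetwork(graph=g, categories=categories)


def triad_table(triads: Sequence[CeRNATriad]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in triads])


def write_network(net: CeRNANetwork, graphml_path, nodes_tsv=None, edges_tsv=None):
    nx.write_graphml(net.graph, graphml_path)
    if nodes_tsv is not None:
        pd.DataFrame(
            [{"node": n, "node_type": d["node_type"], "degree": net.graph.degree[n]}
             for n, d in sorted(net.graph.nodes(data=True))]
        ).to_csv(nodes_tsv, sep="\t", index=False)
    if edges_tsv is not None:
        pd.DataFrame(
            [{"source": a, "target": b, "edge_type": d["edge_type"]}
             for a, b, d in sorted(net.graph.edges(data=True))]
        ).to_csv(edges_tsv, sep="\t", index=False)
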
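"""Preranked gene-set enrichment on phi-scores, with term-overlap networks.

The running-sum enrichment statistic walks the consensus ranking from the
long-lived to the short-lived end: encountering a set gene increments the
sum by that gene's |statistic|^exponent (normalized by the in-set total),
a miss decrements by 1/(N - |S|).  The enrichment score (ES) is the signed
maximum deviation from zero and the leading edge is the run of set genes up
to (positive ES) or after (negative ES) the extremum.

Significance comes from gene-label permutations of the statistic: one
permutation relabels all genes at once and is evaluated against every set
(the fgsea-style scheme), which leaves each set's marginal null exact while
amortizing the cost.  The p-value is one-sided within the observed ES sign,
``p = (1 + #{|ES_perm| >= |ES|, same sign}) / (1 + n_same_sign_perms)``, and
NES divides ES by the mean |permuted ES| of the same sign.  BH-FDR is
applied across the retained sets.

Enriched terms are then linked by Jaccard overlap of their gene content and
clustered (average linkage on 1 - Ji) into functional clusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class GeneSet:
    """One term: display name, namespace (BP/CC), and member genes."""

    name: str
    namespace: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes within set {self.name!r}")


@dataclass
class GeneSetCollection:
    """Mapping of unique term ids to gene sets."""

    sets: dict[str, GeneSet]

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path, namespace: str = "BP") -> GeneSetCollection:
    """Read GMT: one term per line, ``id <tab> description <tab> gene...``.

    A description of the form ``namespace:name`` sets the term's namespace;
    otherwise ``namespace`` applies to every term.
    """
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, desc, genes = parts[0], parts[1], [g.upper() for g in parts[2:] if g]
            ns, name = namespace, desc
            if ":" in desc and desc.split(":", 1)[0] in ("BP", "CC"):
                ns, name = desc.split(":", 1)
            if term in sets:
                raise ValueError(f"duplicate term id {term!r} in {path}")
            sets[term] = GeneSet(name=name, namespace=ns, genes=tuple(dict.fromkeys(genes)))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, gs in collection.items():
            fh.write("\t".join([term, f"{gs.namespace}:{gs.name}", *gs.genes]) + "\n")


@dataclass
class RunningScore:
    """Full running sum for one set along one ranking."""

    es: float
    running: np.ndarray
    leading_edge: list[str]


@dataclass
class GSEAResult:
    term: str
    name: str
    namespace: str
    size: int
    es: float
    nes: float
    p_value: float
    fdr: float
    direction: str
    leading_edge: list[str] = field(default_factory=list)


def _order_by_statistic(statistic: dict[str, float]) -> tuple[list[str], np.ndarray]:
    """Genes sorted from the long-lived (largest statistic) end down.

    Statistic ties are broken lexicographically by gene id so that runs are
    deterministic.
    """
    genes = sorted(statistic, key=lambda g: (-statistic[g], g))
    return genes, np.array([statistic[g] for g in genes], dtype=float)


def running_enrichment_score(
    ranked_genes,
    statistic_values,
    term_genes,
    weight_exponent: float = 1.0,
) -> RunningScore:
    """ES, running sum, and leading edge for a single gene set.

    ``ranked_genes`` must already be ordered from largest to smallest
    statistic.  If the in-set weight total is zero (all |statistic| zero at
    hit positions), uniform hit weights are used.
    """
    ranked_genes = list(ranked_genes)
    values = np.asarray(statistic_values, dtype=float)
    n = len(ranked_genes)
    hits = np.isin(ranked_genes, list(term_genes))
    s = int(hits.sum())
    if s == 0:
        raise ValueError("no term gene present in the ranked universe")
    w = np.where(hits, np.abs(values) ** weight_exponent, 0.0)
    total = w.sum()
    if total == 0:
        w = hits / s
        total = 1.0
    miss = 0.0 if s == n else 1.0 / (n - s)
    running = np.cumsum(w / total - np.where(hits, 0.0, miss))
    max_dev = float(running.max())
    min_dev = float(running.min())
    es = max_dev if max_dev >= -min_dev else min_dev
    hit_idx = np.flatnonzero(hits)
    if es >= 0:
        extremum = int(np.argmax(running))
        edge = [ranked_genes[i] for i in hit_idx if i <= extremum]
    else:
        extremum = int(np.argmin(running))
        edge = [ranked_genes[i] for i in hit_idx if i > extremum]
    return RunningScore(es=es, running=running, leading_edge=edge)


def _batch_es(positions: np.ndarray, sizes: np.ndarray, abs_weights: np.ndarray):
    """Vectorized ES for many sets given hit positions in a fixed ranking.

    ``positions``: (M, smax) int array of 0-based hit positions, padded with
    N past each row's size.  ``abs_weights``: length N+1 array of
    |statistic|^exponent with a trailing zero for the padding slot.  Returns
    (es, max_dev, min_dev, sorted positions, cum-weight matrix) so callers
    can derive leading edges.
    """
    n = len(abs_weights) - 1
    pos = np.sort(positions, axis=1)
    valid = pos < n
    w = abs_weights[pos]
    totals = w.sum(axis=1)
    # degenerate rows (all weights zero): fall back to uniform hit weights
    degenerate = totals == 0
    if degenerate.any():
        w = np.where(degenerate[:, None] & valid, 1.0 / sizes[:, None], w)
        totals = np.where(degenerate, 1.0, totals)
    cumw = np.cumsum(w, axis=1)
    k = np.cumsum(valid, axis=1)
    miss_denom = np.where(sizes < n, n - sizes, np.inf).astype(float)[:, None]
    val_hit = cumw / totals[:, None] - (pos + 1 - k) / miss_denom
    val_before = (cumw - w) / totals[:, None] - (pos - (k - 1)) / miss_denom
    max_dev = np.where(valid, val_hit, -np.inf).max(axis=1)
    min_dev = np.where(valid, val_before, np.inf).min(axis=1)
    es = np.where(max_dev >= -min_dev, max_dev, min_dev)
    return es, max_dev, min_dev, pos, val_hit, val_before, valid


def preranked_gsea(
    statistic: dict[str, float],
    sets: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 100,
    n_perm: int = 10_000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
) -> list[GSEAResult]:
    """Permutation-based preranked GSEA over a collection of gene sets.

    The 10–100 size filter applies to each set's *effective* size after
    intersecting the ranked universe.  A seed is mandatory: results are
    fully reproducible given (inputs, seed).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if seed is None:
        raise ValueError("a seed is required for the permutation null")
    genes, values = _order_by_statistic(statistic)
    n = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    retained: list[tuple[str, GeneSet, np.ndarray]] = []
    for term in sorted(sets.sets):
        gs = sets.sets[term]
        pos = np.array(sorted(gene_index[g] for g in gs.genes if g in gene_index))
        if min_size <= len(pos) <= max_size:
            retained.append((term, gs, pos))
    if not retained:
        warnings.warn("no gene set passes the size filter")
        return []

    m = len(retained)
    smax = max(len(p) for _, _, p in retained)
    positions = np.full((m, smax), n, dtype=np.int64)
    sizes = np.zeros(m, dtype=np.int64)
    for i, (_, _, pos) in enumerate(retained):
        positions[i, : len(pos)] = pos
        sizes[i] = len(pos)

    abs_w = np.append(np.abs(values) ** weight_exponent, 0.0)

    if np.ptp(values) == 0:
        # all statistics identical: no ordering information at all
        results = [
            GSEAResult(
                term=term,
                name=gs.name,
                namespace=gs.namespace,
                size=int(sz),
                es=0.0,
                nes=0.0,
                p_value=1.0,
                fdr=1.0,
                direction="long",
                leading_edge=[],
            )
            for (term, gs, _), sz in zip(retained, sizes)
        ]
        return results

    es_obs, *_ = _batch_es(positions, sizes, abs_w)

    rng = np.random.default_rng(seed)
    ge_same_sign = np.zeros(m, dtype=np.int64)
    n_pos_perm = np.zeros(m, dtype=np.int64)
    n_neg_perm = np.zeros(m, dtype=np.int64)
    sum_abs_pos = np.zeros(m)
    sum_abs_neg = np.zeros(m)
    abs_obs = np.abs(es_obs)
    sign_obs = es_obs >= 0
    sigma = np.empty(n + 1, dtype=np.int64)
    sigma[n] = n  # padding slot maps to itself
    for _ in range(n_perm):
        sigma[:n] = rng.permutation(n)
        es_p, *_ = _batch_es(sigma[positions], sizes, abs_w)
        pos_mask = es_p >= 0
        n_pos_perm += pos_mask
        n_neg_perm += ~pos_mask
        sum_abs_pos += np.where(pos_mask, es_p, 0.0)
        sum_abs_neg += np.where(~pos_mask, -es_p, 0.0)
        same = pos_mask == sign_obs
        ge_same_sign += same & (np.abs(es_p) >= abs_obs)

    n_same = np.where(sign_obs, n_pos_perm, n_neg_perm)
    p = (1.0 + ge_same_sign) / (1.0 + n_same)
    mean_abs = np.divide(
        np.where(sign_obs, sum_abs_pos, sum_abs_neg),
        n_same,
        out=np.zeros(m),
        where=n_same > 0,
    )
    nes = np.divide(es_obs, mean_abs, out=np.zeros(m), where=mean_abs > 0)
    fdr = multipletests(p, method="fdr_bh")[1]

    results = []
    for i, (term, gs, pos) in enumerate(retained):
        hit_genes = {genes[j] for j in pos}
        rs = running_enrichment_score(genes, values, hit_genes, weight_exponent)
        results.append(
            GSEAResult(
                term=term,
                name=gs.name,
                namespace=gs.namespace,
                size=int(sizes[i]),
                es=float(es_obs[i]),
                nes=float(nes[i]),
                p_value=float(p[i]),
                fdr=float(fdr[i]),
                direction="long" if es_obs[i] >= 0 else "short",
                leading_edge=rs.leading_edge,
            )
        )
    return results


def results_frame(results: list[GSEAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "name": [r.name for r in results],
            "namespace": [r.namespace for r in results],
            "size": [r.size for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "direction": [r.direction for r in results],
            "leading_edge": [";".join(r.leading_edge) for r in results],
        }
    )


@dataclass
class TermNetwork:
    """Jaccard-linked network of enriched terms with functional clusters.

    Edges connect terms with Ji strictly above the threshold; clusters come
    from average-linkage hierarchical clustering on distance 1 - Ji, cut at
    ``cut_height``, and each cluster is named after its member term with the
    largest gene count.
    """

    graph: nx.Graph
    clusters: dict[str, str]
    cut_height: float
    ji_threshold: float


def jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def term_network(
    results: list[GSEAResult],
    sets: GeneSetCollection,
    universe=None,
    ji_threshold: float = 0.1,
    cut_height: float = 0.9,
) -> TermNetwork:
    """Build the term-overlap network and functional clusters.

    Gene content is restricted to ``universe`` (the ranked gene universe)
    when given.  Edges require Ji > ji_threshold (strict).
    """
    if not results:
        raise ValueError("need at least one enriched term")
    universe_set = set(universe) if universe is not None else None
    content: dict[str, set] = {}
    for r in results:
        genes = set(sets.sets[r.term].genes)
        if universe_set is not None:
            genes &= universe_set
        content[r.term] = genes
    terms = [r.term for r in results]
    g = nx.Graph()
    for r in results:
        g.add_node(r.term, direction=r.direction, size=len(content[r.term]), name=r.name)
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            ji = jaccard(content[a], content[b])
            if ji > ji_threshold:
                g.add_edge(a, b, ji=ji)
    if len(terms) == 1:
        clusters = {terms[0]: terms[0]}
    else:
        dist = []
        for i, a in enumerate(terms):
            for b in terms[i + 1 :]:
                dist.append(1.0 - jaccard(content[a], content[b]))
        linkage = hierarchy.linkage(np.array(dist), method="average")
        labels = hierarchy.fcluster(linkage, t=cut_height, criterion="distance")
        clusters = {}
        for lab in sorted(set(labels)):
            members = [t for t, l in zip(terms, labels) if l == lab]
            rep = max(members, key=lambda t: (len(content[t]), t))
            for t in members:
                clusters[t] = rep
    return TermNetwork(graph=g, clusters=clusters, cut_height=cut_height, ji_threshold=ji_threshold)


def cluster_leading_edges(
    results: list[GSEAResult], network: TermNetwork
) -> dict[str, set]:
    """Union of member-term leading edges per functional cluster."""
    edges: dict[str, set] = {}
    for r in results:
        label = network.clusters.get(r.term)
        if label is None:
            continue
        edges.setdefault(label, set()).update(r.leading_edge)
    return {k: v for k, v in edges.items() if v}
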
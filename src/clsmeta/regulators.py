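"""Transcription-factor association with functional-cluster leading edges.

For every TF and functional cluster, the displayed quantity is the fraction
of the cluster's leading-edge genes that the TF is documented to regulate;
relevance is a one-sided hypergeometric over-representation test of the
TF's targets within the leading edge, drawn from the gene universe.  TFs
significant in many clusters are 'global' regulators, in few 'local', and
'meso' in between.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class RegulatoryNetwork:
    """TF -> target-gene edges with optional evidence labels."""

    targets: dict[str, set]
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.targets = {tf: {g.upper() for g in tg} for tf, tg in self.targets.items()}

    @property
    def tfs(self) -> list[str]:
        return sorted(self.targets)


def load_network_table(path: str | Path) -> RegulatoryNetwork:
    """Read a TSV of ``tf, target[, evidence]`` rows."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    targets: dict[str, set] = {}
    evidence = {}
    for _, row in df.iterrows():
        tf, tg = row["tf"], row["target"].upper()
        targets.setdefault(tf, set()).add(tg)
        if "evidence" in df.columns and isinstance(row.get("evidence"), str):
            evidence[(tf, tg)] = row["evidence"]
    return RegulatoryNetwork(targets=targets, evidence=evidence)


@dataclass
class RegulatorProfile:
    """Per-TF association profile across functional clusters."""

    tf: str
    fractions: dict[str, float]
    p_values: dict[str, float]
    n_significant: int = 0
    breadth: str = ""


def regulator_association(
    leading_edges: dict[str, set],
    network: RegulatoryNetwork,
    universe,
    relevance_alpha: float = 0.01,
) -> list[RegulatorProfile]:
    """Fraction-regulated and hypergeometric relevance per (TF, cluster).

    A TF is retained when its targets are over-represented (p < alpha) in at
    least one cluster's leading edge; TFs with no targets in the universe
    are skipped with a warning.
    """
    universe_set = {g.upper() for g in universe}
    for cluster, genes in leading_edges.items():
        if not genes:
            raise ValueError(f"cluster {cluster!r} has an empty leading edge")
        stray = set(genes) - universe_set
        if stray:
            raise ValueError(
                f"cluster {cluster!r} leading edge contains genes outside the "
                f"universe, e.g. {sorted(stray)[0]!r}"
            )
    n_universe = len(universe_set)
    profiles = []
    for tf in network.tfs:
        targets = network.targets[tf] & universe_set
        if not targets:
            log.warning("TF %s has no targets in the universe; skipped", tf)
            continue
        fractions, pvals = {}, {}
        for cluster, edge in sorted(leading_edges.items()):
            edge = set(edge)
            overlap = len(targets & edge)
            fractions[cluster] = overlap / len(edge)
            pvals[cluster] = float(
                stats.hypergeom.sf(overlap - 1, n_universe, len(targets), len(edge))
            )
        n_sig = sum(p < relevance_alpha for p in pvals.values())
        if n_sig >= 1:
            profiles.append(
                RegulatorProfile(
                    tf=tf, fractions=fractions, p_values=pvals, n_significant=n_sig
                )
            )
    return profiles


def classify_breadth(
    profiles: list[RegulatorProfile],
    n_clusters: int,
    global_min_clusters: int | None = None,
    local_max_clusters: int = 2,
    relevance_alpha: float = 0.01,
) -> list[RegulatorProfile]:
    """Label each retained TF as a global, meso, or local regulator.

    Global: significant in at least ``global_min_clusters`` clusters
    (default: two thirds of the clusters, rounded up); local: significant in
    at most ``local_max_clusters``; meso otherwise.
    """
    if global_min_clusters is None:
        global_min_clusters = math.ceil(2 * n_clusters / 3)
    for p in profiles:
        n_sig = sum(v < relevance_alpha for v in p.p_values.values())
        p.n_significant = n_sig
        if n_sig >= global_min_clusters:
            p.breadth = "global"
        elif n_sig <= local_max_clusters:
            p.breadth = "local"
        else:
            p.breadth = "meso"
    return profiles


def association_matrix(profiles: list[RegulatorProfile]) -> pd.DataFrame:
    """TF x cluster heat matrix of regulated fractions, clustered for display.

    Rows and columns are ordered by average-linkage hierarchical clustering
    of the fraction profiles (report ordering only).
    """
    if not profiles:
        return pd.DataFrame()
    clusters = sorted({c for p in profiles for c in p.fractions})
    mat = pd.DataFrame(
        [[p.fractions.get(c, 0.0) for c in clusters] for p in profiles],
        index=[p.tf for p in profiles],
        columns=clusters,
    )
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    if len(mat) > 2:
        order = hierarchy.leaves_list(
            hierarchy.linkage(pdist(mat.to_numpy()), method="average")
        )
        mat = mat.iloc[order]
    if len(clusters) > 2:
        order = hierarchy.leaves_list(
            hierarchy.linkage(pdist(mat.to_numpy().T), method="average")
        )
        mat = mat.iloc[:, order]
    return mat
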
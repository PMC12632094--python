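"""Where gene sets and covariates fall along the consensus longevity rank.

ECDF shift tests against the uniform null, hypergeometric tail enrichment,
rank-vs-phenotype Spearman correlation, and decile trend summaries — the
statistics used to ask whether curated phenotypes, replicative-lifespan
genes, aging-gene orthologs, or measured growth rates concentrate at either
extreme of the consensus rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GenePhenotypeVector:
    """Per-gene numeric covariate (e.g. relative growth rate G, lifespan L)."""

    values: dict[str, float]
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        bad = [g for g, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite value for gene {bad[0]!r}")


@dataclass
class TailEnrichment:
    """One-sided hypergeometric over-representation of a set in a rank tail."""

    tail: str
    fraction: float
    tail_size: int
    set_size: int
    overlap: int
    expected: float
    p_value: float


@dataclass
class RankShiftResult:
    """Wilcoxon rank-sum comparison of a gene set against its complement."""

    statistic: float
    p_value: float
    n_set: int
    n_complement: int
    alternative: str


def rank_ecdf(rank: dict[str, float], genes) -> np.ndarray:
    """Cumulative fraction of the set at or above each rank position.

    Entry ``i`` (0-based) is the fraction of set genes with rank <= i+1; a
    set spread uniformly follows the diagonal.
    """
    present = [g for g in set(genes) if g in rank]
    if not present:
        raise ValueError("no set gene present in the ranking")
    n = len(rank)
    set_ranks = np.array([rank[g] for g in present], dtype=float)
    positions = np.arange(1, n + 1)
    return (set_ranks[None, :] <= positions[:, None]).mean(axis=1)


def rank_shift_test(
    rank: dict[str, float],
    genes,
    alternative: str = "two_sided",
) -> RankShiftResult:
    """Wilcoxon rank-sum test of set ranks against complement ranks.

    ``toward_top`` tests whether the set sits at better (smaller) ranks than
    the complement.  Uses exact enumeration when both groups have at most 8
    genes, otherwise the tie-corrected normal approximation.
    """
    alt_map = {"two_sided": "two-sided", "toward_top": "less", "toward_bottom": "greater"}
    if alternative not in alt_map:
        raise ValueError(f"unknown alternative {alternative!r}")
    gene_set = {g for g in genes if g in rank}
    comp = [g for g in rank if g not in gene_set]
    if not gene_set or not comp:
        raise ValueError("set and complement must each contain at least one ranked gene")
    x = np.array([rank[g] for g in gene_set], dtype=float)
    y = np.array([rank[g] for g in comp], dtype=float)
    # exact enumeration for small groups, but only without ties (the exact
    # distribution is not tie-corrected); otherwise tie-corrected normal
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alt_map[alternative], method=method)
    return RankShiftResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_set=len(x),
        n_complement=len(y),
        alternative=alternative,
    )


def tail_enrichment(
    rank: dict[str, float],
    genes,
    tail: str = "bottom",
    fraction: float = 0.05,
) -> TailEnrichment:
    """Hypergeometric over-representation of a set in the top or bottom tail.

    The tail holds the ``floor(fraction * N)`` best (top) or worst (bottom)
    ranks, minimum one gene; p = P(X >= overlap) drawing the tail without
    replacement from the ranked universe.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if tail not in ("top", "bottom"):
        raise ValueError(f"unknown tail {tail!r}")
    n = len(rank)
    k = max(1, int(np.floor(fraction * n)))
    order = sorted(rank, key=lambda g: (rank[g], g))
    tail_genes = set(order[:k] if tail == "top" else order[-k:])
    gene_set = {g for g in set(genes) if g in rank}
    overlap = len(gene_set & tail_genes)
    expected = k * len(gene_set) / n
    p = float(stats.hypergeom.sf(overlap - 1, n, len(gene_set), k))
    return TailEnrichment(
        tail=tail,
        fraction=fraction,
        tail_size=k,
        set_size=len(gene_set),
        overlap=overlap,
        expected=expected,
        p_value=p,
    )


def tail_enrichment_collection(
    rank: dict[str, float],
    sets: dict[str, set],
    tail: str = "bottom",
    fraction: float = 0.05,
) -> pd.DataFrame:
    """Tail over-representation across a family of gene sets, BH-corrected.

    Benjamini–Hochberg adjustment is applied within this family only.
    """
    rows = []
    for name, genes in sets.items():
        e = tail_enrichment(rank, genes, tail=tail, fraction=fraction)
        rows.append(
            {
                "set": name,
                "tail": tail,
                "overlap": e.overlap,
                "expected": e.expected,
                "p_value": e.p_value,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def rank_value_correlation(
    rank: dict[str, float], v: GenePhenotypeVector
) -> tuple[float, float]:
    """Tie-aware Spearman correlation between ranks and a gene covariate."""
    common = sorted(set(rank) & set(v.values))
    if len(common) < 3:
        raise ValueError("need at least 3 genes in common")
    r = np.array([rank[g] for g in common], dtype=float)
    x = np.array([v.values[g] for g in common], dtype=float)
    rho, p = stats.spearmanr(r, x)
    return float(rho), float(p)


def decile_trend(
    rank: dict[str, float],
    v: GenePhenotypeVector,
    n_bins: int = 10,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-bin mean of the covariate along contiguous rank bins, with t-CIs.

    Genes common to the ranking and the vector are ordered by rank and split
    into ``n_bins`` contiguous bins; each bin needs at least two genes for a
    confidence interval.
    """
    common = sorted(set(rank) & set(v.values), key=lambda g: (rank[g], g))
    if len(common) < n_bins:
        raise ValueError("fewer genes than bins")
    values = np.array([v.values[g] for g in common], dtype=float)
    rows = []
    for i, chunk in enumerate(np.array_split(values, n_bins)):
        if len(chunk) < 2:
            raise ValueError(f"bin {i + 1} has fewer than 2 genes")
        mean = float(chunk.mean())
        sem = float(chunk.std(ddof=1) / np.sqrt(len(chunk)))
        tq = stats.t.ppf(0.5 + ci_level / 2, df=len(chunk) - 1)
        rows.append(
            {
                "bin": i + 1,
                "n": len(chunk),
                "mean": mean,
                "ci_low": mean - tq * sem,
                "ci_high": mean + tq * sem,
            }
        )
    return pd.DataFrame(rows)
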
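"""Inter-screen agreement: rank correlation, tail overlap, and its drivers.

Genome-wide lifespan screens agree only modestly with each other.  This
module quantifies that agreement (pairwise Spearman matrix over a common
gene universe, Jaccard overlap of long/short tails) and fits a linear model
that predicts the pairwise correlation from whether two screens share
particular experimental conditions (auxotrophy, ploidy, medium, setup...).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from clsmeta.harmonize import ExperimentalProfile, RankedDataset, ScreenDataset

log = logging.getLogger(__name__)


@dataclass
class PairwiseConcordance:
    """Spearman agreement of two screens over their shared genes."""

    dataset_a: str
    dataset_b: str
    n_shared: int
    rho: float
    p_value: float


@dataclass
class ConcordanceMatrix:
    """Symmetric Spearman matrix with two-sided p-values."""

    datasets: list[str]
    rho: pd.DataFrame
    p_value: pd.DataFrame
    n_genes: int

    def pairs(self) -> list[PairwiseConcordance]:
        """Unordered dataset pairs (upper triangle) as records."""
        out = []
        for a, b in itertools.combinations(self.datasets, 2):
            out.append(
                PairwiseConcordance(
                    dataset_a=a,
                    dataset_b=b,
                    n_shared=self.n_genes,
                    rho=float(self.rho.loc[a, b]),
                    p_value=float(self.p_value.loc[a, b]),
                )
            )
        return out


@dataclass
class SharedVariableModel:
    """OLS of pairwise rho on shared-condition indicators.

    ``coefficients[v]`` is the average change in pairwise Spearman rho when
    two screens share the level of experimental variable ``v``, holding the
    other sharing indicators fixed.  Non-estimable (constant/collinear)
    indicators are listed in ``non_estimable`` with NaN coefficients.
    """

    coefficients: dict[str, float]
    intercept: float
    p_values: dict[str, float]
    standard_errors: dict[str, float]
    r2_adjusted: float
    model_p_value: float
    n_pairs: int
    non_estimable: list[str] = field(default_factory=list)


def spearman_matrix(datasets: list[ScreenDataset], genes: list[str]) -> ConcordanceMatrix:
    """Pairwise Spearman correlation over a fixed common gene list.

    All listed genes must be present in every dataset; p-values are two-sided
    via the t-approximation with tie-aware average ranks (scipy).
    """
    if len(genes) < 3:
        raise ValueError("need at least 3 genes for a Spearman matrix")
    for ds in datasets:
        for g in genes:
            if g not in ds.values:
                raise KeyError(f"gene {g!r} missing from dataset {ds.name!r}")
    names = [ds.name for ds in datasets]
    mat = np.column_stack([[ds.values[g] for g in genes] for ds in datasets])
    n = len(names)
    rho = np.eye(n)
    pval = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        r, p = stats.spearmanr(mat[:, i], mat[:, j])
        rho[i, j] = rho[j, i] = r
        pval[i, j] = pval[j, i] = p
    return ConcordanceMatrix(
        datasets=names,
        rho=pd.DataFrame(rho, index=names, columns=names),
        p_value=pd.DataFrame(pval, index=names, columns=names),
        n_genes=len(genes),
    )


def tail_jaccard(
    a: RankedDataset,
    b: RankedDataset,
    tail: str = "long",
    cutoff_fraction: float = 0.05,
) -> float:
    """Jaccard index of the two screens' long- or short-lived tails.

    Tails are taken over the genes shared by both rankings, re-ranked within
    that common universe; tail size is ``floor(cutoff_fraction * n_shared)``
    with a minimum of one gene.
    """
    if not 0 < cutoff_fraction < 1:
        raise ValueError("cutoff_fraction must be in (0, 1)")
    if tail not in ("long", "short"):
        raise ValueError(f"unknown tail {tail!r}")
    shared = sorted(set(a.ranks) & set(b.ranks))
    if not shared:
        raise ValueError(f"no genes shared between {a.name!r} and {b.name!r}")
    k = max(1, int(np.floor(cutoff_fraction * len(shared))))

    def tail_set(ranked: RankedDataset) -> set[str]:
        # long tail = best (smallest) ranks within the shared universe
        order = sorted(shared, key=lambda g: (ranked.ranks[g], g))
        return set(order[:k] if tail == "long" else order[-k:])

    ta, tb = tail_set(a), tail_set(b)
    return len(ta & tb) / len(ta | tb)


def shared_variable_model(
    pairs: list[PairwiseConcordance],
    profiles: dict[str, ExperimentalProfile],
    variables: list[str],
) -> SharedVariableModel:
    """OLS of pairwise rho on one shared/not-shared indicator per variable.

    For each experimental variable ``v`` the predictor is 1 iff both screens
    of a pair have the identical level of ``v``.  Constant indicators are
    non-estimable; they are excluded with a warning and reported with NaN.
    """
    if not pairs:
        raise ValueError("no pairs given")
    for p in pairs:
        for name in (p.dataset_a, p.dataset_b):
            if name not in profiles:
                raise KeyError(f"no experimental profile for dataset {name!r}")
    y = np.array([p.rho for p in pairs], dtype=float)
    X = pd.DataFrame(
        {
            v: [
                1.0 if profiles[p.dataset_a].shares(profiles[p.dataset_b], v) else 0.0
                for p in pairs
            ]
            for v in variables
        }
    )
    non_estimable = [v for v in variables if X[v].nunique() < 2]
    for v in non_estimable:
        warnings.warn(f"indicator for variable {v!r} is constant; excluded from the model")
    kept = [v for v in variables if v not in non_estimable]
    if len(pairs) < len(kept) + 2:
        raise ValueError(
            f"{len(pairs)} pairs cannot support {len(kept)} indicators plus an intercept"
        )
    design = sm.add_constant(X[kept].to_numpy(), has_constant="add")
    fit = sm.OLS(y, design).fit()
    # collinearity among the kept indicators: flag coefficients that the fit
    # could not pin down (rank-deficient design)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("collinear indicators; some coefficients are not estimable")
    coefs = dict(zip(kept, fit.params[1:]))
    pvals = dict(zip(kept, fit.pvalues[1:]))
    ses = dict(zip(kept, fit.bse[1:]))
    for v in non_estimable:
        coefs[v] = np.nan
        pvals[v] = np.nan
        ses[v] = np.nan
    return SharedVariableModel(
        coefficients=coefs,
        intercept=float(fit.params[0]),
        p_values=pvals,
        standard_errors=ses,
        r2_adjusted=float(fit.rsquared_adj),
        model_p_value=float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else np.nan,
        n_pairs=len(pairs),
        non_estimable=non_estimable,
    )
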
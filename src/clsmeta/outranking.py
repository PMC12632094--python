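"""PROMETHEE II outranking: consensus gene ranking across screens.

Each screen is a criterion, each gene an alternative.  With the *usual*
preference function, gene ``a`` is fully preferred to gene ``b`` on a
criterion whenever its value is strictly larger; ties yield no preference.
Weighted preferences are aggregated into pairwise preference degrees
``pi(a, b)``, and each gene's net flow (phi-score)

    phi(a) = 1/(n-1) * sum_{b != a} [pi(a, b) - pi(b, a)]

measures how consistently ``a`` outranks the rest of the genome across
screens.  Because screens cover different deletion subsets, a pair may share
only some criteria; under the default ``renormalize`` policy the weights are
rescaled to sum to one over the mutually observed criteria, keeping phi on
the [-1, 1] scale for low-coverage genes.  ``zero_preference`` instead
leaves unshared criteria as zero preference (no rescaling).

The public :func:`net_flows` uses an O(n log n)-per-criterion counting path
(grouping genes by their pattern of observed criteria); the quadratic
:func:`net_flows_brute` is the direct transcription of the definition and is
kept as the reference implementation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from clsmeta.evaluation import WeightScheme
from clsmeta.harmonize import ScreenDataset

log = logging.getLogger(__name__)


def usual_preference(d: float) -> float:
    """Usual preference function for a maximized criterion: 1 if d > 0 else 0."""
    if not np.isfinite(d):
        raise ValueError("score difference must be finite")
    return 1.0 if d > 0 else 0.0


@dataclass
class CriteriaMatrix:
    """Gene-by-dataset score matrix with integration weights.

    ``values`` is a float array (alternatives x criteria) with NaN marking
    genes not measured by a screen; every gene must be observed on at least
    one criterion and the weights must cover exactly the criteria.
    """

    alternatives: list[str]
    criteria: list[str]
    values: np.ndarray
    weights: WeightScheme

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.alternatives), len(self.criteria)):
            raise ValueError("values shape does not match alternatives x criteria")
        if set(self.weights.weights) != set(self.criteria):
            raise ValueError("weights must cover exactly the criteria")
        observed = np.isfinite(self.values)
        if not observed.any(axis=1).all():
            orphan = self.alternatives[int(np.argmin(observed.any(axis=1)))]
            raise ValueError(f"gene {orphan!r} has no observed criterion")

    @classmethod
    def from_datasets(
        cls, datasets: list[ScreenDataset], weights: WeightScheme
    ) -> "CriteriaMatrix":
        """Assemble the matrix from oriented screens.

        Alternatives are all genes with data in at least one screen.
        """
        genes = sorted(set().union(*(set(ds.values) for ds in datasets)))
        values = np.full((len(genes), len(datasets)), np.nan)
        index = {g: i for i, g in enumerate(genes)}
        for j, ds in enumerate(datasets):
            for g, v in ds.values.items():
                values[index[g], j] = v
        return cls(
            alternatives=genes,
            criteria=[ds.name for ds in datasets],
            values=values,
            weights=weights,
        )

    @property
    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights.weights[c] for c in self.criteria], dtype=float)


@dataclass
class OutrankingResult:
    """Net flows (phi-scores) and the consensus ordinal ranking."""

    phi: dict[str, float]
    phi_plus: dict[str, float]
    phi_minus: dict[str, float]
    rank: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.phi, key=lambda g: self.rank.get(g, 0))
        return pd.DataFrame(
            {
                "gene": genes,
                "phi": [self.phi[g] for g in genes],
                "phi_plus": [self.phi_plus[g] for g in genes],
                "phi_minus": [self.phi_minus[g] for g in genes],
                "rank": [self.rank[g] for g in genes] if self.rank else np.nan,
            }
        )


def _pair_weight_factors(
    w: np.ndarray, pattern_q: np.ndarray, pattern_r: np.ndarray, policy: str
) -> np.ndarray:
    """Effective per-criterion weight for a pair with observation patterns Q, R.

    Returns zeros outside the mutually observed criteria.  Under
    ``renormalize`` the shared weights are rescaled to sum to one; a pair
    whose shared criteria carry zero total weight contributes nothing.
    """
    shared = pattern_q & pattern_r
    eff = np.where(shared, w, 0.0)
    if policy == "renormalize":
        total = eff.sum()
        if total > 0:
            eff = eff / total
        else:
            eff = np.zeros_like(eff)
    elif policy != "zero_preference":
        raise ValueError(f"unknown missing policy {policy!r}")
    return eff


def net_flows(m: CriteriaMatrix, missing_policy: str = "renormalize") -> OutrankingResult:
    """PROMETHEE II net flows with the usual preference function.

    Fast counting path: genes are grouped by their pattern of observed
    criteria (at most 2^J groups).  For a fixed ordered group pair the
    effective weights are constant, and for the usual function the summed
    preference of gene ``a`` over group ``R`` on criterion ``j`` is simply
    the number of R-genes with a strictly smaller value, obtained by binary
    search against the sorted group values.  Matches :func:`net_flows_brute`
    to numerical precision.
    """
    n = len(m.alternatives)
    if n < 2:
        raise ValueError("need at least 2 alternatives")
    w = m.weight_vector
    observed = np.isfinite(m.values)
    # group genes by observation pattern
    pattern_keys = [tuple(row) for row in observed]
    groups: dict[tuple, np.ndarray] = {}
    for key in set(pattern_keys):
        groups[key] = np.array([i for i, k in enumerate(pattern_keys) if k == key])
    # pre-sort each group's values per criterion it observes
    sorted_vals = {
        (key, j): np.sort(m.values[idx, j])
        for key, idx in groups.items()
        for j in range(len(m.criteria))
        if key[j]
    }
    plus = np.zeros(n)
    minus = np.zeros(n)
    n_disjoint_pairs = 0
    for key_q, idx_q in groups.items():
        pq = np.array(key_q, dtype=bool)
        for key_r, idx_r in groups.items():
            pr = np.array(key_r, dtype=bool)
            eff = _pair_weight_factors(w, pq, pr, missing_policy)
            if not eff.any():
                if (pq & pr).sum() == 0:
                    n_disjoint_pairs += len(idx_q) * len(idx_r)
                continue
            for j in np.flatnonzero(eff):
                vals_r = sorted_vals[(key_r, j)]
                x = m.values[idx_q, j]
                n_less = np.searchsorted(vals_r, x, side="left")
                n_greater = len(vals_r) - np.searchsorted(vals_r, x, side="right")
                # self-comparison is a tie, contributing nothing either way
                plus[idx_q] += eff[j] * n_less
                minus[idx_q] += eff[j] * n_greater
    if n_disjoint_pairs:
        log.info(
            "%d ordered gene pairs share no observed criterion; zero preference",
            n_disjoint_pairs,
        )
    plus /= n - 1
    minus /= n - 1
    phi = plus - minus
    genes = m.alternatives
    result = OutrankingResult(
        phi=dict(zip(genes, phi)),
        phi_plus=dict(zip(genes, plus)),
        phi_minus=dict(zip(genes, minus)),
    )
    result.rank = rank_by_phi(result)
    return result


def net_flows_brute(m: CriteriaMatrix, missing_policy: str = "renormalize") -> OutrankingResult:
    """Reference O(n^2 * J) transcription of the PROMETHEE II definition."""
    n = len(m.alternatives)
    if n < 2:
        raise ValueError("need at least 2 alternatives")
    w = m.weight_vector
    observed = np.isfinite(m.values)
    pi = np.zeros((n, n))
    for a, b in itertools.permutations(range(n), 2):
        eff = _pair_weight_factors(w, observed[a], observed[b], missing_policy)
        for j in np.flatnonzero(eff):
            pi[a, b] += eff[j] * usual_preference(m.values[a, j] - m.values[b, j])
    plus = pi.sum(axis=1) / (n - 1)
    minus = pi.sum(axis=0) / (n - 1)
    genes = m.alternatives
    result = OutrankingResult(
        phi=dict(zip(genes, plus - minus)),
        phi_plus=dict(zip(genes, plus)),
        phi_minus=dict(zip(genes, minus)),
    )
    result.rank = rank_by_phi(result)
    return result


def rank_by_phi(r: OutrankingResult) -> dict[str, int]:
    """Ordinal consensus ranking: rank 1 = largest phi.

    Exact phi ties are broken lexicographically by gene identifier so the
    ranking is deterministic.
    """
    order = sorted(r.phi, key=lambda g: (-r.phi[g], g))
    return {g: i + 1 for i, g in enumerate(order)}
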
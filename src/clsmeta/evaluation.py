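"""Dataset reliability: ROC/AUC against a curated phenotype catalog.

Each screen is scored on how well its ranking separates gene deletions with
curated long- vs short-lived phenotypes (validated by CFU counting or
live/dead staining in small-scale studies).  Curated genes whose phenotype
was validated within the same study as the screen can be excluded to avoid
common-source bias.  The resulting AUCs feed the integration weight schemes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics

from clsmeta.harmonize import RankedDataset, _normalize_gene

log = logging.getLogger(__name__)


@dataclass
class CuratedCatalog:
    """Binary long/short truth labels with their source studies.

    Genes with balanced conflicting evidence are expected to have been
    excluded upstream during curation; this container only validates that
    labels are binary.
    """

    labels: dict[str, str]
    sources: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = {_normalize_gene(g): lab for g, lab in self.labels.items()}
        bad = {lab for lab in self.labels.values() if lab not in ("long", "short")}
        if bad:
            raise ValueError(f"catalog labels must be 'long'/'short', got {sorted(bad)}")
        self.sources = {_normalize_gene(g): set(s) for g, s in self.sources.items()}

    @property
    def genes(self) -> list[str]:
        return sorted(self.labels)


def load_catalog(path: str | Path) -> CuratedCatalog:
    """Read a catalog TSV: ``gene, label, sources`` (semicolon-separated ids)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    labels = dict(zip(df["gene"], df["label"]))
    sources = {}
    if "sources" in df.columns:
        for g, s in zip(df["gene"], df["sources"].fillna("")):
            sources[g] = {x for x in s.split(";") if x}
    return CuratedCatalog(labels=labels, sources=sources)


@dataclass
class ROCResult:
    """ROC curve and AUC of one screen as a long-vs-short classifier."""

    dataset: str
    points: list[tuple[float, float]]
    auc: float
    n_pos: int
    n_neg: int
    excluded: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)


@dataclass
class WeightScheme:
    """Per-dataset integration weights, normalized to sum to one."""

    weights: dict[str, float]
    scheme: str

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if total <= 0:
            raise ValueError("total weight must be positive")
        if abs(total - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 within 1e-12")

    def rounded(self, ndigits: int = 4) -> dict[str, float]:
        """Reporting precision used for printed weights (e.g. 0.2214)."""
        return {k: round(v, ndigits) for k, v in self.weights.items()}


def auc_mann_whitney(pos_scores, neg_scores) -> float:
    """AUC as the Mann–Whitney win fraction: (#pos>neg + 0.5·#ties) / (n+·n−).

    This is the probability that a random positive outscores a random
    negative; it serves as the independent oracle for the trapezoidal ROC
    area.
    """
    pos = np.asarray(list(pos_scores), dtype=float)
    neg = np.asarray(list(neg_scores), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    diff = pos[:, None] - neg[None, :]
    wins = np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)
    return float(wins / (pos.size * neg.size))


def roc_curve(
    ds: RankedDataset,
    catalog: CuratedCatalog,
    exclude_same_source: bool = False,
    dataset_source: str | None = None,
    positive: str = "long",
) -> ROCResult:
    """ROC of one ranked screen against the curated catalog.

    The positive class defaults to long-lived; the classifier score of a gene
    is minus its rank (a better rank gives a higher score).  Catalog genes
    absent from the screen are skipped and reported in ``missing``; with
    ``exclude_same_source``, catalog genes whose evidence includes
    ``dataset_source`` are excluded and reported in ``excluded``.
    """
    if positive not in ("long", "short"):
        raise ValueError(f"positive class must be 'long' or 'short', got {positive!r}")
    excluded, missing = [], []
    scores, labels = [], []
    for gene, label in catalog.labels.items():
        if exclude_same_source and dataset_source and dataset_source in catalog.sources.get(gene, ()):
            excluded.append(gene)
            continue
        if gene not in ds.ranks:
            missing.append(gene)
            continue
        scores.append(-ds.ranks[gene])
        labels.append(1 if label == positive else 0)
    if missing:
        log.info("ROC %s: %d catalog genes not measured, skipped", ds.name, len(missing))
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"dataset {ds.name!r}: need both classes after exclusions "
            f"(n_pos={n_pos}, n_neg={n_neg})"
        )
    fpr, tpr, _ = metrics.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(metrics.auc(fpr, tpr))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    if points[0] != (0.0, 0.0):
        points.insert(0, (0.0, 0.0))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return ROCResult(
        dataset=ds.name,
        points=points,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
        excluded=sorted(excluded),
        missing=sorted(missing),
    )


def make_weights(
    datasets: list[str],
    scheme: str = "equal",
    aucs: dict[str, float] | None = None,
    priority_vector: list[float] | None = None,
) -> WeightScheme:
    """Build an integration weight scheme over the given datasets.

    ``equal`` gives 1/D each; ``auc_proportional`` normalizes the per-dataset
    AUCs to sum to one; ``priority`` normalizes a caller-supplied vector
    (aligned with ``datasets``).
    """
    if not datasets:
        raise ValueError("no datasets given")
    if scheme == "equal":
        w = {d: 1.0 / len(datasets) for d in datasets}
    elif scheme == "auc_proportional":
        if aucs is None or any(d not in aucs for d in datasets):
            raise ValueError("auc_proportional requires an AUC for every dataset")
        total = sum(aucs[d] for d in datasets)
        if total <= 0:
            raise ValueError("total AUC must be positive")
        w = {d: aucs[d] / total for d in datasets}
    elif scheme == "priority":
        if priority_vector is None or len(priority_vector) != len(datasets):
            raise ValueError("priority requires a vector matching the dataset list")
        total = float(sum(priority_vector))
        if total <= 0:
            raise ValueError("total priority must be positive")
        w = {d: v / total for d, v in zip(datasets, priority_vector)}
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    return WeightScheme(weights=w, scheme=scheme)
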
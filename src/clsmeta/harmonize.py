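"""Load and orient heterogeneous lifespan screens onto a common scale.

Each genome-wide screen reports one representative lifespan value per
gene-deletion strain, on its own scale (outgrowth rates, barcode intensities,
fluorescence ratios...).  Harmonization keeps the values as-is but fixes the
orientation (larger = longer-lived) and produces tie-averaged rankings so
that downstream rank-based statistics are comparable across screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)


@dataclass
class ExperimentalProfile:
    """Experimental conditions of one screen.

    The categorical levels describe how a screen was run: strain ploidy and
    auxotrophy, aging-medium composition, whether cultures were pH-buffered
    or aerated, the competition setup, and the lifespan read-out.  These are
    the variables whose sharing between two screens is tested as a predictor
    of inter-screen correlation.

    Arbitrary extra variables go into ``extra``; :meth:`level` resolves both.
    """

    ploidy: str = "haploid"
    auxotrophy: str = "auxotroph"
    medium_base: str = "SC"
    glucose_pct: float = 2.0
    buffered: bool = False
    aerated: bool = False
    setup: str = "monoculture"
    assay: str = "outgrowth"
    nutrient_limitation: str = "none"
    dietary_restriction: bool = False
    extra: dict = field(default_factory=dict)

    def level(self, variable: str):
        """Return the categorical level of ``variable`` for this screen."""
        if variable in self.extra:
            return self.extra[variable]
        if not hasattr(self, variable):
            raise KeyError(f"unknown experimental variable: {variable!r}")
        return getattr(self, variable)

    def shares(self, other: "ExperimentalProfile", variable: str) -> bool:
        """True if both screens have the identical level of ``variable``."""
        return self.level(variable) == other.level(variable)


def _normalize_gene(gene: str) -> str:
    # systematic ORF names are matched case-insensitively
    g = str(gene).strip().upper()
    if not g:
        raise ValueError("empty gene identifier")
    return g


@dataclass
class ScreenDataset:
    """One screen's gene -> lifespan-value table plus its experimental profile.

    After orientation, larger values always mean longer-lived mutants.
    """

    name: str
    values: dict[str, float]
    profile: ExperimentalProfile | None = None
    symbols: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError(f"dataset {self.name!r} has no genes")
        normalized: dict[str, float] = {}
        for gene, value in self.values.items():
            g = _normalize_gene(gene)
            if g in normalized:
                raise ValueError(f"duplicate gene {g!r} in dataset {self.name!r}")
            v = float(value)
            if not np.isfinite(v):
                raise ValueError(f"non-finite value for gene {g!r} in {self.name!r}")
            normalized[g] = v
        self.values = normalized

    @property
    def genes(self) -> list[str]:
        return sorted(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class RankedDataset:
    """Tie-averaged ranking of one screen; rank 1 = most long-lived."""

    name: str
    ranks: dict[str, float]

    @property
    def genes(self) -> list[str]:
        return sorted(self.ranks)

    def __len__(self) -> int:
        return len(self.ranks)


def load_screen_table(
    path: str | Path,
    name: str,
    profile: ExperimentalProfile | None = None,
    orientation: str = "higher_is_longer",
) -> ScreenDataset:
    """Read one screen from a two-column TSV (``gene``, ``value``).

    An optional ``symbol`` column is kept for display only.  Rows whose value
    is missing or non-finite are dropped and counted in the log.  With
    ``orientation="lower_is_longer"`` the values are negated so that larger
    always means longer-lived.

    Raises
    ------
    ValueError
        On duplicate gene rows (naming the gene) or an empty table.
    """
    if orientation not in ("higher_is_longer", "lower_is_longer"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if "gene" not in df.columns or "value" not in df.columns:
        raise ValueError(f"{path}: expected columns 'gene' and 'value'")
    if df.empty:
        raise ValueError(f"{path}: empty screen table")
    df["gene"] = df["gene"].map(_normalize_gene)
    dupes = df["gene"][df["gene"].duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate gene row {dupes.iloc[0]!r}")
    values = pd.to_numeric(df["value"], errors="coerce")
    keep = np.isfinite(values.to_numpy(dtype=float))
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dataset %s: dropped %d rows with missing/non-finite values", name, n_dropped)
    df = df.loc[keep]
    values = values[keep].astype(float)
    if df.empty:
        raise ValueError(f"{path}: no finite values in screen table")
    if orientation == "lower_is_longer":
        values = -values
    symbols = {}
    if "symbol" in df.columns:
        symbols = {g: s for g, s in zip(df["gene"], df["symbol"]) if isinstance(s, str)}
    return ScreenDataset(
        name=name,
        values=dict(zip(df["gene"], values)),
        profile=profile,
        symbols=symbols,
    )


def rank_genes(ds: ScreenDataset) -> RankedDataset:
    """Rank genes from most to least long-lived (rank 1 = largest value).

    Ties receive the average of the spanned ranks, which keeps downstream
    Spearman correlations consistent with ``scipy`` conventions.
    """
    genes = list(ds.values)
    scores = np.array([ds.values[g] for g in genes], dtype=float)
    ranks = rankdata(-scores, method="average")
    return RankedDataset(name=ds.name, ranks=dict(zip(genes, ranks)))


def shared_genes(datasets: list[ScreenDataset]) -> list[str]:
    """Sorted intersection of the gene universes of all datasets."""
    if not datasets:
        raise ValueError("no datasets given")
    common = set(datasets[0].values)
    for ds in datasets[1:]:
        common &= set(ds.values)
    return sorted(common)


def pooled_gene_universe(datasets: list[ScreenDataset]) -> list[str]:
    """Sorted union of the gene universes: every gene measured at least once."""
    if not datasets:
        raise ValueError("no datasets given")
    pooled: set[str] = set()
    for ds in datasets:
        pooled |= set(ds.values)
    return sorted(pooled)


def write_ranked_table(ds: ScreenDataset, path: str | Path) -> None:
    """Write ``gene, score, rank`` TSV for one oriented dataset."""
    ranked = rank_genes(ds)
    genes = sorted(ds.values, key=lambda g: ranked.ranks[g])
    pd.DataFrame(
        {
            "gene": genes,
            "score": [ds.values[g] for g in genes],
            "rank": [ranked.ranks[g] for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)
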
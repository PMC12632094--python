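"""Synthetic pipeline inputs with recorded ground truth.

The generator family emulates the structure of the real study inputs: a set
of noisy, partially overlapping genome-wide screens driven by a shared
latent longevity effect; a small curated catalog labeling the latent
extremes; GO-style gene sets half of which carry a planted rank shift; a
regulatory network with planted broad and narrow regulators; and
competitive-aging plate-reader time series generated from the forward
linear model.  Every generator is bit-reproducible given (parameters, seed)
and emits its ground truth alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from clsmeta.compete import MEASUREMENT_COLUMNS, CompetitionDesign, WellAssignment
from clsmeta.evaluation import CuratedCatalog
from clsmeta.gsea import GeneSet, GeneSetCollection
from clsmeta.harmonize import ExperimentalProfile, ScreenDataset
from clsmeta.regulators import RegulatoryNetwork


@dataclass
class DatasetParams:
    """Loading on the latent effect, noise level, and gene coverage."""

    beta: float = 1.0
    sigma: float = 0.5
    coverage: float = 1.0
    distortion: str = "identity"  # identity | rank | logistic

    def __post_init__(self) -> None:
        if self.beta < 0 or self.sigma < 0 or not 0 < self.coverage <= 1:
            raise ValueError("require beta >= 0, sigma >= 0, 0 < coverage <= 1")
        if self.distortion not in ("identity", "rank", "logistic"):
            raise ValueError(f"unknown distortion {self.distortion!r}")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators."""

    seed: int
    latent: dict[str, float] = field(default_factory=dict)
    dataset_params: list[DatasetParams] = field(default_factory=list)
    planted_sets: dict[str, float] = field(default_factory=dict)
    planted_tfs: dict[str, str] = field(default_factory=dict)
    plate_truth: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["plate_truth"] = {
            plate: {
                "wells": {w: list(v) for w, v in info["wells"].items()},
                "C": {f"{T},{t}": c for (T, t), c in info["C"].items()},
            }
            for plate, info in self.plate_truth.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _gene_names(n_genes: int) -> list[str]:
    return [f"YS{i:05d}W" for i in range(1, n_genes + 1)]


def _distort(scores: np.ndarray, kind: str) -> np.ndarray:
    # strictly monotone transforms: rank order is preserved by construction
    if kind == "identity":
        return scores
    if kind == "rank":
        return np.argsort(np.argsort(scores)).astype(float) + 1.0
    if kind == "logistic":
        return 1.0 / (1.0 + np.exp(-scores))
    raise ValueError(kind)


def simulate_profiles(n_datasets: int, seed: int) -> list[ExperimentalProfile]:
    """Random but reproducible experimental profiles for simulated screens."""
    rng = np.random.default_rng(seed)
    levels = {
        "ploidy": ["haploid", "diploid"],
        "auxotrophy": ["auxotroph", "prototroph"],
        "medium_base": ["SC", "water"],
        "glucose_pct": [0.0, 1.0, 2.0],
        "buffered": [True, False],
        "aerated": [True, False],
        "setup": ["monoculture", "two_strain", "pooled"],
        "assay": ["outgrowth", "barcode_microarray", "barcode_seq", "relative_fluorescence"],
        "nutrient_limitation": ["none", "leucine", "phosphate"],
        "dietary_restriction": [True, False],
    }
    profiles = []
    for _ in range(n_datasets):
        kwargs = {k: v[rng.integers(len(v))] for k, v in levels.items()}
        profiles.append(ExperimentalProfile(**kwargs))
    return profiles


def simulate_screens(
    n_genes: int = 2000,
    dataset_params: list[DatasetParams] | None = None,
    seed: int = 0,
    profiles: list[ExperimentalProfile] | None = None,
    truth: SyntheticTruth | None = None,
) -> tuple[list[ScreenDataset], SyntheticTruth]:
    """Correlated screens driven by a shared latent longevity effect.

    Each gene has a latent effect lambda ~ N(0, 1); screen d reports
    ``beta_d * lambda + Normal(0, sigma_d^2)`` passed through a monotone
    distortion, over a coverage mask drawn without replacement.  Passing an
    existing ``truth`` (with ``latent`` already set, e.g. after planting set
    shifts) reuses its latent effects instead of drawing new ones.
    """
    if dataset_params is None:
        dataset_params = [DatasetParams(beta=1.0, sigma=0.5, coverage=1.0) for _ in range(5)]
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    if truth is None or not truth.latent:
        latent = rng.standard_normal(n_genes)
        truth = truth or SyntheticTruth(seed=seed)
        truth.latent = dict(zip(genes, latent))
    else:
        if set(truth.latent) != set(genes):
            raise ValueError("truth.latent does not cover the requested gene universe")
        latent = np.array([truth.latent[g] for g in genes])
    truth.dataset_params = dataset_params
    datasets = []
    for d, params in enumerate(dataset_params):
        scores = params.beta * latent + rng.normal(0.0, params.sigma, size=n_genes)
        scores = _distort(scores, params.distortion)
        n_obs = int(round(params.coverage * n_genes))
        observed = np.sort(rng.choice(n_genes, size=n_obs, replace=False))
        profile = profiles[d] if profiles else None
        datasets.append(
            ScreenDataset(
                name=f"screen{d + 1:02d}",
                values={genes[i]: float(scores[i]) for i in observed},
                profile=profile,
            )
        )
    return datasets, truth


def simulate_catalog_and_sets(
    truth: SyntheticTruth,
    n_long: int = 81,
    n_short: int = 81,
    label_noise: float = 0.05,
    n_sets: int = 40,
    set_size_range: tuple[int, int] = (10, 100),
    shift: float = 2.0,
    seed: int = 0,
) -> tuple[CuratedCatalog, GeneSetCollection]:
    """Curated catalog from the latent extremes plus planted gene sets.

    Long labels go to the highest-latent genes and short labels to the
    lowest, after which a ``label_noise`` fraction of labels is flipped.
    Half the gene sets are planted: their genes are sampled with weights
    proportional to ``exp(+/-shift * lambda)``, which tilts the standard-
    normal latent distribution to N(+/-shift, 1) — i.e. genes "drawn from a
    shifted latent".  The other half are uniform null sets.  Planted shifts
    are recorded in ``truth.planted_sets`` (0.0 for null sets).
    """
    rng = np.random.default_rng(seed)
    genes = sorted(truth.latent)
    lam = np.array([truth.latent[g] for g in genes])
    if n_long + n_short > len(genes):
        raise ValueError("catalog larger than the gene universe")
    order = np.argsort(-lam)
    labels = {}
    for i in order[:n_long]:
        labels[genes[i]] = "long"
    for i in order[::-1][:n_short]:
        labels[genes[i]] = "short"
    flip = rng.random(len(labels)) < label_noise
    for (g, _), f in zip(list(labels.items()), flip):
        if f:
            labels[g] = "short" if labels[g] == "long" else "long"
    catalog = CuratedCatalog(
        labels=labels, sources={g: {"synthetic_smallscale"} for g in labels}
    )

    lo, hi = set_size_range
    sets = {}
    n_planted = n_sets // 2
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        term = f"SET{i + 1:04d}"
        if i < n_planted:
            delta = shift if i % 2 == 0 else -shift
            w = np.exp(delta * lam)
            members = rng.choice(len(genes), size=size, replace=False, p=w / w.sum())
        else:
            delta = 0.0
            members = rng.choice(len(genes), size=size, replace=False)
        truth.planted_sets[term] = float(delta)
        sets[term] = GeneSet(
            name=f"planted {delta:+g}" if delta else "null set",
            namespace="BP" if i % 2 == 0 else "CC",
            genes=tuple(genes[j] for j in np.sort(members)),
        )
    return catalog, GeneSetCollection(sets=sets)


def simulate_regulatory_network(
    clusters: dict[str, set],
    universe,
    n_global: int = 2,
    n_local: int = 2,
    background_tfs: int = 10,
    edge_noise: float = 0.0,
    target_fraction: float = 0.8,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> tuple[RegulatoryNetwork, dict[str, str]]:
    """Network with planted global, local, and background regulators.

    Global TFs target ``target_fraction`` of every cluster; each local TF
    targets that fraction of a single cluster's *exclusive* genes (members
    of no other cluster), so that narrow regulators stay narrow even when
    cluster gene content overlaps; background TFs target a uniform random
    sample of the universe.  ``edge_noise`` rewires that fraction of each
    TF's edges at random.
    """
    if not clusters:
        raise ValueError("no clusters given")
    rng = np.random.default_rng(seed)
    universe = sorted(set(universe))
    cluster_names = sorted(clusters)
    exclusive = {
        c: set(clusters[c])
        - set().union(*(set(clusters[o]) for o in cluster_names if o != c), set())
        for c in cluster_names
    }
    # plant local TFs where a distinctive target set exists
    local_hosts = sorted(cluster_names, key=lambda c: -len(exclusive[c]))
    local_hosts = [c for c in local_hosts if exclusive[c]] or cluster_names
    mean_size = max(1, int(np.mean([len(clusters[c]) for c in cluster_names])))
    targets: dict[str, set] = {}
    planted: dict[str, str] = {}

    def sample_fraction(pool: set) -> set:
        pool = sorted(pool)
        k = max(1, int(round(target_fraction * len(pool))))
        return set(rng.choice(pool, size=k, replace=False))

    for i in range(n_global):
        tf = f"GTF{i + 1:02d}"
        tg: set = set()
        for c in cluster_names:
            tg |= sample_fraction(clusters[c])
        targets[tf] = tg
        planted[tf] = "global"
    for i in range(n_local):
        tf = f"LTF{i + 1:02d}"
        c = local_hosts[i % len(local_hosts)]
        targets[tf] = sample_fraction(exclusive[c] or clusters[c])
        planted[tf] = "local"
    for i in range(background_tfs):
        tf = f"BTF{i + 1:02d}"
        targets[tf] = set(rng.choice(universe, size=min(mean_size, len(universe)), replace=False))
        planted[tf] = "background"
    if edge_noise > 0:
        for tf in targets:
            tg = sorted(targets[tf])
            n_flip = int(round(edge_noise * len(tg)))
            if n_flip:
                removed = set(rng.choice(tg, size=n_flip, replace=False))
                candidates = sorted(set(universe) - targets[tf])
                added = set(rng.choice(candidates, size=min(n_flip, len(candidates)), replace=False))
                targets[tf] = (targets[tf] - removed) | added
    if truth is not None:
        truth.planted_tfs.update(planted)
    return RegulatoryNetwork(targets=targets), planted


def default_competition_design(
    n_mutants: int = 6, plate: str = "P1", n_wt_wt: int = 2
) -> CompetitionDesign:
    """A small plate: mutants, WT/WT anchors, and one reference per color."""
    wells = {}
    for i in range(n_mutants):
        well = f"{plate}-M{i + 1:02d}"
        wells[well] = WellAssignment(well=well, strain=f"mut{i + 1:02d}", plate=plate, kind="mutant")
    for i in range(n_wt_wt):
        well = f"{plate}-W{i + 1:02d}"
        wells[well] = WellAssignment(well=well, strain="WT/WT", plate=plate, kind="wt_wt")
    for color in ("rfp", "cfp"):
        well = f"{plate}-R{color.upper()}"
        wells[well] = WellAssignment(
            well=well, strain=f"WT_{color.upper()}", plate=plate, kind=f"ref_{color}"
        )
    return CompetitionDesign(wells=wells)


def simulate_plate_truth(
    design: CompetitionDesign,
    seed: int = 0,
    a_mean: float = 0.69,
    a_sd: float = 0.3,
    s_sd: float = 0.15,
    g_sd: float = 0.02,
    c_sd: float = 0.05,
    days=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
    times=(2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0),
) -> dict:
    """Draw per-well (A, S, G) and centered per-plate C effects.

    ``a_mean`` defaults to ln 2, the 2:1 RFP:CFP mixing ratio of the assay.
    WT/WT wells get S = G = 0 by construction.
    """
    rng = np.random.default_rng(seed)
    truth: dict = {}
    for plate in design.plates:
        wells = {}
        for w in design.wells_of(plate, {"mutant", "wt_wt"}):
            a = float(rng.normal(a_mean, a_sd))
            if design.wells[w].kind == "wt_wt":
                wells[w] = (a, 0.0, 0.0)
            else:
                wells[w] = (a, float(rng.normal(0.0, s_sd)), float(rng.normal(0.0, g_sd)))
        c = rng.normal(0.0, c_sd, size=len(days) * len(times))
        c -= c.mean()  # sum-to-zero, matching the fit's identifiability constraint
        c_map = {
            (float(T), float(t)): float(c[i * len(times) + j])
            for i, T in enumerate(days)
            for j, t in enumerate(times)
        }
        truth[plate] = {"wells": wells, "C": c_map}
    return truth


def _od_curve(t: float) -> float:
    return 0.05 + 0.95 / (1.0 + np.exp(-0.6 * (t - 8.0)))


def simulate_competition_plate(
    design: CompetitionDesign,
    truth: dict,
    noise_sd: float = 0.1,
    days=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
    times=(2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0),
    seed: int = 0,
    background: float = 50.0,
    total_signal: float = 8000.0,
) -> pd.DataFrame:
    """Forward-model plate-reader series from the competitive-aging model.

    For competition wells ``y = A + S*T + G*t + C + Normal(0, noise_sd^2)``
    is exponentiated into an RFP/CFP pair splitting a logistic outgrowth
    signal, then a constant background is added to both channels.
    Single-color reference wells carry the full signal in their own channel
    and pure background in the other.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for plate in design.plates:
        plate_truth = truth[plate]
        for well in sorted(design.wells):
            assign = design.wells[well]
            if assign.plate != plate:
                continue
            for T in days:
                for t in times:
                    od = _od_curve(t)
                    signal = total_signal * od
                    if assign.kind in ("mutant", "wt_wt"):
                        a, s, g = plate_truth["wells"][well]
                        c = plate_truth["C"][(float(T), float(t))]
                        y = a + s * T + g * t + c
                        if noise_sd > 0:
                            y += rng.normal(0.0, noise_sd)
                        frac_rfp = np.exp(y) / (1.0 + np.exp(y))
                        rfp = signal * frac_rfp + background
                        cfp = signal * (1.0 - frac_rfp) + background
                    elif assign.kind == "ref_rfp":
                        rfp, cfp = signal + background, background
                    else:  # ref_cfp
                        rfp, cfp = background, signal + background
                    rows.append(
                        {
                            "plate": plate,
                            "well": well,
                            "strain": assign.strain,
                            "is_wt_wt": assign.kind == "wt_wt",
                            "aging_day": float(T),
                            "outgrowth_hour": float(t),
                            "od": float(od),
                            "rfp": float(rfp),
                            "cfp": float(cfp),
                        }
                    )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def write_input_bundle(
    outdir: str | Path,
    seed: int = 0,
    n_genes: int = 2000,
    dataset_params: list[DatasetParams] | None = None,
    n_sets: int = 40,
    shift: float = 2.0,
    n_plates: int = 1,
) -> SyntheticTruth:
    """Write a complete, self-consistent input bundle into a directory.

    Produces oriented screen TSVs with a profiles YAML, a curated-catalog
    TSV, gene sets in GMT, a TF-network TSV (planted on the enriched-set
    gene content), competition-plate TSVs, and the recorded truth JSON.
    Planted set shifts are applied to the latent effects *before* screens
    are drawn so that downstream enrichment is real.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=6)]

    # latent first, then sets (which tilt membership toward latent extremes),
    # then screens from the same latent truth
    truth = SyntheticTruth(seed=seed)
    genes = _gene_names(n_genes)
    lat_rng = np.random.default_rng(sub[0])
    truth.latent = dict(zip(genes, lat_rng.standard_normal(n_genes)))
    catalog, sets = simulate_catalog_and_sets(
        truth, n_sets=n_sets, shift=shift, seed=sub[1]
    )
    profiles = simulate_profiles(5 if dataset_params is None else len(dataset_params), sub[2])
    screens, truth = simulate_screens(
        n_genes=n_genes,
        dataset_params=dataset_params,
        seed=sub[3],
        profiles=profiles,
        truth=truth,
    )

    screen_dir = outdir / "screens"
    screen_dir.mkdir(exist_ok=True)
    profile_map = {}
    for ds in screens:
        pd.DataFrame({"gene": sorted(ds.values), "value": [ds.values[g] for g in sorted(ds.values)]}).to_csv(
            screen_dir / f"{ds.name}.tsv", sep="\t", index=False
        )
        prof = asdict(ds.profile) if ds.profile else {}
        prof.pop("extra", None)
        profile_map[ds.name] = prof
    (outdir / "profiles.yaml").write_text(yaml.safe_dump(profile_map, sort_keys=True))

    pd.DataFrame(
        {
            "gene": catalog.genes,
            "label": [catalog.labels[g] for g in catalog.genes],
            "sources": [";".join(sorted(catalog.sources.get(g, set()))) for g in catalog.genes],
        }
    ).to_csv(outdir / "catalog.tsv", sep="\t", index=False)

    from clsmeta.gsea import write_gmt

    write_gmt(sets, outdir / "sets.gmt")

    planted_clusters = {
        term: set(sets.sets[term].genes)
        for term, delta in truth.planted_sets.items()
        if delta != 0.0
    }
    network, _ = simulate_regulatory_network(
        planted_clusters, genes, seed=sub[4], truth=truth
    )
    edges = [(tf, tg) for tf in network.tfs for tg in sorted(network.targets[tf])]
    pd.DataFrame(edges, columns=["tf", "target"]).assign(evidence="both").to_csv(
        outdir / "network.tsv", sep="\t", index=False
    )

    frames = []
    for p in range(n_plates):
        design = default_competition_design(n_mutants=6, plate=f"P{p + 1}")
        plate_truth = simulate_plate_truth(design, seed=sub[5] + p)
        truth.plate_truth.update(plate_truth)
        frames.append(
            simulate_competition_plate(design, plate_truth, noise_sd=0.1, seed=sub[5] + p)
        )
    pd.concat(frames, ignore_index=True).to_csv(outdir / "plates.tsv", sep="\t", index=False)

    truth.to_json(outdir / "truth.json")
    return truth
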
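"""Orchestrate the full meta-analysis from a declarative config file.

Stage order: harmonize -> concordance -> evaluation -> outranking ->
rankdist -> gsea -> regulators; the competitive-aging fit runs independently
on plate inputs.  Every stage writes its TSV outputs into the configured
output directory and contributes to a machine-readable JSON summary; any
stage failure aborts with the stage name.  All thresholds (tail fractions,
Ji > 0.1, 10-100 set sizes, TF relevance alpha, growth-defect cutoff) live
in the config, never in code.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from clsmeta import __version__, compete, concordance, evaluation, gsea, harmonize
from clsmeta import outranking as outranking_mod
from clsmeta import rankdist, regulators

log = logging.getLogger(__name__)

STAGES = [
    "harmonize",
    "concordance",
    "evaluation",
    "outranking",
    "rankdist",
    "gsea",
    "regulators",
]

_DEPENDENCIES = {
    "harmonize": [],
    "concordance": ["harmonize"],
    "evaluation": ["harmonize"],
    "outranking": ["harmonize", "evaluation"],
    "rankdist": ["outranking"],
    "gsea": ["outranking"],
    "regulators": ["gsea"],
}


@dataclass
class DatasetEntry:
    path: str
    name: str
    orientation: str = "higher_is_longer"
    profile: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    """Declarative description of one meta-analysis run."""

    datasets: list[DatasetEntry]
    out_dir: str = "results"
    seed: int = 0
    catalog: str | None = None
    criteria: list[str] | None = None
    weight_scheme: str = "equal"
    priority_vector: list[float] | None = None
    exclude_same_source: bool = False
    missing_policy: str = "renormalize"
    gene_sets: str | None = None
    gsea_n_perm: int = 10_000
    gsea_min_size: int = 10
    gsea_max_size: int = 100
    network: str | None = None
    tail_fraction: float = 0.05
    ji_threshold: float = 0.1
    cluster_cut_height: float = 0.9
    relevance_alpha: float = 0.01
    growth_defect_threshold: float = 0.95
    variables: list[str] = field(default_factory=list)
    plates: str | None = None
    base_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        raw["datasets"] = [DatasetEntry(**d) for d in raw.get("datasets", [])]
        raw.setdefault("base_dir", str(path.parent))
        cfg = cls(**raw)
        for entry in cfg.datasets:
            if not cfg.resolve(entry.path).exists():
                raise FileNotFoundError(f"dataset file not found: {entry.path}")
        return cfg

    def resolve(self, p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else Path(self.base_dir) / p


@dataclass
class MetaAnalysisReport:
    """In-memory handles to every stage's result plus the JSON summary."""

    datasets: list = field(default_factory=list)
    ranked: dict = field(default_factory=dict)
    concordance: object = None
    variable_model: object = None
    catalog: object = None
    rocs: dict = field(default_factory=dict)
    weights: object = None
    outranking: object = None
    gsea_results: list = field(default_factory=list)
    term_network: object = None
    leading_edges: dict = field(default_factory=dict)
    regulator_profiles: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def _expand_stages(stages) -> list[str]:
    wanted = set(stages)
    changed = True
    while changed:
        changed = False
        for s in list(wanted):
            for dep in _DEPENDENCIES[s]:
                if dep not in wanted:
                    wanted.add(dep)
                    changed = True
    return [s for s in STAGES if s in wanted]


def run_meta_analysis(cfg: RunConfig, stages=None) -> MetaAnalysisReport:
    """Execute the configured stages and write the report bundle."""
    stages = _expand_stages(stages or STAGES)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = MetaAnalysisReport()
    report.summary = {"version": __version__, "seed": cfg.seed, "stages": stages}
    for stage in stages:
        try:
            _STAGE_FUNCS[stage](cfg, report, out)
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    with open(out / "summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=1, sort_keys=True, default=str)
    return report


def _stage_harmonize(cfg: RunConfig, report: MetaAnalysisReport, out: Path) -> None:
    for entry in cfg.datasets:
        profile = harmonize.ExperimentalProfile(**entry.profile) if entry.profile else None
        ds = harmonize.load_screen_table(
            cfg.resolve(entry.path), entry.name, profile=profile, orientation=entry.orientation
        )
        report.datasets.append(ds)
        report.ranked[ds.name] = harmonize.rank_genes(ds)
        harmonize.write_ranked_table(ds, out / f"ranked_{ds.name}.tsv")
    shared = harmonize.shared_genes(report.datasets)
    pooled = harmonize.pooled_gene_universe(report.datasets)
    report.summary["harmonize"] = {
        "n_datasets": len(report.datasets),
        "n_shared_genes": len(shared),
        "n_pooled_genes": len(pooled),
    }


def _stage_concordance(cfg: RunConfig, report: MetaAnalysisReport, out: Path) -> None:
    if len(report.datasets) < 2:
        report.summary["concordance"] = {"skipped": "fewer than two datasets"}
        return
    shared = harmonize.shared_genes(report.datasets)
    mat = concordance.spearman_matrix(report.datasets, shared)
    report.concordance = mat
    mat.rho.to_csv(out / "spearman_rho.tsv", sep="\t")
    mat.p_value.to_csv(out / "spearman_p.tsv", sep="\t")
    summary = {"n_shared_genes": mat.n_genes, "max_offdiag_rho": float(np.max(mat.rho.to_numpy()[~np.eye(len(mat.datasets), dtype=bool)]))}
    profiles = {ds.name: ds.profile for ds in report.datasets if ds.profile is not None}
    pairs = mat.pairs()
    if cfg.variables and len(profiles) == len(report.datasets) and len(pairs) >= len(cfg.variables) + 2:
        model = concordance.shared_variable_model(pairs, profiles, cfg.variables)
        report.variable_model = model
        pd.DataFrame(
            {
                "variable": list(model.coefficients),
                "coefficient": list(model.coefficients.values()),
                "p_value": [model.p_values[v] for v in model.coefficients],
            }
        ).to_csv(out / "shared_variable_model.tsv", sep="\t", index=False)
        summary["r2_adjusted"] = model.r2_adjusted
    report.summary["concordance"] = summary


def _stage_evaluation(cfg: RunConfig, report: MetaAnalysisReport, out: Path) -> None:
    criteria = cfg.criteria or [ds.name for ds in report.datasets]
    aucs = {}
    if cfg.catalog:
        report.catalog = evaluation.load_catalog(cfg.resolve(cfg.catalog))
        for name in criteria:
            roc = evaluation.roc_curve(
                report.ranked[name],
                report.catalog,
                exclude_same_source=cfg.exclude_same_source,
                dataset_source=name,
            )
            report.rocs[name] = roc
            aucs[name] = roc.auc
        pd.DataFrame(
            {"dataset": list(aucs), "auc": [round(a, 4) for a in aucs.values()]}
        ).to_csv(out / "roc_auc.tsv", sep="\t", index=False)
    scheme = cfg.weight_scheme
    if scheme == "auc_proportional" and not aucs:
        raise ValueError("auc_proportional weights require a curated catalog")
    report.weights = evaluation.make_weights(
        criteria, scheme=scheme, aucs=aucs or None, priority_vector=cfg.priority_vector
    )
    report.summary["evaluation"] = {
        "weights": report.weights.rounded(),
        "auc": {k: round(v, 4) for k, v in aucs.items()},
    }


def _stage_outranking(cfg: RunConfig, report: MetaAnalysisReport, out: Path) -> None:
    criteria = cfg.criteria or [ds.name for ds in report.datasets]
    by_name = {ds.name: ds for ds in report.datasets}
    matrix = outranking_mod.CriteriaMatrix.from_datasets(
        [by_name[c] for c in criteria], report.weights
    )
    result = outranking_mod.net_flows(matrix, missing_policy=cfg.missing_policy)
    report.outranking = result
    result.to_frame().to_csv(out / "consensus_rank.tsv", sep="\t", index=False)
    report.summary["outranking"] = {
        "n_alternatives": len(matrix.alternatives),
        "criteria": criteria,
        "missing_policy": cfg.missing_policy,
        "phi_sum": float(sum(result.phi.values())),
    }


def _stage_rankdist(cfg: RunConfig, report: MetaAnalysisReport, out: Path) -> None:
    if report.catalog is None:
        report.summary["rankdist"] = {"skipped": "no curated catalog"}
        return
    rank = report.outranking.rank
    summary = {}
    rows = []
    for label, tail in (("long", "top"), ("short", "bottom")):
        genes = {g for g, lab in report.catalog.labels.items() if lab == label}
        genes &= set(rank)
        if not genes:
            continue
        shift = rankdist.rank_shift_test(
            rank, genes, alternative="toward_top" if label == "long" else "toward_bottom"
        )
        enr = rankdist.tail_enrichment(rank, genes, tail=tail, fraction=cfg.tail_fraction)
        rows.append(
            {
                "set": f"curated_{label}",
                "n": len(genes),
                "wilcoxon_p": shift.p_value,
                "tail": tail,
                "tail_overlap": enr.overlap,
                "tail_expected": enr.expected,
                "hypergeom_p": enr.p_value,
            }
        )
        summary[label] = {"wilcoxon_p": shift.p_value, "tail_p": enr.p_value}
    pd.DataFrame(rows).to_csv(out / "catalog_rank_tests.tsv", sep="\t", index=False)
    report.summary["rankdist"] = summary


def _stage_gsea(cfg: RunConfig, report: MetaAnalysisReport, out: Path) -> None:
    if not cfg.gene_sets:
        report.summary["gsea"] = {"skipped": "no gene sets configured"}
        return
    sets = gsea.read_gmt(cfg.resolve(cfg.gene_sets))
    results = gsea.preranked_gsea(
        report.outranking.phi,
        sets,
        min_size=cfg.gsea_min_size,
        max_size=cfg.gsea_max_size,
        n_perm=cfg.gsea_n_perm,
        seed=cfg.seed,
    )
    report.gsea_results = results
    gsea.results_frame(results).to_csv(out / "gsea_results.tsv", sep="\t", index=False)
    significant = [r for r in results if r.fdr < 0.05]
    report.summary["gsea"] = {
        "n_tested": len(results),
        "n_significant": len(significant),
        "n_perm": cfg.gsea_n_perm,
    }
    if significant:
        net = gsea.term_network(
            significant,
            sets,
            universe=list(report.outranking.phi),
            ji_threshold=cfg.ji_threshold,
            cut_height=cfg.cluster_cut_height,
        )
        report.term_network = net
        pd.DataFrame(
            [(a, b, d["ji"]) for a, b, d in net.graph.edges(data=True)],
            columns=["term_a", "term_b", "ji"],
        ).to_csv(out / "term_network_edges.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(net.clusters.items()), columns=["term", "cluster"]
        ).to_csv(out / "term_clusters.tsv", sep="\t", index=False)
        report.leading_edges = gsea.cluster_leading_edges(significant, net)
        report.summary["gsea"]["n_clusters"] = len(set(net.clusters.values()))


def _stage_regulators(cfg: RunConfig, report: MetaAnalysisReport, out: Path) -> None:
    if not cfg.network or not report.leading_edges:
        report.summary["regulators"] = {"skipped": "no network or no enriched clusters"}
        return
    network = regulators.load_network_table(cfg.resolve(cfg.network))
    universe = list(report.outranking.phi)
    profiles = regulators.regulator_association(
        report.leading_edges, network, universe, relevance_alpha=cfg.relevance_alpha
    )
    profiles = regulators.classify_breadth(
        profiles, n_clusters=len(report.leading_edges), relevance_alpha=cfg.relevance_alpha
    )
    report.regulator_profiles = profiles
    mat = regulators.association_matrix(profiles)
    mat.to_csv(out / "tf_fraction_matrix.tsv", sep="\t")
    pd.DataFrame(
        {
            "tf": [p.tf for p in profiles],
            "n_significant": [p.n_significant for p in profiles],
            "breadth": [p.breadth for p in profiles],
        }
    ).to_csv(out / "tf_breadth.tsv", sep="\t", index=False)
    report.summary["regulators"] = {
        "n_retained": len(profiles),
        "breadth_counts": {
            k: int(v)
            for k, v in pd.Series([p.breadth for p in profiles]).value_counts().items()
        },
    }


_STAGE_FUNCS = {
    "harmonize": _stage_harmonize,
    "concordance": _stage_concordance,
    "evaluation": _stage_evaluation,
    "outranking": _stage_outranking,
    "rankdist": _stage_rankdist,
    "gsea": _stage_gsea,
    "regulators": _stage_regulators,
}


def run_competition_fit(
    plates_path: str | Path,
    out_path: str | Path | None = None,
    od_min: float = 0.05,
    od_max: float = 1.0,
) -> compete.SurvivalFit:
    """Independent competitive-aging stage: background-correct and fit."""
    measurements = compete.load_measurements(plates_path)
    design = compete.design_from_frame(measurements)
    corrected = compete.subtract_background(measurements, design)
    fit = compete.fit_survival_model(corrected, design, od_min=od_min, od_max=od_max)
    if out_path is not None:
        fit.to_frame().to_csv(out_path, sep="\t", index=False)
    return fit
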
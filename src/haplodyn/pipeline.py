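"""End-to-end orchestration: simulate/load -> quantify -> DE -> ASE ->
network -> enrichment/intersection, with one config and one seed.

Every stage is a pure function of its inputs, so a rerun with the same
config reproduces identical numbers; the consolidated report carries the
config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ase_bias, coexpression, diffexpr, enrich_intersect, quantify, synthetic_data
from .io_formats import (
    ConfigurationError,
    PipelineStageError,
    attach_library_sizes,
    get_logger,
    read_count_matrix,
    read_gene_list,
    read_gene_models,
    read_sample_sheet,
    read_term_map,
    write_count_matrix,
    write_json,
)

__all__ = ["PipelineConfig", "run_pipeline"]

_log = get_logger("pipeline")


@dataclass
class PipelineConfig:
    """All pipeline inputs and parameters.

    Either the four real-input paths or ``sim`` (synthetic mode) must be
    set.  Parameter defaults are the study settings: DE alpha 0.05 and BCV
    0.1, twofold ASE criterion, FPKM < 5 low-expression filter, module size
    80 with eigengene merge cut 0.3, |GS| > 0.2, |MM| > 0.8, edge weight
    0.3, expression-class boundaries 5/20/100.
    """

    # inputs: real mode ...
    allele_counts: str | None = None
    gene_counts: str | None = None
    gene_models: str | None = None
    sample_sheet: str | None = None
    # ... or synthetic mode
    sim: synthetic_data.SimConfig | None = None
    # optional extras
    term_map: str | None = None
    external_gene_list: str | None = None
    # parameters
    seed: int = 0
    alpha: float = 0.05
    bcv: float = 0.1
    fold: float = 2.0
    ase_floor: float = 0.5
    fpkm_filter: float = 5.0
    min_module_size: int = 80
    merge_cut_height: float = 0.3
    branch_cut: float = 0.95
    gs_min: float = 0.2
    mm_min: float = 0.8
    edge_weight_min: float = 0.3
    edge_tiers: tuple[int, ...] = (5, 50)
    network_top_genes: int = 2000

    def __post_init__(self):
        real = all(
            getattr(self, k) is not None
            for k in ("allele_counts", "gene_counts", "gene_models", "sample_sheet")
        )
        if not real and self.sim is None:
            raise ConfigurationError(
                "config must set the input paths (allele_counts, gene_counts, "
                "gene_models, sample_sheet) or a 'sim' block for synthetic mode"
            )

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = synthetic_data._config_to_dict(self.sim)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        if d.get("sim") is not None:
            d["sim"] = synthetic_data._config_from_dict(d["sim"])
        if "edge_tiers" in d:
            d["edge_tiers"] = tuple(d["edge_tiers"])
        return cls(**d)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineStageError(name, str(exc)) from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages in dependency order; optionally write the report
    bundle to ``out_dir``.  Returns the in-memory report."""
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    artifacts: dict = {}

    # ---- inputs ----------------------------------------------------------
    @_stage("inputs")
    def load():
        if config.sim is not None:
            sim = synthetic_data.simulate(
                dataclasses.replace(config.sim, seed=config.seed)
            )
            return sim.allele_counts, sim.gene_counts, sim.models, sim.samples, sim
        allele = read_count_matrix(config.allele_counts, id_kind="allele")
        gene = read_count_matrix(config.gene_counts, id_kind="gene")
        models = read_gene_models(config.gene_models)
        samples = attach_library_sizes(read_sample_sheet(config.sample_sheet), gene)
        return allele, gene, models, samples, None

    allele_counts, gene_counts, models, samples, sim = load()
    report["n_genes"] = int(gene_counts.shape[0])
    report["n_samples"] = int(gene_counts.shape[1])

    # ---- quantification --------------------------------------------------
    @_stage("quantify")
    def do_quantify():
        expr = quantify.fpkm(gene_counts, models)
        classes = quantify.expression_classes(expr)
        corr, linkage, newick = quantify.sample_correlation(expr)
        retained = quantify.low_expression_filter(expr, config.fpkm_filter)
        return expr, classes, corr, newick, retained

    expr, classes, corr, newick, retained = do_quantify()
    report["expression_classes"] = {cls: classes.loc[cls].to_dict() for cls in classes.index}
    report["n_genes_pass_fpkm_filter"] = int(len(retained))
    artifacts.update(fpkm=expr, classes=classes, sample_correlation=corr, dendrogram=newick)

    # ---- differential expression ----------------------------------------
    @_stage("diffexpr")
    def do_de():
        return diffexpr.run_de(gene_counts, samples, alpha=config.alpha, bcv=config.bcv)

    de_table, de_sum = do_de()
    report["de"] = {
        "per_comparison": de_sum["per_comparison"],
        "pooled_union": {
            k: de_sum["pooled_union"][k] for k in ("n_up", "n_down", "n_conflicting")
        },
    }
    artifacts["de_results"] = de_table
    artifacts["de_summary"] = de_sum

    # ---- allele-specific expression --------------------------------------
    @_stage("ase")
    def do_ase():
        return ase_bias.run_ase(
            allele_counts, models, samples, fold=config.fold, floor=config.ase_floor
        )

    trajectories, ase_summary, ase_sets = do_ase()
    report["ase"] = ase_summary.as_dict()
    artifacts["trajectories"] = trajectories
    artifacts["ase_sets"] = ase_sets

    # ---- co-expression network -------------------------------------------
    @_stage("network")
    def do_network():
        sub = expr.loc[retained]
        if len(sub) > config.network_top_genes:
            variances = sub.var(axis=1).sort_values(ascending=False)
            sub = sub.loc[variances.index[: config.network_top_genes]]
        network = coexpression.build_network(
            sub,
            samples,
            min_module_size=config.min_module_size,
            merge_cut_height=config.merge_cut_height,
            branch_cut=config.branch_cut,
        )
        if network.eigengenes.shape[1]:
            hub = coexpression.hub_screen(
                network,
                gs_min=config.gs_min,
                mm_min=config.mm_min,
                edge_weight_min=config.edge_weight_min,
                edge_tiers=config.edge_tiers,
            )
        else:
            hub = None
        return network, hub

    network, hub = do_network()
    report["network"] = {
        "beta": network.beta,
        "n_modules": int(network.eigengenes.shape[1]),
        "module_sizes": network.modules[network.modules != coexpression.GREY]
        .value_counts()
        .to_dict(),
        "n_grey": int((network.modules == coexpression.GREY).sum()),
    }
    if hub is not None:
        report["network"]["n_hub_genes"] = int(len(hub["hubs"]))
    artifacts["network"] = network
    artifacts["hub"] = hub

    # ---- enrichment & intersections --------------------------------------
    @_stage("enrich_intersect")
    def do_enrich():
        out = {}
        if config.term_map is not None:
            term_map = read_term_map(config.term_map)
            universe = set(retained)
            interest = (ase_sets["salt_union"] | ase_sets["drought_union"]) & universe
            out["enrichment"] = enrich_intersect.fisher_enrich(
                interest, universe, term_map, alpha=config.alpha
            )
        if hub is not None:
            tier_sets = {
                "salt_specific": ase_sets["salt_union"] - ase_sets["drought_union"],
                "drought_specific": ase_sets["drought_union"] - ase_sets["salt_union"],
                "both": ase_sets["salt_union"] & ase_sets["drought_union"],
            }
            out["ase_network"] = enrich_intersect.ase_network_overlap(
                tier_sets, hub["edge_count"], thresholds=config.edge_tiers
            )
        if config.external_gene_list is not None:
            external = read_gene_list(config.external_gene_list)
            out["external"] = enrich_intersect.external_list_overlap(
                ase_sets["salt_union"], ase_sets["drought_union"], external
            )
        return out

    extras = do_enrich()
    if "ase_network" in extras:
        report["ase_network_overlap"] = extras["ase_network"].to_dict(orient="records")
    if "external" in extras:
        report["external_overlap"] = {
            k: v for k, v in extras["external"].items() if not isinstance(v, dict)
        }
    if "enrichment" in extras:
        enr = extras["enrichment"]
        report["enrichment"] = {
            "n_terms_tested": int(len(enr)),
            "n_enriched": int(enr["enriched"].sum()) if len(enr) else 0,
        }
    artifacts.update(extras)

    if out_dir is not None:
        _write_bundle(Path(out_dir), config, report, artifacts, sim)
    report["artifacts"] = artifacts
    return report


def _write_bundle(out_dir: Path, config, report, artifacts, sim) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if sim is not None:
        synthetic_data.write_fixture(out_dir / "inputs", sim)
    artifacts["fpkm"].to_csv(out_dir / "fpkm.tsv", sep="\t")
    artifacts["classes"].to_csv(out_dir / "expression_classes.tsv", sep="\t")
    artifacts["sample_correlation"].to_csv(out_dir / "sample_correlation.tsv", sep="\t")
    (out_dir / "sample_dendrogram.nwk").write_text(artifacts["dendrogram"] + "\n")
    artifacts["de_results"].to_csv(out_dir / "de_results.tsv", sep="\t", index=False)
    write_json(artifacts["de_summary"], out_dir / "deg_summary.json")
    artifacts["trajectories"].to_csv(out_dir / "trajectories.tsv", sep="\t", index=False)
    network = artifacts["network"]
    network.modules.rename("module").to_csv(out_dir / "modules.tsv", sep="\t")
    network.eigengenes.to_csv(out_dir / "eigengenes.tsv", sep="\t")
    network.module_trait_cor.to_csv(out_dir / "module_trait_cor.tsv", sep="\t")
    network.module_trait_p.to_csv(out_dir / "module_trait_p.tsv", sep="\t")
    if artifacts.get("hub") is not None:
        artifacts["hub"]["edges"].to_csv(out_dir / "edges.tsv", sep="\t", index=False)
        artifacts["hub"]["hubs"].to_csv(out_dir / "hubs.tsv", sep="\t", index=False)
    if "enrichment" in artifacts:
        artifacts["enrichment"].to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
    sets_dir = out_dir / "responsive_sets"
    sets_dir.mkdir(exist_ok=True)
    for name, genes in artifacts["ase_sets"].items():
        (sets_dir / f"{name}.txt").write_text("".join(f"{g}\n" for g in sorted(genes)))
    write_json(report, out_dir / "report.json")
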
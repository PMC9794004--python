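"""End-to-end orchestration of the dual-omics analysis.

From three aligned inputs (species relative abundances, annotated metabolite
abundances with a pathway mapping, clinical metadata) the pipeline runs:
differential screens (metabolites, species, genera, optional KO pathways) ->
pathway activity scoring and comparison -> full-cohort and bootstrapped
co-occurrence networks -> balance selection against the group label and each
OGTT glucose endpoint -> sPLS and Spearman association maps -> random-forest
Shapley attribution of species to every significantly altered pathway.
All stage outputs land in one directory as TSV/JSON, with a manifest that
records every parameter and seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from dualomics import balance as balance_mod
from dualomics import diffstats, integrate, netboot, papi_score, shap_attr
from dualomics.core_io import (
    AbundanceTable,
    MetaboliteTable,
    SampleMetadata,
    collapse_to_genus,
    read_abundance_table,
    read_metabolite_table,
    read_metadata,
    select_top_taxa,
    write_manifest,
    write_results,
)
from dualomics.errors import ValidationError

log = logging.getLogger("dualomics.pipeline")

CLINICAL_COLUMNS = [
    "ogtt_glucose_0h",
    "ogtt_glucose_1h",
    "ogtt_glucose_2h",
    "homa_ir",
    "fasting_insulin",
    "hba1c",
    "bmi_prepregnancy",
    "tg",
    "neutrophil_count",
    "neutrophil_pct",
    "lymphocyte_pct",
]


@dataclass
class RunConfig:
    """All knobs of one pipeline run; see module docstring for the stages."""

    abundance_path: str | None = None
    metabolite_path: str | None = None
    pathway_map_path: str | None = None
    pathway_sizes_path: str | None = None
    metadata_path: str | None = None
    ko_pathway_path: str | None = None
    out_dir: str = "results"
    fdr_discovery: float = 0.2
    fdr_strict: float = 0.05
    top_k: int = 50
    rho_min: float = 0.3
    network_alpha: float = 0.05
    n_boot: int = 100
    subsample: int = 30
    balance_max_size: int = 8
    balance_folds: int = 5
    balance_repeats: int = 10
    spls_components: int = 2
    spls_keep_x: int = 10
    spls_keep_y: int = 5
    rf_trees: int = 500
    shap_permutations: int = 200
    seeds: dict = field(default_factory=lambda: {"network": 0, "balance": 0, "shap": 0})

    def __post_init__(self) -> None:
        for name in ("fdr_discovery", "fdr_strict", "network_alpha"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must be in (0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _align(
    abundance: AbundanceTable,
    metabolites: MetaboliteTable,
    metadata: SampleMetadata,
) -> tuple[AbundanceTable, MetaboliteTable, SampleMetadata]:
    shared = [
        s
        for s in abundance.sample_ids
        if s in set(metabolites.sample_ids) and s in set(metadata.sample_ids)
    ]
    if len(shared) < 10:
        raise ValidationError(
            f"only {len(shared)} samples shared across inputs (need >= 10)"
        )
    log.info("aligned %d shared samples", len(shared))
    return (
        abundance.subset_samples(shared),
        MetaboliteTable(
            metabolites.data.loc[shared],
            metabolites.pathway_map,
            metabolites.pathway_sizes,
        ),
        metadata.subset_samples(shared),
    )


def run_pipeline(
    abundance: AbundanceTable,
    metabolites: MetaboliteTable,
    metadata: SampleMetadata,
    config: RunConfig,
    ko_pathways: pd.DataFrame | None = None,
) -> dict:
    """Run every stage on in-memory tables; returns a dict of results."""
    t0 = time.time()
    abundance, metabolites, metadata = _align(abundance, metabolites, metadata)
    groups = metadata.groups
    results: dict = {"n_samples": abundance.n_samples}

    # --- differential screens -------------------------------------------
    log.info("stage diffstats")
    results["diff_metabolites"] = diffstats.wilcoxon_bh(metabolites.data, groups)
    results["diff_species"] = diffstats.wilcoxon_bh(abundance.data, groups)
    genus = collapse_to_genus(abundance)
    results["diff_genera"] = diffstats.wilcoxon_bh(genus.data, groups)
    if ko_pathways is not None:
        results["diff_ko_pathways"] = diffstats.wilcoxon_bh(ko_pathways, groups)
    else:
        log.info("KO pathway table absent: KO stage skipped")
    results["diversity"] = diffstats.diversity(abundance)

    # --- pathway activity ------------------------------------------------
    log.info("stage papi_score")
    scores = papi_score.score_pathways(metabolites)
    results["pathway_scores"] = scores
    results["diff_pathways"] = papi_score.compare_pathway_scores(
        scores, groups, fdr_cutoff=config.fdr_discovery
    )

    # --- networks ---------------------------------------------------------
    log.info("stage netboot")
    top = select_top_taxa(abundance, min(config.top_k, abundance.n_taxa))
    nets = {}
    for g in ("GDM", "NGT"):
        sub = top.subset_samples([s for s, lab in groups.items() if lab == g])
        nets[g] = netboot.build_network(
            sub, rho_min=config.rho_min, alpha=config.fdr_strict, group=g
        )
    results["networks"] = nets
    results["core_species"] = {
        g: netboot.core_species(nets[g], top_n=10) for g in nets
    }
    subsample = min(
        config.subsample, int((groups == "GDM").sum()), int((groups == "NGT").sum())
    )
    store = netboot.bootstrap_networks(
        top,
        groups,
        subsample_size=subsample,
        n_replicates=config.n_boot,
        rho_min=config.rho_min,
        alpha=config.network_alpha,
        seed=config.seeds.get("network", 0),
    )
    results["bootstrap_store"] = store
    results["network_metric_comparison"] = netboot.compare_metric_distributions(
        store
    )
    results["network_metric_comparison_ranksum"] = (
        netboot.compare_metric_distributions(store, method="ranksum")
    )

    # --- balances ---------------------------------------------------------
    log.info("stage balance")
    positive = balance_mod.replace_zeros(top)
    bal_seed = config.seeds.get("balance", 0)
    results["balance_group"] = balance_mod.fit_balance(
        positive,
        groups == "GDM",
        response_type="binary",
        max_size=config.balance_max_size,
        cv_folds=config.balance_folds,
        cv_repeats=config.balance_repeats,
        seed=bal_seed,
    )
    for i, col in enumerate(
        ("ogtt_glucose_0h", "ogtt_glucose_1h", "ogtt_glucose_2h")
    ):
        if col in metadata.data.columns:
            results[f"balance_{col}"] = balance_mod.fit_balance(
                positive,
                metadata.data[col],
                response_type="continuous",
                max_size=config.balance_max_size,
                cv_folds=config.balance_folds,
                cv_repeats=config.balance_repeats,
                seed=bal_seed + i + 1,
            )

    # --- integration ------------------------------------------------------
    log.info("stage integrate")
    diff_species = diffstats.apply_fdr_threshold(
        results["diff_species"], config.fdr_discovery
    )
    sig_species = [s for s in diff_species.index if s in top.data.columns]
    if len(sig_species) >= 2 and scores.shape[1] >= 2:
        n_comp = min(config.spls_components, len(sig_species), scores.shape[1],
                     abundance.n_samples - 1)
        model = integrate.spls_fit(
            top.data[sig_species],
            scores,
            n_components=n_comp,
            keep_x=config.spls_keep_x,
            keep_y=config.spls_keep_y,
        )
        results["spls_species_pathways"] = integrate.spls_similarity(model)
    clinical = metadata.data[
        [c for c in CLINICAL_COLUMNS if c in metadata.data.columns]
    ]
    if sig_species and clinical.shape[1] > 0:
        results["heatmap_species_clinical"] = integrate.spearman_heatmap(
            top.data[sig_species], clinical
        )
    diff_metab = diffstats.apply_fdr_threshold(
        results["diff_metabolites"], config.fdr_discovery
    )
    if len(diff_metab) > 0 and clinical.shape[1] > 0:
        results["heatmap_metabolites_clinical"] = integrate.spearman_heatmap(
            metabolites.data[list(diff_metab.index)], clinical
        )

    # --- Shapley attribution ---------------------------------------------
    log.info("stage shap_attr")
    sig_pathways = diffstats.apply_fdr_threshold(
        results["diff_pathways"], config.fdr_discovery
    )
    shap_results = {}
    shap_seed = config.seeds.get("shap", 0)
    for i, pathway in enumerate(sig_pathways.index):
        forest = shap_attr.fit_forest(
            top.data,
            scores[pathway],
            n_trees=config.rf_trees,
            seed=shap_seed + i,
        )
        phi = shap_attr.shapley_values(
            forest,
            top.data,
            background_X=top.data,
            n_permutations=config.shap_permutations,
            seed=shap_seed + i,
        )
        comp = shap_attr.compare_shapley_by_group(
            phi, groups, species_filter=sig_species or None
        )
        shap_results[pathway] = {"phi": phi, "comparison": comp, "oob_r2": forest.oob_r2}
    results["shapley"] = shap_results

    results["runtime_s"] = time.time() - t0
    return results


def _dump(results: dict, config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = {}
    for key in (
        "diff_metabolites",
        "diff_species",
        "diff_genera",
        "diff_ko_pathways",
        "diff_pathways",
        "diversity",
        "pathway_scores",
        "network_metric_comparison",
    ):
        if key in results:
            write_results(results[key].reset_index(), out / f"{key}.tsv")
            counts[key] = len(results[key])
    for g, net in results.get("networks", {}).items():
        write_results(net.edges, out / f"network_edges_{g}.tsv")
        counts[f"network_edges_{g}"] = len(net.edges)
    for key, res in results.items():
        if key.startswith("balance_") and hasattr(res, "global_balance"):
            rep = balance_mod.balance_report(res)
            write_results(rep.reset_index(), out / f"{key}_frequencies.tsv")
    for name in ("spls_species_pathways", "heatmap_species_clinical",
                 "heatmap_metabolites_clinical"):
        if name in results:
            write_results(
                results[name].values.rename_axis("feature").reset_index(),
                out / f"{name}.tsv",
            )
    for pathway, res in results.get("shapley", {}).items():
        safe = pathway.replace(" ", "_")
        write_results(res["comparison"].reset_index(), out / f"shapley_{safe}.tsv")
    write_manifest(
        out / "manifest.json",
        config={k: v for k, v in vars(config).items()},
        row_counts=counts,
        runtime_s=results.get("runtime_s"),
    )
    return out


def run_all(config: RunConfig) -> Path:
    """File-based entry point: read inputs, run every stage, write results."""
    for attr in ("abundance_path", "metabolite_path", "metadata_path"):
        if getattr(config, attr) is None:
            raise ValidationError(f"{attr} is required")
    abundance = read_abundance_table(
        config.abundance_path, rank="species", renormalize=True
    )
    metabolites = read_metabolite_table(
        config.metabolite_path,
        pathway_map_path=config.pathway_map_path,
        pathway_sizes_path=config.pathway_sizes_path,
    )
    metadata = read_metadata(config.metadata_path)
    ko = None
    if config.ko_pathway_path is not None:
        ko = pd.read_csv(config.ko_pathway_path, sep="\t", index_col=0).T
    results = run_pipeline(abundance, metabolites, metadata, config, ko_pathways=ko)
    return _dump(results, config)
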
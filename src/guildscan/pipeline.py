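"""End-to-end orchestration: counts in, guilds + statistics out.

``run_analysis`` executes the whole chain in memory (rarefy -> prevalence
filter -> SparCC -> 1-r distance -> Ward -> PERMANOVA tree cut -> guild
abundances -> network, plus diversity and association stages) and returns
every intermediate product. ``run_pipeline`` wraps it with file I/O, a
manifest and a log so a run is reproducible from its output directory
alone.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import mann_whitney_da, spearman_assoc, zscore_table
from .community import (
    alpha_diversity,
    bray_curtis,
    groupwise_tests,
    pairwise_permanova,
    pcoa,
)
from .datatypes import (
    FeatureTable,
    PhenotypeTable,
    RelativeAbundanceTable,
    SampleMetadata,
)
from .guilds import (
    DEFAULT_CUT_ALPHA,
    DEFAULT_CUT_PERMUTATIONS,
    DEFAULT_EDGE_THRESHOLD,
    build_network,
    cut_tree_by_permanova,
    guild_abundance,
    guild_summary,
    to_distance,
    ward_linkage,
)
from .io import (
    read_feature_table,
    read_metadata,
    read_phenotypes,
    write_network,
    write_square_matrix,
    write_tree_newick,
)
from .preprocess import (
    DEFAULT_PREVALENCE,
    DEFAULT_RAREFACTION_DEPTH,
    prevalence_filter,
    rarefy,
    to_relative,
)
from .sparcc import SparccConfig, sparcc, sparcc_pvalues

logger = logging.getLogger("guildscan")

__all__ = ["PipelineParams", "PipelineConfig", "run_analysis", "run_pipeline"]


@dataclass
class PipelineParams:
    """All tunables of a full run, with the standard defaults."""

    rarefaction_depth: int = DEFAULT_RAREFACTION_DEPTH
    prevalence: float = DEFAULT_PREVALENCE
    sparcc_bootstrap: int = 100
    sparcc_dirichlet_draws: int = 20
    compute_sparcc_pvalues: bool = True
    cut_alpha: float = DEFAULT_CUT_ALPHA
    cut_permutations: int = DEFAULT_CUT_PERMUTATIONS
    min_node_size: int = 2
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD
    ward_dialect: str = "ward.D2"
    community_permutations: int = 9999
    association_timepoint: str | None = None  # None = last timepoint seen
    seed: int = 0


@dataclass
class PipelineConfig:
    table_path: str
    metadata_path: str
    phenotype_path: str | None
    out_dir: str
    orientation: str = "asvs-as-rows"
    params: PipelineParams = field(default_factory=PipelineParams)

    def validate(self) -> None:
        for p in (self.table_path, self.metadata_path, self.phenotype_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def run_analysis(
    table: FeatureTable,
    metadata: SampleMetadata,
    phenotypes: PhenotypeTable | None = None,
    params: PipelineParams | None = None,
) -> dict:
    """Run every stage in memory; returns a dict of all products."""
    params = params or PipelineParams()
    seed = params.seed & 0x7FFFFFFF
    out: dict = {"params": params}

    logger.info("input table: %d samples x %d ASVs", *table.shape)
    rarefied, rare_report = rarefy(table, params.rarefaction_depth, seed)
    logger.info(
        "rarefied to %d reads; dropped %d samples below depth: %s",
        params.rarefaction_depth,
        len(rare_report.dropped_samples),
        rare_report.dropped_samples,
    )
    out["rarefied"], out["rarefaction_report"] = rarefied, rare_report

    filtered, prev_report = prevalence_filter(rarefied, params.prevalence)
    logger.info(
        "prevalence filter (>= %.0f%% of samples): %d ASVs kept, %d removed; "
        "retained reads per sample %.2f +/- %.2f %%",
        params.prevalence * 100,
        prev_report.n_retained,
        prev_report.n_removed,
        prev_report.mean_retained_pct,
        prev_report.sd_retained_pct,
    )
    out["filtered"], out["prevalence_report"] = filtered, prev_report
    filtered.require_min_size(2, 4)

    rel_full = to_relative(rarefied)
    rel_filtered = RelativeAbundanceTable(
        rel_full.df[filtered.asv_ids].copy(), closed=False
    )
    out["relative"], out["relative_filtered"] = rel_full, rel_filtered

    cfg = SparccConfig(
        n_dirichlet_draws=params.sparcc_dirichlet_draws,
        n_bootstrap=params.sparcc_bootstrap,
        rng_seed=seed,
    )
    corr, diag = sparcc(filtered, cfg)
    logger.info(
        "SparCC: %d draws, %d values clamped, %d basis variances floored",
        cfg.n_dirichlet_draws, diag.n_clamped, diag.n_floored_variances,
    )
    out["correlations"], out["sparcc_diagnostics"] = corr, diag
    if params.compute_sparcc_pvalues:
        out["sparcc_pvalues"] = sparcc_pvalues(filtered, corr, cfg)

    dist = to_distance(corr)
    tree = ward_linkage(dist, params.ward_dialect)
    assignment = cut_tree_by_permanova(
        tree, dist,
        alpha=params.cut_alpha,
        n_perm=params.cut_permutations,
        seed=seed,
        min_node_size=params.min_node_size,
    )
    logger.info("tree cut: %d ASVs -> %d CAGs", len(dist.ids), assignment.n_cags)
    out["distance"], out["tree"], out["assignment"] = dist, tree, assignment

    guilds = guild_abundance(rel_filtered, assignment)
    out["guild_abundance"] = guilds
    out["guild_summary"] = guild_summary(guilds, metadata)
    out["network"] = build_network(
        corr, assignment, rel_filtered,
        min_abs_r=params.edge_threshold,
        pvalues=out.get("sparcc_pvalues"),
    )

    alpha = alpha_diversity(rarefied)
    out["alpha_diversity"] = alpha
    out["alpha_tests"] = groupwise_tests(alpha, metadata)
    bc = bray_curtis(rarefied)
    out["bray_curtis"], out["pcoa"] = bc, pcoa(bc)
    out["beta_tests"] = pairwise_permanova(
        bc, metadata, n_perm=params.community_permutations, seed=seed
    )

    tp = params.association_timepoint
    if tp is None:
        seen = list(dict.fromkeys(metadata.timepoints))
        tp = seen[-1]
    out["association_timepoint"] = tp
    out["differential"] = mann_whitney_da(guilds, metadata, timepoint=tp)
    out["zscores"] = zscore_table(guilds, metadata, timepoint=tp)
    if phenotypes is not None:
        tp_samples = [
            s for s in guilds.sample_ids
            if metadata.df.loc[s, "timepoint"] == tp and s in phenotypes.df.index
        ]
        from .datatypes import GuildAbundanceTable

        guilds_tp = GuildAbundanceTable(guilds.df.loc[tp_samples].copy())
        phen_tp = PhenotypeTable(phenotypes.df.loc[tp_samples].copy())
        out["associations"] = spearman_assoc(guilds_tp, phen_tp)
    return out


def _write_outputs(results: dict, out_dir: Path) -> dict[str, str]:
    files: dict[str, str] = {}

    def save(name: str, fn) -> None:
        path = out_dir / name
        fn(path)
        files[name] = str(path)

    corr = results["correlations"]
    save("sparcc_correlations.tsv", lambda p: write_square_matrix(corr, p))
    if "sparcc_pvalues" in results:
        pv = pd.DataFrame(results["sparcc_pvalues"], index=corr.ids, columns=corr.ids)
        save("sparcc_pvalues.tsv", lambda p: pv.to_csv(p, sep="\t", index_label="id"))
    save("sparcc_distance.tsv", lambda p: write_square_matrix(results["distance"], p))
    save("cluster_tree.nwk", lambda p: write_tree_newick(results["tree"], p))
    save(
        "cag_assignment.tsv",
        lambda p: results["assignment"].to_frame().to_csv(p, sep="\t"),
    )
    save(
        "cag_abundance.tsv",
        lambda p: results["guild_abundance"].df.to_csv(
            p, sep="\t", index_label="sample_id"
        ),
    )
    save(
        "cag_summary.tsv",
        lambda p: results["guild_summary"].to_csv(p, sep="\t", index=False),
    )
    save("network.graphml", lambda p: write_network(results["network"], p, "graphml"))
    save("network.sif", lambda p: write_network(results["network"], p, "sif"))
    save(
        "alpha_diversity.tsv",
        lambda p: results["alpha_diversity"].to_csv(p, sep="\t", index_label="sample_id"),
    )
    save(
        "alpha_tests.tsv",
        lambda p: results["alpha_tests"].to_csv(p, sep="\t", index=False),
    )
    save("bray_curtis.tsv", lambda p: write_square_matrix(results["bray_curtis"], p))
    save(
        "pcoa_coordinates.tsv",
        lambda p: results["pcoa"].coordinates.to_csv(p, sep="\t", index_label="sample_id"),
    )
    save(
        "beta_tests.tsv",
        lambda p: results["beta_tests"].to_csv(p, sep="\t", index=False),
    )
    save(
        "cag_differential.tsv",
        lambda p: results["differential"].to_csv(p, sep="\t", index=False),
    )
    save(
        "cag_zscores.tsv",
        lambda p: results["zscores"].to_csv(p, sep="\t", index_label="cag"),
    )
    if "associations" in results:
        save(
            "cag_associations.tsv",
            lambda p: results["associations"].to_csv(p, sep="\t", index=False),
        )
    return files


def run_pipeline(config: PipelineConfig) -> dict:
    """Read inputs, run every stage, write all products plus a manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "read-inputs"
    try:
        table = read_feature_table(config.table_path, config.orientation)
        metadata = read_metadata(config.metadata_path)
        phenotypes = (
            read_phenotypes(config.phenotype_path) if config.phenotype_path else None
        )
        stage = "analysis"
        results = run_analysis(table, metadata, phenotypes, config.params)
        stage = "write-outputs"
        files = _write_outputs(results, out_dir)
        manifest = {
            "guildscan_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "seed": config.params.seed,
            "config": {
                "table_path": config.table_path,
                "metadata_path": config.metadata_path,
                "phenotype_path": config.phenotype_path,
                "orientation": config.orientation,
                "params": asdict(config.params),
            },
            "stages": {
                "input_shape": list(table.shape),
                "rarefied_samples": len(results["rarefied"].sample_ids),
                "dropped_samples": results["rarefaction_report"].dropped_samples,
                "filtered_asvs": results["filtered"].shape[1],
                "retained_read_pct_mean": results["prevalence_report"].mean_retained_pct,
                "retained_read_pct_sd": results["prevalence_report"].sd_retained_pct,
                "n_cags": results["assignment"].n_cags,
                "n_network_edges": results["network"].number_of_edges(),
                "association_timepoint": results["association_timepoint"],
            },
            "outputs": sorted(files),
        }
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
        results["manifest"] = manifest
        return results
    except Exception as exc:
        logger.exception("pipeline failed at stage %r", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
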
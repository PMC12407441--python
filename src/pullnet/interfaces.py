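"""End-to-end orchestration: configuration, run directory, manifest.

`run_all` drives the whole pipeline — omics QC, metabolite-to-protein seed
mapping, virtual pulldown, over-representation analysis, classification and
reporting — from real input files or from the synthetic generator, and
writes every artifact plus a machine-readable manifest into a run
directory. `run_synthetic_benchmark` evaluates planted-module recovery
against the generator's ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from . import __version__
from .assoc_map import AssociationTable, SeedMap, association_stats, resolve_metabolites
from .enrich import (
    GeneSetCollection,
    classify_networks,
    enrich_collection,
    rank_networks,
    seed_q_values,
)
from .omics_qc import (
    clr_transform,
    detect_outliers,
    filter_asvs,
    metabolite_qc_pipeline,
)
from .pulldown import Interactome, PulldownParams, run_pulldown
from .summarize import aggregate_annotations, module_table, select_top_annotations
from .synthetic_data import (
    GroundTruth,
    SimulationConfig,
    generate_abundance,
    generate_associations,
    generate_asv_counts,
    generate_gene_sets,
    generate_interactome,
)

__all__ = ["PipelineConfig", "run_all", "run_synthetic_benchmark"]


@dataclass
class PipelineConfig:
    """Every pipeline tunable, with the study's stated settings as defaults."""

    # QC
    max_missing: float = 0.30
    prevalence_min: float = 0.10
    pseudocount: float = 1.0
    outlier_components: int = 2
    outlier_quantile: float = 0.99
    # pulldown
    min_confidence: float = 0.1
    degree_percentile: float = 0.99
    inside_fraction_min: float = 0.10
    max_nodes: int = 200
    exemption_q: float = 1e-4
    overlap_min: float = 0.75
    overlap_metric: str = "containment"
    neighborhood: str = "induced"
    whitelist: list[list[str]] = field(default_factory=list)
    # enrichment / classification
    bh_family: str = "class"
    background: str = "interactome"  # interactome | union-of-networks
    q_max: float = 0.05
    min_metabolites: int = 3
    # annotation summaries
    top_k: int = 20
    p_max: float = 0.01
    es_min: float = 1.5
    # randomness (synthetic mode only; the pulldown itself is deterministic)
    rng_seed: int = 0

    def pulldown_params(self) -> PulldownParams:
        return PulldownParams(
            min_confidence=self.min_confidence,
            degree_percentile=self.degree_percentile,
            inside_fraction_min=self.inside_fraction_min,
            max_nodes=self.max_nodes,
            exemption_q=self.exemption_q,
            overlap_min=self.overlap_min,
            overlap_metric=self.overlap_metric,
            neighborhood=self.neighborhood,
            whitelist=frozenset(frozenset(p) for p in self.whitelist),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _synthetic_inputs(config: PipelineConfig, sim: SimulationConfig | None):
    sim = sim or SimulationConfig(rng_seed=config.rng_seed)
    interactome, truth = generate_interactome(sim)
    associations = generate_associations(truth, sim)
    plasma, feces = generate_abundance(sim)
    asv = generate_asv_counts(sim)
    gene_sets = generate_gene_sets(truth, rng_seed=sim.rng_seed)
    queries = sorted({r.metabolite_id for r in associations.rows})
    return interactome, associations, queries, gene_sets, plasma, feces, asv, truth


def run_all(
    config: PipelineConfig,
    out_dir: str | Path,
    synthetic: bool = False,
    sim: SimulationConfig | None = None,
    interactome_path: str | Path | None = None,
    associations_path: str | Path | None = None,
    queries: list[str] | None = None,
    gene_sets_path: str | Path | None = None,
) -> dict:
    """Run the full pipeline and write all artifacts to ``out_dir``.

    With ``synthetic=True`` all inputs come from the generator (seeded by
    ``config.rng_seed``); otherwise ``interactome_path``,
    ``associations_path``, ``queries`` and ``gene_sets_path`` must point at
    real files. Returns the manifest dict (also written to
    ``out_dir/manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pullnet_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "synthetic": synthetic,
        "stages": {},
    }

    plasma = feces = asv = truth = None
    if synthetic:
        (interactome, associations, queries, gene_sets,
         plasma, feces, asv, truth) = _synthetic_inputs(config, sim)
    else:
        missing = [
            name for name, v in [
                ("--interactome", interactome_path),
                ("--associations", associations_path),
                ("--gene-sets", gene_sets_path),
            ] if v is None
        ]
        if missing:
            raise ValueError(
                f"missing required inputs {missing}; pass them or use --synthetic"
            )
        interactome = pio.read_interactome_tsv(interactome_path)
        associations = pio.read_association_table(associations_path)
        gene_sets = pio.read_gmt(gene_sets_path)
        if queries is None:
            queries = sorted({r.metabolite_id for r in associations.rows})

    # --- stage: omics QC (synthetic mode or when tables are provided) ------
    qc_report: list[str] = []
    if plasma is not None:
        for label, table in (("plasma", plasma), ("feces", feces)):
            n_before = table.values.shape[1]
            processed = metabolite_qc_pipeline(table, max_missing=config.max_missing)
            n_after = processed.values.shape[1]
            qc_report.append(
                f"{label}: {n_before} metabolites -> {n_after} after QC"
            )
            outliers = detect_outliers(
                processed.values,
                n_components=config.outlier_components,
                quantile=config.outlier_quantile,
            )
            qc_report.append(f"{label}: outlier samples flagged: {sorted(outliers)}")
            pio.write_feature_table(processed.values, out / f"qc_{label}.tsv")
            manifest["stages"][f"qc_{label}_metabolites"] = n_after
    if asv is not None:
        filtered_asv = filter_asvs(asv, prevalence_min=config.prevalence_min)
        clr = clr_transform(filtered_asv, pseudocount=config.pseudocount)
        qc_report.append(
            f"asv: {asv.counts.shape[1]} taxa -> {filtered_asv.counts.shape[1]} after filter"
        )
        pio.write_feature_table(clr, out / "qc_asv_clr.tsv")
        manifest["stages"]["qc_asv_taxa"] = filtered_asv.counts.shape[1]
    (out / "qc_report.txt").write_text("\n".join(qc_report) + "\n" if qc_report else "")

    # --- stage: seed mapping ------------------------------------------------
    seed_map = resolve_metabolites(queries, associations)
    n_mapped, n_proteins, n_pairs = association_stats(seed_map)
    pio.write_seed_map(seed_map, out / "seed_map.tsv")
    manifest["stages"].update(
        {
            "n_query_metabolites": len(queries),
            "n_mapped_metabolites": n_mapped,
            "n_unmapped_metabolites": len(seed_map.unmapped_metabolites),
            "n_seed_proteins": n_proteins,
            "n_metabolite_protein_pairs": n_pairs,
        }
    )

    # --- stage: virtual pulldown -------------------------------------------
    params = config.pulldown_params()
    modules, log = run_pulldown(interactome, seed_map, params)
    manifest["stages"].update(log)
    from .pulldown import filter_interactome

    filtered = filter_interactome(interactome, config.min_confidence)
    pio.write_xgmml(modules, filtered, out / "networks.xgmml")
    pio.write_module_edgelist(modules, filtered, out / "networks_edges.tsv")

    # --- stage: enrichment & classification ---------------------------------
    if config.background == "interactome":
        background = frozenset(filtered.graph.nodes)
    elif config.background == "union-of-networks":
        background = frozenset().union(*(m.nodes for m in modules)) if modules else frozenset()
    else:
        raise ValueError(f"unknown background choice {config.background!r}")

    seed_set = frozenset(s for s in seed_map.union_seed_list if s in background)
    full_sets = GeneSetCollection(
        sets={**gene_sets.sets, "seed_proteins": seed_set or frozenset(seed_map.union_seed_list)},
        class_labels={**gene_sets.class_labels, "seed_proteins": "seed"},
    )
    results = enrich_collection(modules, full_sets, background, family=config.bh_family)
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
        out / "enrichment.tsv", sep="\t", index=False
    )

    classification = classify_networks(
        modules, results,
        q_max=config.q_max, min_metabolites=config.min_metabolites,
    )
    manifest["stages"]["n_core_networks"] = len(classification.core_ids)
    manifest["stages"]["n_exploratory_networks"] = len(classification.exploratory_ids)

    ranked = rank_networks(modules, results, ids=classification.exploratory_ids)
    qs = seed_q_values(results)
    module_table(modules, qs, order=ranked).to_csv(
        out / "exploratory_networks.tsv", sep="\t", index=False
    )
    module_table(modules, qs, order=classification.core_ids).to_csv(
        out / "core_networks.tsv", sep="\t", index=False
    )

    # --- stage: annotation summaries over the top exploratory networks ------
    top_ids = ranked[: config.top_k]
    if top_ids:
        summaries = aggregate_annotations(results, top_ids)
        selected = select_top_annotations(
            summaries, top_k=config.top_k, p_max=config.p_max, es_min=config.es_min
        )
        pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
            out / "annotation_summaries.tsv", sep="\t", index=False
        )
        pd.DataFrame([dataclasses.asdict(s) for s in selected]).to_csv(
            out / "annotation_top.tsv", sep="\t", index=False
        )
        manifest["stages"]["n_top_annotations"] = len(selected)

    pio.write_json(manifest, out / "manifest.json")
    return manifest


# -- parameter-recovery benchmark -------------------------------------------

def _node_jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    return len(a & b) / len(a | b) if (a or b) else 0.0


def run_synthetic_benchmark(
    sim: SimulationConfig | None = None,
    config: PipelineConfig | None = None,
    n_runs: int = 10,
    base_seed: int = 0,
    jaccard_min: float = 0.6,
) -> dict:
    """Planted-module recovery over seeded replicates of the generator.

    For each replicate: generate interactome + associations, resolve seeds,
    run the pulldown, and score (a) per planted module the best node-Jaccard
    achieved by any final network and (b) the median seed-enrichment q of
    planted-derived networks (seeded from a planted module) versus decoy
    networks. Returns the pooled recovery fraction at ``jaccard_min`` and
    the per-group q medians.
    """
    config = config or PipelineConfig()
    base_sim = sim or SimulationConfig()
    best_jaccards: list[float] = []
    planted_q: list[float] = []
    decoy_q: list[float] = []
    for run in range(n_runs):
        sim_i = dataclasses.replace(base_sim, rng_seed=base_seed + run)
        interactome, truth = generate_interactome(sim_i)
        associations = generate_associations(truth, sim_i)
        queries = sorted({r.metabolite_id for r in associations.rows})
        seed_map = resolve_metabolites(queries, associations)
        modules, _ = run_pulldown(interactome, seed_map, config.pulldown_params())

        planted_nodes: set[str] = set()
        for members in truth.planted_module_memberships.values():
            best = max(
                (_node_jaccard(m.nodes, members) for m in modules), default=0.0
            )
            best_jaccards.append(best)
            planted_nodes |= members

        from .pulldown import filter_interactome

        filtered = filter_interactome(interactome, config.min_confidence)
        background = frozenset(filtered.graph.nodes)
        seed_set = frozenset(s for s in seed_map.union_seed_list if s in background)
        sets = GeneSetCollection(
            sets={"seed_proteins": seed_set}, class_labels={"seed_proteins": "seed"}
        )
        results = enrich_collection(modules, sets, background, family=config.bh_family)
        qs = seed_q_values(results)
        for m in modules:
            q = qs.get(m.network_id, 1.0)
            if m.seed_proteins & planted_nodes:
                planted_q.append(q)
            else:
                decoy_q.append(q)

    return {
        "n_runs": n_runs,
        "n_module_instances": len(best_jaccards),
        "best_jaccards": best_jaccards,
        "recovery_fraction": float(
            np.mean([j >= jaccard_min for j in best_jaccards])
        ) if best_jaccards else 0.0,
        "median_planted_q": float(np.median(planted_q)) if planted_q else 1.0,
        "median_decoy_q": float(np.median(decoy_q)) if decoy_q else 1.0,
    }
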
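"""Synthetic study generator: interactome, associations, omics matrices.

Emulates the data layout of a four-group rodent multi-omics study (wild-type
and transgenic animals under control or high-fat diet) together with a
confidence-weighted interactome, so that every downstream stage can be
exercised and validated against a known ground truth without external
downloads:

* an interactome built as stochastic-block-model modules planted in a
  preferential-attachment background, reproducing the two artifacts the
  pulldown pipeline must cope with — dense functional modules and
  promiscuous hub proteins — with per-edge confidences drawn from a Beta
  distribution whose lower tail falls below the 0.1 confidence filter;
* a metabolite-protein association table whose true discriminant
  metabolites link preferentially into their assigned planted module;
* lognormal sample x metabolite intensity blocks (plasma-like and
  feces-like) with left-censored missingness and group shifts on the
  discriminant metabolites;
* Dirichlet-multinomial ASV count tables;
* gene sets derived from the planted modules with configurable corruption.

All generators are bit-reproducible given ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .assoc_map import AssociationRow, AssociationTable
from .enrich import GeneSetCollection
from .omics_qc import AsvTable, MetaboliteTable
from .pulldown import Interactome

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_interactome",
    "generate_associations",
    "generate_abundance",
    "generate_asv_counts",
    "generate_gene_sets",
]

GROUPS = ("WT-CD", "WT-HFD", "Tg-CD", "Tg-HFD")


class ConfigurationError(ValueError):
    """Invalid simulation configuration; names the offending field."""


@dataclass
class SimulationConfig:
    """Conditions of the synthetic study.

    Defaults mirror the study design being emulated where it states them
    (four groups of 6/3/6/6 animals; ~30% overall missingness; 120 genera)
    and the standard recovery benchmark otherwise (500 proteins, 5 planted
    modules of 15-25 proteins with within-module edge probability 0.4 over
    a sparse background).
    """

    n_proteins: int = 500
    n_planted_modules: int = 5
    module_size_range: tuple[int, int] = (15, 25)
    p_in: float = 0.4
    p_out: float = 0.01
    hub_count: int = 5
    confidence_beta_params: tuple[float, float] = (1.5, 1.5)
    n_metabolites: int = 40
    n_discriminant: int = 20
    links_per_metabolite: tuple[int, int] = (3, 8)
    group_sizes: tuple[int, int, int, int] = (6, 3, 6, 6)
    effect_log2: float = 2.0
    missing_rate: float = 0.30
    high_missing_fraction: float = 0.15
    in_module_link_fraction: float = 0.9
    sequencing_depth: int = 10_000
    n_taxa: int = 120
    rng_seed: int = 0

    def validate(self) -> None:
        def bad(name: str, why: str) -> ConfigurationError:
            return ConfigurationError(f"invalid {name}: {why}")

        if self.n_proteins <= 0:
            raise bad("n_proteins", "must be a positive integer")
        if self.n_planted_modules < 0:
            raise bad("n_planted_modules", "must be non-negative")
        lo, hi = self.module_size_range
        if not (2 <= lo <= hi):
            raise bad("module_size_range", "need 2 <= min <= max")
        if hi * self.n_planted_modules + self.hub_count > self.n_proteins:
            raise bad("module_size_range", "planted modules and hubs exceed n_proteins")
        for name in ("p_in", "p_out", "missing_rate", "high_missing_fraction",
                     "in_module_link_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise bad(name, "must lie in [0, 1]")
        if self.hub_count < 0:
            raise bad("hub_count", "must be non-negative")
        a, b = self.confidence_beta_params
        if a <= 0 or b <= 0:
            raise bad("confidence_beta_params", "Beta shapes must be positive")
        if self.n_metabolites <= 0:
            raise bad("n_metabolites", "must be a positive integer")
        if self.n_discriminant > self.n_metabolites:
            raise bad("n_discriminant", "cannot exceed n_metabolites")
        llo, lhi = self.links_per_metabolite
        if not (1 <= llo <= lhi):
            raise bad("links_per_metabolite", "need 1 <= min <= max")
        if any(g <= 0 for g in self.group_sizes):
            raise bad("group_sizes", "all four group sizes must be positive")
        if self.effect_log2 < 0:
            raise bad("effect_log2", "must be non-negative")
        if self.n_taxa <= 0 or self.sequencing_depth <= 0:
            raise bad("n_taxa", "taxa count and sequencing depth must be positive")


@dataclass
class GroundTruth:
    """What was planted, for parameter-recovery evaluation."""

    planted_module_memberships: dict[str, frozenset[str]]
    protein_ids: tuple[str, ...]
    hub_proteins: frozenset[str] = frozenset()
    true_discriminant_metabolites: frozenset[str] = frozenset()
    metabolite_to_planted_module: dict[str, str] = field(default_factory=dict)


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # independent deterministic streams per generator stage
    return np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, stream]))


def _metabolite_ids(cfg: SimulationConfig) -> list[str]:
    return [f"met{i:03d}" for i in range(cfg.n_metabolites)]


def generate_interactome(cfg: SimulationConfig) -> tuple[Interactome, GroundTruth]:
    """Build the synthetic interactome and its ground truth.

    Dense modules (edge probability ``p_in``) are planted on disjoint node
    sets over a preferential-attachment background whose edge count matches
    a background density of ``p_out``; ``hub_count`` designated nodes are
    wired up to at least 10x the median degree. Every edge receives a
    confidence drawn from Beta(``confidence_beta_params``).
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    proteins = [f"P{i:04d}" for i in range(cfg.n_proteins)]

    g = nx.Graph()
    g.add_nodes_from(proteins)

    # preferential-attachment background scaled to the requested density
    if cfg.p_out > 0 and cfg.n_proteins > 2:
        m = max(1, int(round(cfg.p_out * (cfg.n_proteins - 1) / 2)))
        background = nx.barabasi_albert_graph(
            cfg.n_proteins, min(m, cfg.n_proteins - 1),
            seed=int(rng.integers(2**31)),
        )
        g.add_edges_from(
            (proteins[u], proteins[v]) for u, v in background.edges
        )

    # plant disjoint dense modules
    lo, hi = cfg.module_size_range
    order = rng.permutation(cfg.n_proteins)
    memberships: dict[str, frozenset[str]] = {}
    cursor = 0
    for j in range(cfg.n_planted_modules):
        size = int(rng.integers(lo, hi + 1))
        members = [proteins[i] for i in order[cursor:cursor + size]]
        cursor += size
        memberships[f"module_{j}"] = frozenset(members)
        for a in range(size):
            for b in range(a + 1, size):
                if cfg.p_in >= 1.0 or rng.random() < cfg.p_in:
                    g.add_edge(members[a], members[b])

    # promiscuous hubs: boost designated background nodes to >= 10x median degree
    hubs: list[str] = []
    if cfg.hub_count > 0:
        hubs = [proteins[i] for i in order[cursor:cursor + cfg.hub_count]]
        # boost, then top up once because hub edges nudge the median itself
        for _ in range(2):
            degrees = np.array([d for _, d in g.degree()], dtype=float)
            target = max(int(np.ceil(10 * np.median(degrees))), 10)
            for h in hubs:
                candidates = [p for p in proteins if p != h and not g.has_edge(h, p)]
                need = target - g.degree(h)
                if need > 0:
                    for p in rng.choice(candidates, size=min(need, len(candidates)),
                                        replace=False):
                        g.add_edge(h, p)

    a, b = cfg.confidence_beta_params
    edges = sorted(tuple(sorted(e)) for e in g.edges)
    confidences = rng.beta(a, b, size=len(edges))
    for (u, v), c in zip(edges, confidences):
        g.edges[u, v]["confidence"] = float(c)

    # pre-assign discriminant metabolites to modules round-robin
    met_ids = _metabolite_ids(cfg)
    discriminant = met_ids[: cfg.n_discriminant]
    module_names = sorted(memberships) or [""]
    met_to_module = {
        m: module_names[i % len(module_names)]
        for i, m in enumerate(discriminant)
        if module_names[0]
    }
    truth = GroundTruth(
        planted_module_memberships=memberships,
        protein_ids=tuple(proteins),
        hub_proteins=frozenset(hubs),
        true_discriminant_metabolites=frozenset(discriminant),
        metabolite_to_planted_module=met_to_module,
    )
    return Interactome(g), truth


def generate_associations(truth: GroundTruth, cfg: SimulationConfig) -> AssociationTable:
    """Metabolite-protein association table with aliases and evidence classes.

    True discriminant metabolites draw most links
    (``in_module_link_fraction``) from their assigned planted module, the
    rest from the background; decoy metabolites link to random proteins. A
    fifth of the decoys carry text-mining-only evidence, which downstream
    mapping must exclude.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    proteins = np.array(truth.protein_ids)
    met_ids = _metabolite_ids(cfg)
    llo, lhi = cfg.links_per_metabolite

    rows: list[AssociationRow] = []
    for i, met in enumerate(met_ids):
        k = int(rng.integers(llo, lhi + 1))
        is_discriminant = met in truth.true_discriminant_metabolites
        targets: list[str] = []
        if is_discriminant and truth.metabolite_to_planted_module.get(met):
            module = sorted(
                truth.planted_module_memberships[truth.metabolite_to_planted_module[met]]
            )
            n_in = min(int(round(cfg.in_module_link_fraction * k)), len(module))
            targets.extend(rng.choice(module, size=n_in, replace=False))
        remaining = [p for p in proteins if p not in set(targets)]
        n_out = k - len(targets)
        if n_out > 0:
            targets.extend(rng.choice(remaining, size=n_out, replace=False))

        text_mining_only = (not is_discriminant) and rng.random() < 0.2
        for p in targets:
            if text_mining_only:
                cls = "text-mining"
            else:
                cls = "physical" if rng.random() < 0.5 else "functional"
            rows.append(
                AssociationRow(
                    metabolite_id=met,
                    synonyms=(f"Metabolite {i}", f"MET-{i}"),
                    structural_key=f"SYNTHKEY{i:05d}-MOCK",
                    protein_id=str(p),
                    association_class=cls,
                    source="synthetic",
                )
            )
    return AssociationTable(rows)


def _sample_frame(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    groups = [g for g, n in zip(GROUPS, cfg.group_sizes) for _ in range(n)]
    ids = [f"S{i:02d}" for i in range(len(groups))]
    genotype = [g.split("-")[0] for g in groups]
    diet = [g.split("-")[1] for g in groups]
    volume = rng.uniform(0.8, 1.2, size=len(ids)).round(3)
    return pd.DataFrame(
        {"group": groups, "genotype": genotype, "diet": diet, "volume": volume},
        index=pd.Index(ids, name="sample_id"),
    )


def generate_abundance(cfg: SimulationConfig) -> tuple[MetaboliteTable, MetaboliteTable]:
    """Plasma-like and feces-like lognormal intensity blocks.

    Discriminant metabolites are shifted by ``effect_log2`` (in log2 units)
    between the relevant groups — alternating metabolites respond to diet
    (high-fat vs control) or genotype (transgenic vs wild-type), mirroring
    the two discriminant axes of the study design. Missingness is left
    censoring: per metabolite, the lowest cells are removed at a
    per-metabolite rate, with ``high_missing_fraction`` of metabolites
    exceeding the 30% QC threshold so the filter is exercised. Plasma raw
    intensities are multiplied by the sample volume (undone by the volume
    adjustment in QC).
    """
    cfg.validate()
    rng = _rng(cfg, 2)
    meta = _sample_frame(cfg, rng)
    n_samples = len(meta)
    met_ids = _metabolite_ids(cfg)
    effect_ln = cfg.effect_log2 * np.log(2.0)

    def one_block(block: str) -> MetaboliteTable:
        base = rng.normal(10.0, 1.0, size=cfg.n_metabolites)
        logx = rng.normal(0.0, 0.5, size=(n_samples, cfg.n_metabolites)) + base
        for j, met in enumerate(met_ids):
            if met not in _metabolite_ids(cfg)[: cfg.n_discriminant]:
                continue
            axis = "diet" if j % 2 == 0 else "genotype"
            if axis == "diet":
                shifted = meta["diet"].to_numpy() == "HFD"
            else:
                shifted = meta["genotype"].to_numpy() == "Tg"
            logx[shifted, j] += effect_ln
        values = np.exp(logx)

        # per-metabolite left-censoring rates: a configurable fraction of
        # metabolites exceed the 30% filter threshold, the rest are scaled
        # so the overall rate matches missing_rate
        if cfg.missing_rate > 0:
            n_high = int(round(cfg.high_missing_fraction * cfg.n_metabolites))
            high = rng.choice(cfg.n_metabolites, size=n_high, replace=False)
            rates = np.zeros(cfg.n_metabolites)
            rates[high] = rng.uniform(0.35, 0.60, size=n_high)
            low_rate = max(
                0.0,
                (cfg.missing_rate - rates[high].sum() / cfg.n_metabolites)
                / max(1 - n_high / cfg.n_metabolites, 1e-9),
            )
            low_mask = np.ones(cfg.n_metabolites, bool)
            low_mask[high] = False
            rates[low_mask] = np.clip(
                rng.uniform(0.5 * low_rate, 1.5 * low_rate, size=low_mask.sum()), 0, 0.30
            )
            for j in range(cfg.n_metabolites):
                n_miss = int(round(rates[j] * n_samples))
                if n_miss > 0:
                    lowest = np.argsort(values[:, j])[:n_miss]
                    values[lowest, j] = np.nan

        if block == "plasma":
            values = values * meta["volume"].to_numpy()[:, None]
        df = pd.DataFrame(values, index=meta.index, columns=met_ids)
        return MetaboliteTable(values=df, block_label=block, sample_metadata=meta)

    return one_block("plasma"), one_block("feces")


def generate_asv_counts(cfg: SimulationConfig, depth: int | None = None) -> AsvTable:
    """Dirichlet-multinomial ASV counts with a heavy-tailed base composition.

    Every sample's counts sum exactly to the sequencing depth; lognormal
    base proportions give a realistic mix of dominant and rare genera so the
    prevalence filter has work to do.
    """
    cfg.validate()
    rng = _rng(cfg, 3)
    depth = depth if depth is not None else cfg.sequencing_depth
    meta = _sample_frame(cfg, rng)
    taxa = [f"g__taxon{i:03d}" for i in range(cfg.n_taxa)]
    base = rng.lognormal(0.0, 2.0, size=cfg.n_taxa)
    base /= base.sum()
    concentration = 50.0
    counts = np.zeros((len(meta), cfg.n_taxa), dtype=np.int64)
    for i in range(len(meta)):
        p = rng.dirichlet(base * concentration + 1e-6)
        counts[i] = rng.multinomial(depth, p)
    return AsvTable(
        counts=pd.DataFrame(counts, index=meta.index, columns=taxa),
        taxonomy={t: f"Bacteria;{t}" for t in taxa},
    )


def generate_gene_sets(
    truth: GroundTruth,
    noise_fraction: float = 0.1,
    n_decoy_sets: int = 10,
    class_label: str = "ad",
    rng_seed: int = 0,
) -> GeneSetCollection:
    """Gene sets from planted modules, corrupted by membership swaps.

    Each planted member is swapped for a random non-member with probability
    ``noise_fraction`` (so expected truth overlap is (1 - noise) x module
    size). ``n_decoy_sets`` random sets of comparable size are added under
    the same class label to provide a null for enrichment ranking.
    """
    if not (0.0 <= noise_fraction <= 1.0):
        raise ConfigurationError("invalid noise_fraction: must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 4]))
    proteins = np.array(truth.protein_ids)
    sets: dict[str, frozenset[str]] = {}
    labels: dict[str, str] = {}
    sizes = []
    for name in sorted(truth.planted_module_memberships):
        members = sorted(truth.planted_module_memberships[name])
        sizes.append(len(members))
        outside = [p for p in proteins if p not in set(members)]
        kept = [m for m in members if rng.random() >= noise_fraction]
        n_swap = len(members) - len(kept)
        swapped = list(rng.choice(outside, size=n_swap, replace=False)) if n_swap else []
        sets[f"geneset_{name}"] = frozenset(kept + swapped)
        labels[f"geneset_{name}"] = class_label
    mean_size = int(np.mean(sizes)) if sizes else 20
    for d in range(n_decoy_sets):
        sets[f"geneset_decoy_{d}"] = frozenset(
            rng.choice(proteins, size=mean_size, replace=False)
        )
        labels[f"geneset_decoy_{d}"] = class_label
    return GeneSetCollection(sets=sets, class_labels=labels)
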
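"""Over-representation analysis and network-set classification.

Each network module is tested against gene-set collections with a one-sided
Fisher exact test (upper hypergeometric tail), corrected per gene-set class
with the Benjamini-Hochberg step-up procedure. Networks significantly
enriched in disease-associated proteins form the "core" set; networks
enriched in the seed-protein list and linked to several discriminant
metabolites form the "exploratory" set used for downstream biology.

The enrichment score is the fold over-representation (k/n) / (K/M): overlap
fraction of the network versus the gene set's background frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "fisher_ora",
    "bh_adjust",
    "enrich_collection",
    "classify_networks",
    "rank_networks",
]

_Q_FLOOR = 1e-300  # displayed "0.000" q-values are rounding; never emit exact zero


@dataclass
class GeneSetCollection:
    """Named protein sets, each carrying a class label.

    Class labels partition sets into test families, e.g. ``ad`` for
    disease-associated collections, ``seed`` for the seed-protein list, and
    annotation categories (``disease`` / ``pathway`` / ``go``) for the
    cross-network summaries.
    """

    sets: dict[str, frozenset[str]]
    class_labels: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.sets) != set(self.class_labels):
            raise ValueError("every gene set needs exactly one class label")
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene sets not allowed: {empty[:5]}")

    def by_class(self, label: str) -> dict[str, frozenset[str]]:
        return {n: s for n, s in self.sets.items() if self.class_labels[n] == label}

    @property
    def classes(self) -> set[str]:
        return set(self.class_labels.values())


@dataclass
class EnrichmentResult:
    """One network x gene-set over-representation test."""

    network_id: str
    gene_set_name: str
    k: int  # overlap
    n: int  # network size (within background)
    K: int  # gene-set size within background
    M: int  # background size
    p_value: float
    enrichment_score: float
    q_value: float | None = None
    gene_set_class: str = ""


def fisher_ora(
    network_nodes: frozenset[str] | set[str],
    gene_set: frozenset[str] | set[str],
    background: frozenset[str] | set[str],
    network_id: str = "",
    gene_set_name: str = "",
) -> EnrichmentResult:
    """One-sided (greater) Fisher exact test of network/gene-set overlap.

    The gene set is intersected with the background universe before
    testing; the p-value is the upper hypergeometric tail P(X >= k) for the
    2x2 table (k, n-k; K-k, M-K-n+k). With zero overlap the upper tail
    includes the observation, so p = 1.
    """
    background = frozenset(background)
    if not background:
        raise ValueError("background universe must be non-empty")
    nodes = frozenset(network_nodes) & background
    if not nodes:
        raise ValueError("network is empty (or disjoint from background)")
    gs = frozenset(gene_set) & background
    M, n, K = len(background), len(nodes), len(gs)
    k = len(nodes & gs)
    # P(X >= k) for X ~ Hypergeom(M, K, n); sf(k-1) is exact
    p = float(hypergeom.sf(k - 1, M, K, n))
    es = (k / n) / (K / M) if K > 0 else 0.0
    return EnrichmentResult(
        network_id=network_id, gene_set_name=gene_set_name,
        k=k, n=n, K=K, M=M, p_value=min(p, 1.0), enrichment_score=es,
    )


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values (monotone, clipped to [floor, 1])."""
    if len(p_values) == 0:
        return []
    if any(p < 0 or p > 1 for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(p_values, method="fdr_bh")[1]
    return [max(float(v), _Q_FLOOR) for v in q]


def enrich_collection(
    modules,
    gene_sets: GeneSetCollection,
    background: frozenset[str],
    family: str = "class",
) -> list[EnrichmentResult]:
    """Test every module against every gene set and BH-adjust.

    ``family`` controls the multiple-testing family: ``"class"`` (default)
    adjusts each gene-set class across all networks separately; ``"global"``
    adjusts all tests together.
    """
    results: list[EnrichmentResult] = []
    for m in modules:
        for name, gs in gene_sets.sets.items():
            r = fisher_ora(
                m.nodes, gs, background,
                network_id=m.network_id, gene_set_name=name,
            )
            results.append(replace(r, gene_set_class=gene_sets.class_labels[name]))
    if family == "global":
        groups: dict[str, list[int]] = {"all": list(range(len(results)))}
    elif family == "class":
        groups = {}
        for i, r in enumerate(results):
            groups.setdefault(r.gene_set_class, []).append(i)
    else:
        raise ValueError(f"unknown BH family scope {family!r}")
    for idx in groups.values():
        qs = bh_adjust([results[i].p_value for i in idx])
        for i, q in zip(idx, qs):
            results[i] = replace(results[i], q_value=q)
    return results


@dataclass
class NetworkClassification:
    core_ids: list[str] = field(default_factory=list)  # disease-enriched
    exploratory_ids: list[str] = field(default_factory=list)  # seed-enriched


def classify_networks(
    modules,
    results: list[EnrichmentResult],
    ad_class: str = "ad",
    seed_class: str = "seed",
    q_max: float = 0.05,
    min_metabolites: int = 3,
) -> NetworkClassification:
    """Split the collection into core and exploratory network sets.

    Core networks are significantly enriched (BH q <= ``q_max``) in at
    least one disease-associated gene set. Exploratory networks are
    enriched in the seed-protein set AND linked to at least
    ``min_metabolites`` discriminant metabolites. The two sets may overlap.
    """
    classes = {r.gene_set_class for r in results}
    for required in (ad_class, seed_class):
        if required not in classes:
            raise ValueError(f"no enrichment results for gene-set class {required!r}")
    mods = {m.network_id: m for m in modules}
    core, exploratory = [], []
    for nid in sorted(mods):
        ad_hit = any(
            r.network_id == nid and r.gene_set_class == ad_class and r.q_value <= q_max
            for r in results
        )
        seed_hit = any(
            r.network_id == nid and r.gene_set_class == seed_class and r.q_value <= q_max
            for r in results
        )
        if ad_hit:
            core.append(nid)
        if seed_hit and len(mods[nid].linked_metabolites) >= min_metabolites:
            exploratory.append(nid)
    return NetworkClassification(core_ids=core, exploratory_ids=exploratory)


def seed_q_values(
    results: list[EnrichmentResult], seed_class: str = "seed"
) -> dict[str, float]:
    """Per-network minimum seed-enrichment q (one seed set -> the q itself)."""
    out: dict[str, float] = {}
    for r in results:
        if r.gene_set_class == seed_class and r.q_value is not None:
            out[r.network_id] = min(out.get(r.network_id, 1.0), r.q_value)
    return out


def rank_networks(
    modules,
    results: list[EnrichmentResult],
    ids: list[str] | None = None,
    seed_class: str = "seed",
) -> list[str]:
    """Order networks by linked-metabolite count (desc), then seed q (asc).

    Stable and deterministic: final tie-break is the network id. The paper
    convention puts metabolite participation first, so the top network is
    the one where the most discriminant metabolites converge.
    """
    mods = {m.network_id: m for m in modules}
    qs = seed_q_values(results, seed_class)
    pool = ids if ids is not None else sorted(mods)
    return sorted(
        pool,
        key=lambda nid: (-len(mods[nid].linked_metabolites), qs.get(nid, 1.0), nid),
    )
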
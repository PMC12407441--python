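"""Cross-network annotation aggregation and tabular reporting.

For a fixed subset of networks (typically the top exploratory modules), each
annotation's significance is summarized as the geometric mean of its
BH-corrected values across the networks and its effect as the arithmetic
mean of the enrichment scores; the strongest annotations are then selected
by rank and dual thresholds. Also provides the per-metabolite
representation count across a network collection (how many networks a
metabolite's seed proteins participate in) and the standard module summary
table (id, size, linked metabolites, seed q).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .enrich import EnrichmentResult

__all__ = [
    "AnnotationSummary",
    "aggregate_annotations",
    "select_top_annotations",
    "metabolite_representation",
    "module_table",
    "load_reference_exploratory_networks",
]

_P_FLOOR = 1e-300


@dataclass
class AnnotationSummary:
    """Aggregate of one annotation across a network subset."""

    annotation_name: str
    annotation_class: str
    geometric_mean_p: float
    mean_enrichment: float
    n_networks_significant: int


def aggregate_annotations(
    results: list[EnrichmentResult],
    network_ids: list[str],
    use_corrected: bool = True,
    missing_as_one: bool = True,
    significance_q: float = 0.05,
) -> list[AnnotationSummary]:
    """Summarize annotations across a fixed network subset.

    Per annotation: geometric mean of the (BH-corrected by default)
    p-values over the ``network_ids`` subset and arithmetic mean of the
    enrichment scores. Annotations untested in a given network count as
    p = 1 and enrichment 0 (set ``missing_as_one=False`` to average over
    tested networks only). Values are floored at 1e-300 before the log.
    """
    if not results:
        raise ValueError("no enrichment results to aggregate")
    subset = set(network_ids)
    per_annotation: dict[str, dict[str, tuple[float, float]]] = {}
    classes: dict[str, str] = {}
    for r in results:
        if r.network_id not in subset:
            continue
        val = r.q_value if use_corrected else r.p_value
        if val is None:
            raise ValueError("corrected values requested but q_value missing")
        per_annotation.setdefault(r.gene_set_name, {})[r.network_id] = (
            val, r.enrichment_score,
        )
        classes[r.gene_set_name] = r.gene_set_class

    k = len(network_ids)
    out = []
    for name in sorted(per_annotation):
        vals = per_annotation[name]
        if missing_as_one:
            ps = [vals.get(nid, (1.0, 0.0))[0] for nid in network_ids]
            es = [vals.get(nid, (1.0, 0.0))[1] for nid in network_ids]
        else:
            ps = [v[0] for v in vals.values()]
            es = [v[1] for v in vals.values()]
        logs = [math.log(max(p, _P_FLOOR)) for p in ps]
        out.append(
            AnnotationSummary(
                annotation_name=name,
                annotation_class=classes[name],
                geometric_mean_p=math.exp(sum(logs) / len(logs)),
                mean_enrichment=sum(es) / len(es),
                n_networks_significant=sum(
                    1 for p in (vals.get(nid, (1.0, 0.0))[0] for nid in network_ids)
                    if p <= significance_q
                ) if k else 0,
            )
        )
    return out


def select_top_annotations(
    summaries: list[AnnotationSummary],
    top_k: int = 20,
    p_max: float = 0.01,
    es_min: float = 1.5,
) -> list[AnnotationSummary]:
    """Keep the ``top_k`` lowest-average-p annotations, then apply thresholds.

    The rank cut precedes the filters: an annotation outside the top-k is
    dropped even if it passes both thresholds. Ties in the average p are
    broken by annotation name for stability.
    """
    ranked = sorted(summaries, key=lambda s: (s.geometric_mean_p, s.annotation_name))
    return [
        s for s in ranked[:top_k]
        if s.geometric_mean_p <= p_max and s.mean_enrichment >= es_min
    ]


def metabolite_representation(records: list[dict] | pd.DataFrame) -> dict[str, int]:
    """Count, per metabolite name, the networks whose linked list contains it.

    Membership is exact full-name string matching, so structurally distinct
    entries such as "palmitate (16:0)" and "(14 or 15)-methylpalmitate
    (a17:0 or i17:0)" are counted separately. Order of records is
    irrelevant. Records carry a ``metabolites`` field, either a list of
    names or a semicolon-joined string.
    """
    if isinstance(records, pd.DataFrame):
        records = records.to_dict("records")
    counts: Counter[str] = Counter()
    for rec in records:
        mets = rec["metabolites"]
        if isinstance(mets, str):
            mets = [m.strip() for m in mets.split(";") if m.strip()]
        counts.update(set(mets))
    return dict(counts)


def module_table(modules, seed_q: dict[str, float], order: list[str] | None = None) -> pd.DataFrame:
    """Standard per-network summary table.

    One row per network: id, size (protein count), linked-metabolite count,
    semicolon-joined metabolite names (sorted), and seed-enrichment q.
    Re-running on the same collection yields an identical table.
    """
    mods = {m.network_id: m for m in modules}
    ids = order if order is not None else sorted(mods)
    rows = [
        {
            "network_id": nid,
            "size": mods[nid].size,
            "n_metabolites": len(mods[nid].linked_metabolites),
            "metabolites": ";".join(sorted(mods[nid].linked_metabolites)),
            "seed_q": seed_q.get(nid, float("nan")),
        }
        for nid in ids
    ]
    return pd.DataFrame(
        rows, columns=["network_id", "size", "n_metabolites", "metabolites", "seed_q"]
    )


def load_reference_exploratory_networks() -> pd.DataFrame:
    """Load the packaged published summary of the 20 exploratory networks.

    Columns: network_id, size, n_metabolites, metabolites (semicolon-joined
    full metabolite names, verbatim), seed_q. Used as a reference input for
    metabolite-representation counting.
    """
    ref = resources.files("pullnet.data") / "exploratory_networks.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"network_id": str})
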
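"""Resolution of discriminant metabolites to seed proteins.

Consumes a pre-extracted metabolite-protein association table (a frozen
snapshot of curated sources such as UniProt, PubChem bioassays, HMDB, ChEMBL
and STITCH) and maps query metabolites onto protein identifiers. Matching
proceeds through identifier tiers — exact primary id, then structural key
(e.g. InChIKey), then case-insensitive name/synonym — and rows supported
only by text-mining co-mentions are excluded as insufficient evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ASSOCIATION_CLASSES",
    "AssociationRow",
    "AssociationTable",
    "SeedMap",
    "resolve_metabolites",
    "association_stats",
]

ASSOCIATION_CLASSES = ("physical", "functional", "text-mining")


@dataclass(frozen=True)
class AssociationRow:
    """One metabolite-protein link with its identifier aliases and evidence."""

    metabolite_id: str
    synonyms: tuple[str, ...]
    structural_key: str
    protein_id: str
    association_class: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if self.association_class not in ASSOCIATION_CLASSES:
            raise ValueError(
                f"association_class {self.association_class!r} not in {ASSOCIATION_CLASSES}"
            )


@dataclass
class AssociationTable:
    """Many-to-many metabolite <-> protein association rows."""

    rows: list[AssociationRow]

    def __post_init__(self) -> None:
        # a primary id carrying two different non-empty structural keys is
        # suspicious but tolerated: warn and keep both rows
        keys: dict[str, str] = {}
        for r in self.rows:
            if not r.structural_key:
                continue
            prev = keys.setdefault(r.metabolite_id, r.structural_key)
            if prev != r.structural_key:
                warnings.warn(
                    f"metabolite {r.metabolite_id!r} maps to conflicting structural "
                    f"keys {prev!r} and {r.structural_key!r}; both rows retained",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metabolite_id": [r.metabolite_id for r in self.rows],
                "synonyms": ["|".join(r.synonyms) for r in self.rows],
                "structural_key": [r.structural_key for r in self.rows],
                "protein_id": [r.protein_id for r in self.rows],
                "association_class": [r.association_class for r in self.rows],
                "source": [r.source for r in self.rows],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AssociationTable":
        rows = [
            AssociationRow(
                metabolite_id=str(r.metabolite_id),
                synonyms=tuple(s for s in str(r.synonyms).split("|") if s and s != "nan"),
                structural_key="" if pd.isna(r.structural_key) else str(r.structural_key),
                protein_id=str(r.protein_id),
                association_class=str(r.association_class),
                source="" if pd.isna(getattr(r, "source", "")) else str(getattr(r, "source", "")),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(rows)


@dataclass
class SeedMap:
    """Resolved metabolite -> seed-protein assignment."""

    metabolite_to_proteins: dict[str, frozenset[str]]
    unmapped_metabolites: list[str] = field(default_factory=list)

    @property
    def union_seed_list(self) -> list[str]:
        """Sorted unique union of all per-metabolite protein sets."""
        out: set[str] = set()
        for prots in self.metabolite_to_proteins.values():
            out |= prots
        return sorted(out)

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {"metabolite_id": m, "protein_id": p}
            for m in sorted(self.metabolite_to_proteins)
            for p in sorted(self.metabolite_to_proteins[m])
        ]
        return pd.DataFrame(recs, columns=["metabolite_id", "protein_id"])


def _usable(row: AssociationRow) -> bool:
    # text-mining-only co-mentions are insufficiently supported evidence
    return row.association_class != "text-mining"


def resolve_metabolites(query_ids: list[str], table: AssociationTable) -> SeedMap:
    """Map each query metabolite to its seed proteins.

    Matching tiers, first hit wins: (1) exact primary-id match; (2) exact
    structural-key match; (3) case-insensitive match against names and
    synonyms. Rows with text-mining evidence only never contribute proteins;
    queries matching no usable row are reported as unmapped. Resolution is
    deterministic and independent of table row order.
    """
    if not query_ids:
        raise ValueError("query list must be non-empty")

    usable = [r for r in table.rows if _usable(r)]
    by_primary: dict[str, set[str]] = {}
    by_key: dict[str, set[str]] = {}
    by_name: dict[str, set[str]] = {}
    for r in usable:
        by_primary.setdefault(r.metabolite_id, set()).add(r.protein_id)
        if r.structural_key:
            by_key.setdefault(r.structural_key, set()).add(r.protein_id)
        for name in (r.metabolite_id, *r.synonyms):
            by_name.setdefault(name.casefold(), set()).add(r.protein_id)

    mapped: dict[str, frozenset[str]] = {}
    unmapped: list[str] = []
    for q in query_ids:
        hit = by_primary.get(q) or by_key.get(q) or by_name.get(q.casefold())
        if hit:
            mapped[q] = frozenset(hit)
        else:
            unmapped.append(q)
    return SeedMap(metabolite_to_proteins=mapped, unmapped_metabolites=unmapped)


def association_stats(seed_map: SeedMap) -> tuple[int, int, int]:
    """(mapped metabolites, unique proteins, metabolite-protein pairs)."""
    n_mapped = len(seed_map.metabolite_to_proteins)
    proteins: set[str] = set()
    n_pairs = 0
    for prots in seed_map.metabolite_to_proteins.values():
        proteins |= prots
        n_pairs += len(prots)
    return n_mapped, len(proteins), n_pairs
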
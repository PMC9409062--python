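"""Functional annotation transfer from protein-family and structure hits.

Each predicted protein is compared (upstream, by HMM profile-profile search)
against a database of orthologous phage-protein families ("phrogs") and,
as a fallback, against known protein structures (pdb70).  This module consumes
the resulting hit tables and applies the transfer rules:

* family affiliation is accepted when probability >= 80% AND E-value <= 1e-4
  (the rejection region is written as prob < 80%, E > 1e-4, so acceptance is
  boundary-inclusive);
* proteins without an acceptable family hit are "singletons" of unknown
  function;
* proteins still of unknown function may receive a product from a structure
  hit when probability > 80%, E-value < 1e-3 (strict, as the acceptance
  region is written) and the alignment covers enough of the query;
* a curated re-annotation overlay renames families whose database annotation
  is "unknown function" but for which a function could be inferred, updating
  every member of the family consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import ContractError, ValidationError
from .util import percent

UNKNOWN = "unknown function"
SINGLETON = "singleton"

#: Functional categories used by the family database.
KNOWN_CATEGORIES = frozenset(
    {
        "connector",
        "lysis",
        "tail",
        "head and packaging",
        "moron, auxiliary metabolic gene and host takeover",
        "transcription regulation",
        "other",
        "DNA, RNA, and nucleotide metabolism",
        "integration and excision",
        UNKNOWN,
    }
)


@dataclass(frozen=True)
class ProfileHit:
    """One query-protein vs family/structure comparison record."""

    query_id: str
    subject_id: str
    database: str  # "phrog" or "pdb"
    probability: float  # percent, 0..100
    evalue: float
    coverage: float  # fraction of the query aligned, 0..1
    annotation: str = UNKNOWN
    category: str = UNKNOWN

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 100.0:
            raise ValidationError(
                f"probability {self.probability} outside [0, 100] "
                f"for query {self.query_id!r}"
            )
        if self.evalue < 0:
            raise ValidationError(
                f"negative E-value {self.evalue} for query {self.query_id!r}"
            )
        if not 0.0 <= self.coverage <= 1.0:
            raise ValidationError(
                f"coverage {self.coverage} outside [0, 1] "
                f"for query {self.query_id!r}"
            )


@dataclass
class FunctionalAssignment:
    """The finalized function of one predicted protein."""

    query_id: str
    family_id: str  # "phrog_N", a structure id, or "singleton"
    product: str
    category: str
    source: str  # phrog | pdb-fallback | reannotation-overlay | none
    evidence: Optional[ProfileHit] = None


class ReannotationTable:
    """Curated family -> (product, category) overlay.

    The packaged default carries 24 families originally annotated "unknown
    function" in the family database for which a function could be proposed
    from structure comparisons and genomic context.
    """

    def __init__(self, entries: Mapping[str, tuple[str, str]]):
        for family, (product, _cat) in entries.items():
            if not product:
                raise ValidationError(f"empty product for family {family!r}")
        self.entries = dict(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, family_id: str) -> bool:
        return family_id in self.entries

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReannotationTable":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"family_id", "product", "category"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(
                f"re-annotation table missing columns {sorted(missing)}"
            )
        if df["family_id"].duplicated().any():
            dups = df.loc[df["family_id"].duplicated(), "family_id"].tolist()
            raise ValidationError(f"duplicate family ids: {dups}")
        return cls(
            {
                row.family_id: (row.product, row.category)
                for row in df.itertuples()
            }
        )

    @classmethod
    def packaged_default(cls) -> "ReannotationTable":
        from .synthetic_data import fixture_path

        return cls.from_tsv(fixture_path("reannotation_table4.tsv"))


def select_best_hit(
    hits: Sequence[ProfileHit], database: Optional[str] = None
) -> Optional[ProfileHit]:
    """Best hit for one query: highest probability, then lowest E-value.

    Remaining ties break on lexicographic subject id for determinism.
    Returns ``None`` on an empty list.
    """
    if database is not None:
        hits = [h for h in hits if h.database == database]
    if not hits:
        return None
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ContractError(f"hits span multiple queries: {sorted(queries)}")
    return min(hits, key=lambda h: (-h.probability, h.evalue, h.subject_id))


def assign_phrog(
    best: Optional[ProfileHit],
    query_id: Optional[str] = None,
    prob_min: float = 80.0,
    evalue_max: float = 1e-4,
) -> FunctionalAssignment:
    """Affiliate a protein to a family, or declare it a singleton.

    The affiliation is accepted iff probability >= ``prob_min`` and
    E-value <= ``evalue_max`` (inclusive boundaries).  Too-distant or absent
    hits yield a singleton of unknown function.
    """
    if best is None:
        if query_id is None:
            raise ContractError("query_id required when there is no hit")
        return FunctionalAssignment(
            query_id=query_id,
            family_id=SINGLETON,
            product=UNKNOWN,
            category=UNKNOWN,
            source="none",
            evidence=None,
        )
    if best.database != "phrog":
        raise ContractError(
            f"assign_phrog expects a family-database hit, got {best.database!r}"
        )
    if best.probability >= prob_min and best.evalue <= evalue_max:
        return FunctionalAssignment(
            query_id=best.query_id,
            family_id=best.subject_id,
            product=best.annotation,
            category=best.category,
            source="phrog",
            evidence=best,
        )
    return FunctionalAssignment(
        query_id=best.query_id,
        family_id=SINGLETON,
        product=UNKNOWN,
        category=UNKNOWN,
        source="none",
        evidence=best,
    )


def pdb_fallback(
    assignment: FunctionalAssignment,
    pdb_best: Optional[ProfileHit],
    prob_min: float = 80.0,
    evalue_max: float = 1e-3,
    coverage_min: float = 0.5,
) -> FunctionalAssignment:
    """Rename an unknown-function protein from a reliable structure hit.

    Applies only to proteins whose product is still "unknown function".
    The structure hit must pass probability > ``prob_min`` (strict),
    E-value < ``evalue_max`` (strict) and coverage >= ``coverage_min``;
    the coverage check rejects matches against a small portion (a domain
    or sub-domain) of the query.  The family id is left unchanged so that
    singletons remain identifiable.
    """
    if assignment.product != UNKNOWN:
        return assignment
    if pdb_best is None or pdb_best.database != "pdb":
        return assignment
    if (
        pdb_best.probability > prob_min
        and pdb_best.evalue < evalue_max
        and pdb_best.coverage >= coverage_min
    ):
        return replace(
            assignment,
            product=pdb_best.annotation,
            source="pdb-fallback",
            evidence=pdb_best,
        )
    return assignment


def apply_reannotation(
    assignments: Sequence[FunctionalAssignment], table: ReannotationTable
) -> list[FunctionalAssignment]:
    """Apply the curated overlay to every member of a re-annotated family.

    Idempotent: applying the overlay twice equals applying it once.
    """
    out = []
    for a in assignments:
        if a.family_id in table:
            product, category = table.entries[a.family_id]
            out.append(
                replace(
                    a,
                    product=product,
                    category=category,
                    source="reannotation-overlay",
                )
            )
        else:
            out.append(a)
    return out


@dataclass
class AnnotationSummary:
    n_orfs: int
    pct_unknown_function: float
    pct_singleton: float


def summarize_annotation(
    assignments: Sequence[FunctionalAssignment],
) -> AnnotationSummary:
    """Fraction of proteins of unknown function and of singletons (1 decimal)."""
    n = len(assignments)
    n_unknown = sum(1 for a in assignments if a.product == UNKNOWN)
    n_singleton = sum(1 for a in assignments if a.family_id == SINGLETON)
    return AnnotationSummary(
        n_orfs=n,
        pct_unknown_function=percent(n_unknown, n),
        pct_singleton=percent(n_singleton, n),
    )
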
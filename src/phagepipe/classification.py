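"""Lifestyle calling from marker families and taxon clustering.

Lifestyle: a phage is called *temperate* when its proteome carries an
integrase together with at least one other lysogeny-associated function
(an excisionase/RDF, a CI-like repressor, a CII-like regulator or a CIII
anti-termination protein); otherwise *virulent*.  A solitary
temperate-associated marker (e.g. an RDF without an integrase, a known
situation in some strictly virulent genera) is reported in the rationale but
does not flip the call.

Taxonomy: genomes are clustered from a pairwise intergenomic-similarity
matrix by single-linkage at the species (95%) and genus (70%) thresholds —
connected components of the graph whose edges join genomes at or above the
threshold.  Species clusters nest inside genus clusters by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .annotation_transfer import FunctionalAssignment
from .errors import ConfigurationError
from .io_formats import SimilarityMatrix

#: Marker roles and their default family ids.
DEFAULT_MARKERS = {
    "integrase": frozenset({"phrog_216"}),
    "rdf": frozenset({"phrog_66"}),
    "ci_repressor": frozenset({"phrog_6201"}),
    "cii": frozenset({"phrog_725"}),
    "ciii": frozenset({"phrog_550"}),
    "antirepressor": frozenset({"phrog_130"}),
}

#: Product keywords used as a fallback when family ids come from another
#: database.  Matching is case-insensitive substring.
DEFAULT_KEYWORDS = {
    "integrase": ("integrase",),
    "rdf": ("excisionase", "recombination directionality"),
    "ci_repressor": ("ci-like_repressor", "ci-like repressor", "ci repressor"),
    "cii": ("cii-like", "cii regulator"),
    "ciii": ("ciii",),
    "antirepressor": ("antirepressor", "anti-repressor"),
}

#: Roles that count as lysogeny co-markers alongside the integrase.
CO_MARKER_ROLES = ("rdf", "ci_repressor", "cii", "ciii")


@dataclass
class MarkerSet:
    """Family ids recognized as lifestyle markers, by role."""

    families: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_MARKERS)
    )
    keywords: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_KEYWORDS)
    )
    use_keywords: bool = False

    def roles_of(self, assignment: FunctionalAssignment) -> list[str]:
        roles = [
            role
            for role, fams in self.families.items()
            if assignment.family_id in fams
        ]
        if not roles and self.use_keywords:
            product = assignment.product.lower()
            roles = [
                role
                for role, words in self.keywords.items()
                if any(w in product for w in words)
            ]
        return roles


@dataclass
class LifestyleCall:
    genome_id: str
    call: str  # "temperate" or "virulent"
    markers_found: list[tuple[str, str]]  # (family_id, role)
    rationale: str


def classify_lifestyle(
    genome_id: str,
    assignments: Sequence[FunctionalAssignment],
    markers: MarkerSet | None = None,
    min_co_markers: int = 1,
) -> LifestyleCall:
    """Call the lifestyle of one genome from its functional assignments.

    Temperate requires an integrase plus at least ``min_co_markers`` other
    lysogeny-associated functions.  Monotone: adding marker hits can only
    move the call from virulent to temperate, never the reverse.
    """
    markers = markers or MarkerSet()
    found: list[tuple[str, str]] = []
    for a in assignments:
        for role in markers.roles_of(a):
            found.append((a.family_id, role))
    roles_present = {role for _fam, role in found}
    has_integrase = "integrase" in roles_present
    n_co = sum(1 for role in CO_MARKER_ROLES if role in roles_present)
    if has_integrase and n_co >= min_co_markers:
        call = "temperate"
        rationale = (
            "integrase present with lysogeny co-marker(s): "
            + ", ".join(sorted(roles_present))
        )
    else:
        call = "virulent"
        orphans = sorted(
            {role for _f, role in found if role != "integrase"}
        )
        if orphans:
            rationale = (
                "no integrase-plus-co-marker combination; solitary "
                "temperate-associated marker(s) noted: " + ", ".join(orphans)
            )
        elif has_integrase:
            rationale = "integrase present but no lysogeny co-marker"
        else:
            rationale = "no lifestyle markers detected"
    return LifestyleCall(
        genome_id=genome_id, call=call,
        markers_found=sorted(set(found)), rationale=rationale,
    )


@dataclass
class TaxonCluster:
    level: str  # "species" or "genus"
    members: tuple[str, ...]
    threshold_used: float


def _components(matrix: SimilarityMatrix, threshold: float) -> list[tuple[str, ...]]:
    g = nx.Graph()
    g.add_nodes_from(matrix.genome_ids)
    n = len(matrix.genome_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.values[i, j] >= threshold:
                g.add_edge(matrix.genome_ids[i], matrix.genome_ids[j])
    comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    return sorted(comps)


def cluster_genomes(
    matrix: SimilarityMatrix,
    species_threshold: float = 95.0,
    genus_threshold: float = 70.0,
) -> list[TaxonCluster]:
    """Single-linkage clustering at the species and genus thresholds."""
    for name, t in (("species", species_threshold), ("genus", genus_threshold)):
        if not 0.0 < t <= 100.0:
            raise ConfigurationError(
                f"{name} threshold {t} outside (0, 100]"
            )
    clusters = [
        TaxonCluster("species", members, species_threshold)
        for members in _components(matrix, species_threshold)
    ]
    clusters += [
        TaxonCluster("genus", members, genus_threshold)
        for members in _components(matrix, genus_threshold)
    ]
    # species partition refines the genus partition (guaranteed when
    # species_threshold >= genus_threshold; asserted regardless)
    genus_of = {
        m: c.members for c in clusters if c.level == "genus" for m in c.members
    }
    for c in clusters:
        if c.level == "species":
            parents = {genus_of[m] for m in c.members}
            assert len(parents) == 1, (
                f"species cluster {c.members} spans genus clusters"
            )
    return clusters


def novelty_call(cluster: TaxonCluster, reference_ids: Iterable[str]) -> str:
    """``new-species`` iff the species cluster contains no reference genome."""
    refs = set(reference_ids)
    return "known-species" if any(m in refs for m in cluster.members) else "new-species"
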
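"""Automated curation of overlapping and spurious ORFs.

Phage genes legitimately overlap by a few base pairs, and a gene can even be
entirely contained in another on the opposite strand ("overprinting").  But a
*highly* overlapping pair where one member has only a weak family affiliation
usually betrays a false-positive prediction.  This module automates the
decision rules, with a complete audit trail:

* ORF-ORF conflict (overlap >= 50% of the shorter member by default):
  when at least one member is strongly affiliated, every weak member without
  a rescuing structure hit is discarded; when all members are strong, all are
  kept; when all are weak, all are kept and flagged for manual review.
* ORF-tRNA conflict (complete containment either way): the tRNA — reliably
  predicted upstream — is always kept; the ORF is discarded when its
  affiliation is weak or it is a singleton.

Strand is ignored for ORF-ORF conflict detection (overlapping pairs occur on
the same or opposite strands); tRNA containment follows the same-strand case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import networkx as nx

from .annotation_transfer import SINGLETON, FunctionalAssignment
from .consensus import ConsensusOrf
from .errors import ContractError
from .io_formats import TrnaRecord


@dataclass
class OverlapConflict:
    """A maximal clique of mutually overlapping features."""

    members: tuple[str, ...]
    overlap_bp: int
    overlap_fraction_of_shorter: float
    kind: str  # "orf-orf" or "orf-trna"


@dataclass
class CurationDecision:
    feature_id: str
    action: str  # keep | discard
    rule: str  # weak-vs-strong | all-strong-keep | trna-overlap | no-conflict | all-weak-review
    justification: str


def _interval_overlap(
    a: tuple[int, int], b: tuple[int, int], genome_length: int, circular: bool
) -> int:
    """Overlap in bp between two (start, end) intervals, wrap-aware."""
    shifts = (0,) if not circular else (-genome_length, 0, genome_length)
    best = 0
    for shift in shifts:
        lo = max(a[0], b[0] + shift)
        hi = min(a[1], b[1] + shift)
        best = max(best, hi - lo + 1)
    return max(best, 0)


def _orf_id(orf: ConsensusOrf) -> str:
    return f"{orf.strand}:{orf.stop_anchor}"


def orf_feature_id(orf: ConsensusOrf) -> str:
    """Stable identifier of a consensus ORF within its genome."""
    return _orf_id(orf)


def find_overlaps(
    orfs: Sequence[ConsensusOrf],
    trnas: Sequence[TrnaRecord] = (),
    min_fraction: float = 0.5,
    genome_length: Optional[int] = None,
    circular: bool = False,
) -> list[OverlapConflict]:
    """Detect highly overlapping ORF groups and ORF/tRNA containments.

    ORF-ORF conflicts are reported as maximal cliques of ORFs whose pairwise
    overlap is at least ``min_fraction`` of the shorter member.  ORF-tRNA
    conflicts are reported when one feature completely contains the other on
    the same strand.
    """
    L = genome_length or (
        max((o.selected_end for o in orfs), default=1)
        if orfs else 1
    )
    ids = [_orf_id(o) for o in orfs]
    spans = {_orf_id(o): (o.selected_start, o.selected_end) for o in orfs}

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    pair_overlap: dict[frozenset[str], int] = {}
    for i in range(len(orfs)):
        for j in range(i + 1, len(orfs)):
            a, b = orfs[i], orfs[j]
            ov = _interval_overlap(
                spans[_orf_id(a)], spans[_orf_id(b)], L, circular
            )
            if ov <= 0:
                continue
            shorter = min(a.length, b.length)
            if ov / shorter >= min_fraction:
                graph.add_edge(_orf_id(a), _orf_id(b))
                pair_overlap[frozenset((_orf_id(a), _orf_id(b)))] = ov

    conflicts: list[OverlapConflict] = []
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue
        clique = tuple(sorted(clique))
        ovs = [
            pair_overlap[frozenset((clique[i], clique[j]))]
            for i in range(len(clique))
            for j in range(i + 1, len(clique))
        ]
        shortest = min(
            spans[m][1] - spans[m][0] + 1 for m in clique
        )
        conflicts.append(
            OverlapConflict(
                members=clique,
                overlap_bp=min(ovs),
                overlap_fraction_of_shorter=min(ovs) / shortest,
                kind="orf-orf",
            )
        )

    for orf in orfs:
        os_, oe = spans[_orf_id(orf)]
        for k, t in enumerate(trnas, start=1):
            if t.strand != orf.strand:
                continue
            contained = (os_ <= t.start and t.end <= oe) or (
                t.start <= os_ and oe <= t.end
            )
            if contained:
                ov = _interval_overlap((os_, oe), (t.start, t.end), L, circular)
                shorter = min(orf.length, t.length)
                conflicts.append(
                    OverlapConflict(
                        members=(_orf_id(orf), f"tRNA{k}-{t.isotype}"),
                        overlap_bp=ov,
                        overlap_fraction_of_shorter=ov / shorter,
                        kind="orf-trna",
                    )
                )
    conflicts.sort(key=lambda c: (c.kind, c.members))
    return conflicts


def classify_affiliation_strength(
    assignment: Optional[FunctionalAssignment],
    weak_prob_max: float = 70.0,
    weak_evalue_min: float = 1e-4,
) -> str:
    """``weak`` if there is no evidence hit, the probability is below
    ``weak_prob_max`` or the E-value above ``weak_evalue_min``; else ``strong``.
    """
    if assignment is None or assignment.evidence is None:
        return "weak"
    hit = assignment.evidence
    if hit.probability < weak_prob_max or hit.evalue > weak_evalue_min:
        return "weak"
    return "strong"


def resolve_conflict(
    conflict: OverlapConflict,
    strengths: Mapping[str, str],
    pdb_rescue: Optional[Mapping[str, bool]] = None,
    singleton: Optional[Mapping[str, bool]] = None,
) -> list[CurationDecision]:
    """Apply the keep/discard rules to one conflict.

    ``strengths`` maps ORF member ids to "strong"/"weak"; ``pdb_rescue``
    marks weak members that nevertheless have a passing structure hit and
    must not be discarded.  For orf-trna conflicts, ``singleton`` marks the
    ORF as affiliation-less; the tRNA member receives no decision (it is
    always kept upstream).
    """
    pdb_rescue = pdb_rescue or {}
    singleton = singleton or {}
    decisions: list[CurationDecision] = []
    if conflict.kind == "orf-trna":
        orf_members = [m for m in conflict.members if not m.startswith("tRNA")]
        for m in orf_members:
            weakish = strengths.get(m, "weak") == "weak" or singleton.get(m, False)
            if weakish and not pdb_rescue.get(m, False):
                decisions.append(
                    CurationDecision(
                        m, "discard", "trna-overlap",
                        "ORF with weak/singleton affiliation completely "
                        "overlapping a reliably predicted tRNA",
                    )
                )
            else:
                decisions.append(
                    CurationDecision(
                        m, "keep", "trna-overlap",
                        "ORF overlaps a tRNA but carries a strong affiliation",
                    )
                )
        return decisions

    for m in conflict.members:
        if m not in strengths:
            raise ContractError(f"no affiliation strength for member {m!r}")
    member_strengths = {m: strengths[m] for m in conflict.members}
    n_strong = sum(1 for s in member_strengths.values() if s == "strong")
    if n_strong == len(conflict.members):
        for m in conflict.members:
            decisions.append(
                CurationDecision(
                    m, "keep", "all-strong-keep",
                    "all overlapping members strongly affiliated; "
                    "cannot decide which is spurious",
                )
            )
    elif n_strong == 0:
        for m in conflict.members:
            decisions.append(
                CurationDecision(
                    m, "keep", "all-weak-review",
                    "all overlapping members weakly affiliated; "
                    "kept and flagged for manual review",
                )
            )
    else:
        for m in conflict.members:
            if member_strengths[m] == "strong":
                decisions.append(
                    CurationDecision(
                        m, "keep", "weak-vs-strong",
                        "strong affiliation retained over weak overlappers",
                    )
                )
            elif pdb_rescue.get(m, False):
                decisions.append(
                    CurationDecision(
                        m, "keep", "weak-vs-strong",
                        "weak family affiliation but strong structure "
                        "homology; kept",
                    )
                )
            else:
                decisions.append(
                    CurationDecision(
                        m, "discard", "weak-vs-strong",
                        "weak affiliation, no structure rescue, overlapping "
                        "a strongly affiliated ORF",
                    )
                )
    return decisions


def curate_genome(
    orfs: Sequence[ConsensusOrf],
    trnas: Sequence[TrnaRecord],
    assignments: Mapping[str, FunctionalAssignment],
    min_fraction: float = 0.5,
    weak_prob_max: float = 70.0,
    weak_evalue_min: float = 1e-4,
    pdb_rescue: Optional[Mapping[str, bool]] = None,
    genome_length: Optional[int] = None,
    circular: bool = False,
) -> tuple[list[ConsensusOrf], list[CurationDecision]]:
    """Run conflict detection and resolution over one genome.

    ``assignments`` maps :func:`orf_feature_id` ids to functional
    assignments; every ORF must have one.  Returns the kept ORFs and an
    exhaustive audit table (exactly one decision per input ORF; discarded
    ORFs are removed from the kept set but preserved in the audit).  The
    result is independent of the input ORF order.
    """
    orfs = sorted(orfs, key=lambda o: (o.strand, o.stop_anchor))
    ids = [_orf_id(o) for o in orfs]
    for oid in ids:
        if oid not in assignments:
            raise ContractError(f"no functional assignment for ORF {oid!r}")
    strengths = {
        oid: classify_affiliation_strength(
            assignments[oid], weak_prob_max, weak_evalue_min
        )
        for oid in ids
    }
    singleton = {oid: assignments[oid].family_id == SINGLETON for oid in ids}
    conflicts = find_overlaps(
        orfs, trnas, min_fraction, genome_length, circular
    )
    # precedence when an ORF appears in several conflicts: any discard wins
    rule_priority = {
        "trna-overlap": 0, "weak-vs-strong": 1,
        "all-strong-keep": 2, "all-weak-review": 3,
    }
    per_orf: dict[str, CurationDecision] = {}
    for conflict in conflicts:
        for d in resolve_conflict(conflict, strengths, pdb_rescue, singleton):
            cur = per_orf.get(d.feature_id)
            if cur is None:
                per_orf[d.feature_id] = d
                continue
            if d.action == "discard" and cur.action == "keep":
                per_orf[d.feature_id] = d
            elif (
                d.action == cur.action
                and rule_priority[d.rule] < rule_priority[cur.rule]
            ):
                per_orf[d.feature_id] = d
    decisions = []
    kept = []
    for orf, oid in zip(orfs, ids):
        d = per_orf.get(oid) or CurationDecision(
            oid, "keep", "no-conflict", "no overlap conflict"
        )
        decisions.append(d)
        if d.action == "keep":
            kept.append(orf)
    return kept, decisions
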
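"""Anti-CRISPR (Acr) candidate screening.

Candidates come from two machine-learning predictors plus a similarity search
against validated Acr proteins.  Meaningful scores are over 0.5 for predictor
A (PaCRISPR-style) and over -5 for predictor B (AcRanker-style), both strict.
Validated Acr are mostly short proteins, so overlong candidates (> 200 aa)
and those whose homolog query cover is below 40% are excluded outright.

The retention rule combines the two predictors disjunctively: a candidate is
retained when either score is meaningful.  A candidate failing both scores
can still be rescued by genus consistency — when the same protein family is
retained with passing scores in enough other genomes of the same genus.
Finally, a genomic-context check flags candidates placed between the portal
and head scaffolding protein genes, the known neighborhood of the validated
AcrIE3 locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .errors import FeatureLookupError
from .io_formats import GeneRecord


@dataclass(frozen=True)
class AcrCandidate:
    """Per-protein anti-CRISPR evidence."""

    genome_id: str
    protein_id: str
    family_id: str
    length_aa: int
    score_a: Optional[float]  # predictor A; meaningful > 0.5
    score_b: Optional[float]  # predictor B; meaningful > -5
    homolog_id: str = ""
    query_cover: float = 0.0  # percent, 0..100
    crispr_type: str = ""
    genus: str = ""


@dataclass
class AcrCall:
    candidate: AcrCandidate
    retained: bool
    reasons: list[str] = field(default_factory=list)
    context_flag: bool = False

    @property
    def excluded(self) -> bool:
        return "excluded-length" in self.reasons or "excluded-cover" in self.reasons


def filter_candidates(
    candidates: Sequence[AcrCandidate],
    a_min: float = 0.5,
    b_min: float = -5.0,
    max_len: int = 200,
    min_cover: float = 40.0,
) -> list[AcrCall]:
    """Score/length/coverage filter.

    A candidate longer than ``max_len`` aa or with query cover below
    ``min_cover`` percent is excluded regardless of scores.  Otherwise it is
    retained iff score_a > ``a_min`` OR score_b > ``b_min`` (strict
    inequalities; a missing score fails that predictor).
    """
    calls = []
    for c in candidates:
        reasons: list[str] = []
        if c.length_aa > max_len:
            reasons.append("excluded-length")
        if c.query_cover < min_cover:
            reasons.append("excluded-cover")
        if reasons:
            calls.append(AcrCall(candidate=c, retained=False, reasons=reasons))
            continue
        if c.score_a is not None and c.score_a > a_min:
            reasons.append("score-pass-a")
        if c.score_b is not None and c.score_b > b_min:
            reasons.append("score-pass-b")
        calls.append(
            AcrCall(candidate=c, retained=bool(reasons), reasons=reasons)
        )
    return calls


def rescue_by_genus_consistency(
    calls: Sequence[AcrCall], min_supporting_genomes: int = 2
) -> list[AcrCall]:
    """Rescue score-failing candidates whose family is genus-consistent.

    A non-retained, non-excluded candidate becomes retained (reason
    ``rescued-by-genus``) when its family is retained with passing scores in
    at least ``min_supporting_genomes`` *other* genomes of the same genus.
    Monotone: adding supporting genomes never un-rescues a candidate.
    Candidates excluded on length or coverage are never rescued.
    """
    supporting: dict[tuple[str, str], set[str]] = {}
    for call in calls:
        c = call.candidate
        if call.retained and any(r.startswith("score-pass") for r in call.reasons):
            supporting.setdefault((c.genus, c.family_id), set()).add(c.genome_id)
    out = []
    for call in calls:
        c = call.candidate
        if call.retained or call.excluded:
            out.append(call)
            continue
        others = supporting.get((c.genus, c.family_id), set()) - {c.genome_id}
        if len(others) >= min_supporting_genomes:
            out.append(
                AcrCall(
                    candidate=c, retained=True,
                    reasons=call.reasons + ["rescued-by-genus"],
                    context_flag=call.context_flag,
                )
            )
        else:
            out.append(call)
    return out


def context_check(
    candidate: AcrCandidate,
    genes: Sequence[GeneRecord],
    portal_keywords: Sequence[str] = ("portal",),
    scaffold_keywords: Sequence[str] = ("scaffold", "scaffolding"),
    window: int = 3,
) -> bool:
    """True when the candidate gene lies strictly between a portal-protein
    gene and a head-scaffolding gene.

    ``genes`` must be in genomic order with products assigned.  The portal
    and scaffold genes must each be within ``window`` intervening genes of
    the candidate; either orientation (portal first or scaffold first)
    counts.  A genome without a portal annotation returns False.
    """
    ordered = sorted(genes, key=lambda g: (g.start, g.end))
    idx = next(
        (
            i
            for i, g in enumerate(ordered)
            if candidate.protein_id in (g.locus_tag, g.feature_id)
        ),
        None,
    )
    if idx is None:
        raise FeatureLookupError(
            f"candidate gene {candidate.protein_id!r} absent from annotation"
        )

    def matches(g: GeneRecord, keywords: Sequence[str]) -> bool:
        product = g.product.lower()
        return any(k in product for k in keywords)

    portals = [i for i, g in enumerate(ordered) if matches(g, portal_keywords)]
    scaffolds = [i for i, g in enumerate(ordered) if matches(g, scaffold_keywords)]
    for p in portals:
        for s in scaffolds:
            lo, hi = min(p, s), max(p, s)
            if lo < idx < hi and idx - lo <= window and hi - idx <= window:
                return True
    return False


def annotate_context(
    calls: Sequence[AcrCall], genes: Sequence[GeneRecord], **kwargs
) -> list[AcrCall]:
    """Set ``context_flag`` on each call from the genome annotation."""
    out = []
    for call in calls:
        try:
            flag = context_check(call.candidate, genes, **kwargs)
        except FeatureLookupError:
            flag = False
        out.append(replace(call, context_flag=flag))
    return out
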
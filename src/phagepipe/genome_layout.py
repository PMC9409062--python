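"""Normalize assembled contigs and assign locus tags.

Assemblers leave an exact duplicated stretch (one k-mer length, 77 bp for the
assemblies this models) at both extremities of a circularly permuted contig;
the right-most copy is removed and the contig treated as circular downstream.
For comparability between genomes, numbering starts at the terminase small
subunit gene as GP_001, flipping and/or rotating the sequence so that this
gene sits on the forward strand at position 1.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .annotation_transfer import FunctionalAssignment
from .consensus import ConsensusOrf
from .curation import CurationDecision, orf_feature_id
from .errors import FeatureLookupError, UnsupportedOperationError
from .io_formats import GeneRecord, GenomeAnnotation, GenomeSequence, TrnaRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def trim_terminal_repeat(
    genome: GenomeSequence, min_repeat: int = 20, max_repeat: int = 1000
) -> tuple[GenomeSequence, int]:
    """Remove the right-most copy of an exact terminal repeat.

    Finds the longest exact prefix==suffix repeat with length in
    ``[min_repeat, max_repeat]`` (capped at just under half the contig) and
    trims it from the right end, marking the genome circular-permuted.
    Returns the (possibly unchanged) genome and the trimmed length (0 when
    no repeat was found).  Detection is exact-match only: the assembler
    artifact is an exact duplication.
    """
    seq = genome.sequence
    upper = min(max_repeat, (len(seq) - 1) // 2)
    for r in range(upper, min_repeat - 1, -1):
        if seq[:r] == seq[-r:]:
            return (
                GenomeSequence(
                    id=genome.id,
                    sequence=seq[:-r],
                    topology="circular-permuted",
                    packaging=genome.packaging,
                ),
                r,
            )
    return genome, 0


def _flip_interval(start: int, end: int, strand: str, L: int) -> tuple[int, int, str]:
    """Image of a (possibly wrap-around) interval under reverse complement."""
    length = end - start + 1
    ns = L - end + 1
    while ns < 1:
        ns += L
    return ns, ns + length - 1, ("-" if strand == "+" else "+")


def _rotate_interval(start: int, end: int, shift: int, L: int) -> tuple[int, int]:
    length = end - start + 1
    ns = (start - 1 - shift) % L + 1
    return ns, ns + length - 1


def _rebuild_orf(orf: ConsensusOrf, ns: int, ne: int, strand: str, L: int) -> ConsensusOrf:
    anchor = (ne - 1) % L + 1 if strand == "+" else ns
    return ConsensusOrf(
        genome_id=orf.genome_id,
        strand=strand,
        stop_anchor=anchor,
        supporting_callers=orf.supporting_callers,
        selected_start=ns,
        selected_end=ne,
        variants=dict(orf.variants),
    )


def orient_genome(
    genome: GenomeSequence,
    orfs: Sequence[ConsensusOrf],
    terminase_orf_id: str,
    trnas: Sequence[TrnaRecord] = (),
) -> tuple[GenomeSequence, list[ConsensusOrf], list[TrnaRecord]]:
    """Rotate/flip a circular-permuted genome so the terminase small subunit
    gene starts at position 1 on the forward strand.

    ``terminase_orf_id`` is the :func:`~phagepipe.curation.orf_feature_id`
    of the anchor gene.  All feature coordinates are remapped by the same
    transformation; genome length and base composition are preserved.
    Applying the operation a second time is the identity.
    """
    if genome.topology != "circular-permuted":
        raise UnsupportedOperationError(
            f"cannot rotate {genome.topology} genome {genome.id!r}"
        )
    ids = [orf_feature_id(o) for o in orfs]
    if terminase_orf_id not in ids:
        raise FeatureLookupError(f"terminase ORF {terminase_orf_id!r} not found")
    term_idx = ids.index(terminase_orf_id)
    L = genome.length
    seq = genome.sequence
    spans = [(o.selected_start, o.selected_end, o.strand) for o in orfs]
    trna_spans = [(t.start, t.end, t.strand) for t in trnas]

    if spans[term_idx][2] == "-":
        seq = _revcomp(seq)
        spans = [_flip_interval(s, e, st, L) for s, e, st in spans]
        trna_spans = [_flip_interval(s, e, st, L) for s, e, st in trna_spans]

    shift = spans[term_idx][0] - 1
    seq = seq[shift:] + seq[:shift]
    spans = [
        (*_rotate_interval(s, e, shift, L), st) for s, e, st in spans
    ]
    trna_spans = [
        (*_rotate_interval(s, e, shift, L), st) for s, e, st in trna_spans
    ]

    new_genome = GenomeSequence(
        id=genome.id, sequence=seq,
        topology="circular-permuted", packaging=genome.packaging,
    )
    new_orfs = [
        _rebuild_orf(o, s, e, st, L) for o, (s, e, st) in zip(orfs, spans)
    ]
    new_trnas = [
        TrnaRecord(t.genome_id, s, e, st, t.isotype)
        for t, (s, e, st) in zip(trnas, trna_spans)
    ]
    return new_genome, new_orfs, new_trnas


def assign_locus_tags(
    prefix: str,
    orfs: Sequence[ConsensusOrf],
    trnas: Sequence[TrnaRecord] = (),
) -> tuple[dict[str, str], dict[int, str]]:
    """Assign locus tags in genomic order.

    CDS tags are ``<prefix>_GP_%03d`` starting at 001 in order of start
    coordinate (curated-out ORFs should not be passed: numbering is
    contiguous over the given set).  tRNA tags are ``<prefix>_tRNA%d``.
    Returns (orf feature id -> tag, tRNA input index -> tag).
    """
    orf_tags: dict[str, str] = {}
    for n, orf in enumerate(
        sorted(orfs, key=lambda o: (o.selected_start, o.selected_end)), start=1
    ):
        tag = f"{prefix}_GP_{n:03d}"
        oid = orf_feature_id(orf)
        assert oid not in orf_tags, f"duplicate feature id {oid}"
        orf_tags[oid] = tag
    trna_tags: dict[int, str] = {}
    order = sorted(range(len(trnas)), key=lambda i: trnas[i].start)
    for n, i in enumerate(order, start=1):
        trna_tags[i] = f"{prefix}_tRNA{n}"
    return orf_tags, trna_tags


def build_annotation(
    genome: GenomeSequence,
    kept_orfs: Sequence[ConsensusOrf],
    trnas: Sequence[TrnaRecord],
    assignments: Mapping[str, FunctionalAssignment],
    decisions: Sequence[CurationDecision] = (),
    discarded_orfs: Sequence[ConsensusOrf] = (),
    prefix: Optional[str] = None,
) -> GenomeAnnotation:
    """Assemble the final per-genome annotation with locus tags.

    Kept ORFs are tagged contiguously; discarded ORFs are included untagged
    with their curation rule so the audit export is complete.
    """
    prefix = prefix or genome.id
    orf_tags, _trna_tags = assign_locus_tags(prefix, kept_orfs, trnas)
    rule_by_id = {d.feature_id: d for d in decisions}
    genes: list[GeneRecord] = []
    for orf in kept_orfs:
        oid = orf_feature_id(orf)
        a = assignments.get(oid)
        d = rule_by_id.get(oid)
        genes.append(
            GeneRecord(
                feature_id=oid,
                genome_id=genome.id,
                start=orf.selected_start,
                end=orf.selected_end,
                strand=orf.strand,
                product=a.product if a else "unknown function",
                family_id=a.family_id if a else "singleton",
                category=a.category if a else "unknown function",
                locus_tag=orf_tags[oid],
                curation_action="keep",
                curation_rule=d.rule if d else "no-conflict",
                supporting_callers=tuple(sorted(orf.supporting_callers)),
            )
        )
    for orf in discarded_orfs:
        oid = orf_feature_id(orf)
        a = assignments.get(oid)
        d = rule_by_id.get(oid)
        genes.append(
            GeneRecord(
                feature_id=oid,
                genome_id=genome.id,
                start=orf.selected_start,
                end=orf.selected_end,
                strand=orf.strand,
                product=a.product if a else "unknown function",
                family_id=a.family_id if a else "singleton",
                category=a.category if a else "unknown function",
                locus_tag=None,
                curation_action="discard",
                curation_rule=d.rule if d else "no-conflict",
                supporting_callers=tuple(sorted(orf.supporting_callers)),
            )
        )
    return GenomeAnnotation(
        genome_id=genome.id,
        genome_length=genome.length,
        genes=genes,
        trnas=list(trnas),
    )
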
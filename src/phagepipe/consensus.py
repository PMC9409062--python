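"""Merge per-caller ORF predictions into a consensus set.

Different gene callers disagree mostly on start codons and on marginal genes.
Two predictions are considered the *same* ORF when they end at the same stop
codon on the same strand, regardless of the predicted start.  The identity key
is therefore the "stop anchor": the forward-strand coordinate of the ORF's
3'-terminal base.  When callers disagree on the start, the longest predicted
extent is kept.

This module also computes the cross-caller agreement statistics (Venn subset
counts) used to judge whether a caller is an outlier, and applies the
union-keep policy over a configured set of trusted callers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ConfigurationError, ValidationError
from .util import percent


def _wrap(coord: int, genome_length: Optional[int]) -> int:
    """Map a 1-based coordinate (possibly > L on a wrapped gene) into 1..L."""
    if genome_length is None:
        return coord
    return (coord - 1) % genome_length + 1


@dataclass(frozen=True)
class OrfPrediction:
    """One caller's predicted coding region.

    Coordinates are 1-based inclusive.  On a circular-permuted genome a gene
    spanning the contig extremity is represented with ``end = start + len - 1``
    possibly exceeding the genome length; the stop anchor is reduced modulo
    the genome length when one is supplied.
    """

    genome_id: str
    caller: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"strand must be '+' or '-', got {self.strand!r}"
            )
        if self.end < self.start:
            raise ValidationError(
                f"end < start for {self.genome_id}:{self.start}-{self.end}"
            )
        if self.length % 3 != 0:
            raise ValidationError(
                f"ORF length {self.length} is not a multiple of 3 "
                f"({self.genome_id}:{self.start}-{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def stop_anchor(self, genome_length: Optional[int] = None) -> int:
        """Forward-strand coordinate of the 3'-terminal base."""
        raw = self.end if self.strand == "+" else self.start
        return _wrap(raw, genome_length)


@dataclass
class ConsensusOrf:
    """A merged ORF identified by (strand, stop anchor)."""

    genome_id: str
    strand: str
    stop_anchor: int
    supporting_callers: frozenset[str]
    selected_start: int
    selected_end: int
    variants: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.selected_end - self.selected_start + 1

    @property
    def key(self) -> tuple[str, int]:
        return (self.strand, self.stop_anchor)


@dataclass
class AgreementStats:
    """Venn-style agreement structure over a consensus set.

    ``per_subset_counts`` maps each non-empty caller subset to the number of
    consensus ORFs supported by *exactly* that subset; subsets with zero
    count are included so that the map always has 2^k - 1 entries.
    """

    callers: list[str]
    n_union: int
    per_subset_counts: dict[frozenset[str], int]
    per_caller_totals: dict[str, int]
    per_caller_unique_counts: dict[str, int]

    def subset_count(self, subset: Iterable[str]) -> int:
        return self.per_subset_counts.get(frozenset(subset), 0)

    def all_callers_count(self) -> int:
        """ORFs predicted by every caller."""
        return self.subset_count(self.callers)

    def shared_percent(self) -> float:
        """Percentage of the union predicted by every caller (1 decimal)."""
        return percent(self.all_callers_count(), self.n_union)

    def unique_percent(self, caller: str) -> float:
        """Percentage of a caller's predictions unique to it (1 decimal)."""
        return percent(
            self.per_caller_unique_counts[caller],
            self.per_caller_totals[caller],
        )


def merge_predictions(
    predictions: Sequence[OrfPrediction],
    callers: Sequence[str],
    genome_length: Optional[int] = None,
) -> list[ConsensusOrf]:
    """Group predictions by (strand, stop anchor) and keep the longest extent.

    Parameters
    ----------
    predictions
        All predictions for a single genome, from any subset of ``callers``.
    callers
        The configured caller order.  Used to break the (never observed in
        practice) tie of two equally long variants sharing a stop anchor:
        the variant from the earliest caller in this order wins.
    genome_length
        When given, stop anchors are reduced modulo the genome length so
        that wrap-around representations of the same gene merge.

    Returns
    -------
    One :class:`ConsensusOrf` per distinct (strand, stop anchor), ordered by
    (strand, stop_anchor).
    """
    order = {c: i for i, c in enumerate(callers)}
    genomes = {p.genome_id for p in predictions}
    if len(genomes) > 1:
        raise ConfigurationError(
            f"predictions span multiple genomes: {sorted(genomes)}"
        )
    groups: dict[tuple[str, int], list[OrfPrediction]] = {}
    for p in predictions:
        if p.caller not in order:
            raise ConfigurationError(
                f"prediction from unconfigured caller {p.caller!r}"
            )
        groups.setdefault((p.strand, p.stop_anchor(genome_length)), []).append(p)

    merged: list[ConsensusOrf] = []
    for (strand, anchor), members in sorted(groups.items()):
        # longest extent wins; ties broken by configured caller order
        best = min(members, key=lambda p: (-p.length, order[p.caller]))
        variants: dict[str, tuple[int, int]] = {}
        for p in sorted(members, key=lambda p: (-p.length, order[p.caller])):
            variants.setdefault(p.caller, (p.start, p.end))
        merged.append(
            ConsensusOrf(
                genome_id=members[0].genome_id,
                strand=strand,
                stop_anchor=anchor,
                supporting_callers=frozenset(variants),
                selected_start=best.start,
                selected_end=best.end,
                variants=variants,
            )
        )
    return merged


def agreement_stats(
    consensus: Sequence[ConsensusOrf], callers: Sequence[str]
) -> AgreementStats:
    """Count consensus ORFs by exact supporting-caller subset."""
    callers = list(callers)
    counts: dict[frozenset[str], int] = {
        frozenset(sub): 0
        for r in range(1, len(callers) + 1)
        for sub in itertools.combinations(callers, r)
    }
    for orf in consensus:
        key = frozenset(orf.supporting_callers)
        if key not in counts:
            raise ConfigurationError(
                f"consensus ORF supported by unconfigured callers {sorted(key)}"
            )
        counts[key] += 1
    totals = {
        c: sum(n for sub, n in counts.items() if c in sub) for c in callers
    }
    uniques = {c: counts[frozenset([c])] for c in callers}
    return AgreementStats(
        callers=callers,
        n_union=len(consensus),
        per_subset_counts=counts,
        per_caller_totals=totals,
        per_caller_unique_counts=uniques,
    )


def flag_outlier_callers(
    stats: AgreementStats, unique_fraction_threshold: float = 25.0
) -> list[tuple[str, float, bool]]:
    """Flag callers whose unique-prediction share exceeds the threshold.

    A caller whose predictions are mostly unique to it disagrees with the
    ensemble and is a candidate for exclusion.  Flagging is advisory only:
    actually excluding a caller is an explicit configuration choice.

    Returns ``(caller, unique_fraction_percent, flagged)`` per caller, in
    the configured order.  A caller with zero predictions reports 0 and is
    never flagged.
    """
    out = []
    for c in stats.callers:
        total = stats.per_caller_totals[c]
        frac = stats.unique_percent(c) if total else 0.0
        exact = (
            100.0 * stats.per_caller_unique_counts[c] / total if total else 0.0
        )
        out.append((c, frac, exact > unique_fraction_threshold))
    return out


def consensus_keep_policy(
    consensus: Sequence[ConsensusOrf], included_callers: Sequence[str]
) -> list[ConsensusOrf]:
    """Union-keep: retain every ORF supported by at least one trusted caller.

    This is the conservative policy of keeping all ORFs predicted by any of
    the included callers (so that small genes — Acr, immunity proteins — are
    not lost), rather than requiring multi-caller support.  Supporting-caller
    sets and variants are restricted to the included callers and the longest
    remaining variant is re-selected.
    """
    included = list(included_callers)
    if not included:
        raise ConfigurationError("included_callers must not be empty")
    order = {c: i for i, c in enumerate(included)}
    kept: list[ConsensusOrf] = []
    for orf in consensus:
        support = orf.supporting_callers & set(included)
        if not support:
            continue
        variants = {c: v for c, v in orf.variants.items() if c in support}
        best_caller = min(
            variants, key=lambda c: (-(variants[c][1] - variants[c][0]), order[c])
        )
        start, end = variants[best_caller]
        kept.append(
            ConsensusOrf(
                genome_id=orf.genome_id,
                strand=orf.strand,
                stop_anchor=orf.stop_anchor,
                supporting_callers=frozenset(support),
                selected_start=start,
                selected_end=end,
                variants=variants,
            )
        )
    return kept
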
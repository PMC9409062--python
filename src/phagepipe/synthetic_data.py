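"""Synthetic inputs with controllable statistical structure, and packaged
fixtures reproducing published worked examples.

All generators are pure functions of their parameters and a seed.  The
agreement-fixture builder emits five caller prediction sets whose merged
consensus reproduces a requested Venn-cell structure exactly; the packaged
default reproduces the case-study genome's cross-caller agreement numbers
(union 290, five-way intersection 90, one outlier caller with 144
predictions of which 47 unique, four-caller union 243 with 186 shared,
34 unique to the phage-specific caller).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .acr_screen import AcrCandidate
from .annotation_transfer import (
    SINGLETON,
    UNKNOWN,
    FunctionalAssignment,
    ProfileHit,
    assign_phrog,
)
from .consensus import ConsensusOrf, OrfPrediction
from .errors import ConfigurationError
from .io_formats import GenomeSequence, SimilarityMatrix, TrnaRecord

STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODONS = ("ATG", "GTG", "TTG")

#: The five benchmarked gene callers, in configured order.
DEFAULT_CALLERS = (
    "AMIGene", "Glimmer", "MetaGeneAnnotator", "Phanotate", "Prodigal",
)


def fixture_path(name: str) -> Path:
    """Path to a packaged fixture TSV."""
    return Path(importlib.resources.files("phagepipe") / "data" / name)


# ---------------------------------------------------------------------------
# Genome generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedOrf:
    """Ground truth for one planted gene."""

    start: int
    end: int
    strand: str
    label: str  # e.g. "terminase small subunit" or "gene"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def stop_anchor(self) -> int:
        return self.end if self.strand == "+" else self.start


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]  # A, T, G, C
    return rng.choice(np.array(list("ATGC")), size=n, p=p)


def _make_gene(rng: np.random.Generator, length: int, gc: float) -> str:
    """An in-frame gene: start codon, stop-free interior, stop codon."""
    interior = _random_bases(rng, length - 6, gc)
    gene = list("ATG") + list(interior) + list(rng.choice(STOP_CODONS))
    # scrub in-frame stops from the interior (genetic code 11)
    for i in range(3, length - 3, 3):
        while "".join(gene[i : i + 3]) in STOP_CODONS:
            gene[i + 2] = "C" if gene[i + 2] != "C" else "G"
    return "".join(gene)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def make_genome(
    length: int,
    gc: float = 0.5,
    terminal_repeat: int = 0,
    seed: int = 0,
    gene_density: float = 0.85,
) -> tuple[GenomeSequence, list[PlantedOrf]]:
    """Generate a phage-like genome with planted in-frame genes.

    Genes (start codon, stop-free interior, valid stop) are packed left to
    right with short intergenic gaps until ~``gene_density`` of the genome is
    coding; one mid-genome gene is labeled "terminase small subunit".  When
    ``terminal_repeat`` > 0, the first that many bases are appended to the
    end, emulating the assembler's exact terminal duplication on circularly
    permuted contigs.
    """
    if length < 1000:
        raise ConfigurationError("genome length must be >= 1000")
    if terminal_repeat >= length / 2:
        raise ConfigurationError(
            f"terminal repeat {terminal_repeat} >= half the genome length"
        )
    rng = np.random.default_rng(seed)
    seq = _random_bases(rng, length, gc)
    orfs: list[PlantedOrf] = []
    pos = int(rng.integers(50, 150))
    while pos < length - 1600:
        gene_len = int(rng.integers(100, 500)) * 3
        if pos + gene_len > length - 100:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        gene = _make_gene(rng, gene_len, gc)
        if strand == "-":
            gene = gene.translate(_COMPLEMENT)[::-1]
        seq[pos - 1 : pos - 1 + gene_len] = list(gene)
        orfs.append(PlantedOrf(pos, pos + gene_len - 1, strand, "gene"))
        mean_gap = max(10.0, 300.0 * (1 - gene_density) / max(gene_density, 0.05))
        pos += gene_len + 10 + int(rng.exponential(mean_gap))
    if not orfs:
        raise ConfigurationError("genome too short to plant any gene")
    term_idx = len(orfs) // 2
    orfs[term_idx] = PlantedOrf(
        orfs[term_idx].start, orfs[term_idx].end, orfs[term_idx].strand,
        "terminase small subunit",
    )
    sequence = "".join(seq)
    if terminal_repeat:
        sequence = sequence + sequence[:terminal_repeat]
    return (
        GenomeSequence(id=f"synthetic_{seed}", sequence=sequence),
        orfs,
    )


# ---------------------------------------------------------------------------
# Caller-output generator
# ---------------------------------------------------------------------------


def make_caller_outputs(
    true_orfs: Sequence[PlantedOrf],
    genome_length: int,
    callers: Sequence[str] = DEFAULT_CALLERS,
    sensitivity: Optional[Mapping[str, float]] = None,
    fp_rate: Optional[Mapping[str, float]] = None,
    start_jitter: float = 0.0,
    seed: int = 0,
    genome_id: str = "synthetic",
) -> dict[str, list[OrfPrediction]]:
    """Emulate per-caller disagreement on a set of true genes.

    Each caller detects each true gene with its sensitivity; with probability
    ``start_jitter`` the detected start is moved in-frame (stop preserved),
    exercising the stop-anchor identity rule; false predictions are added at
    ``fp_rate`` per kb with random stops.
    """
    sensitivity = dict(sensitivity or {c: 1.0 for c in callers})
    fp_rate = dict(fp_rate or {c: 0.0 for c in callers})
    for c in callers:
        for name, rates in (("sensitivity", sensitivity), ("fp_rate", fp_rate)):
            v = rates.get(c, 1.0 if name == "sensitivity" else 0.0)
            if name == "sensitivity" and not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}[{c}] = {v} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out: dict[str, list[OrfPrediction]] = {}
    for caller in callers:
        preds: list[OrfPrediction] = []
        taken_anchors: set[tuple[str, int]] = set()
        for orf in true_orfs:
            if rng.random() > sensitivity.get(caller, 1.0):
                continue
            start, end = orf.start, orf.end
            if rng.random() < start_jitter and orf.length > 120:
                shrink = 3 * int(rng.integers(1, min(10, (orf.length - 60) // 3)))
                if orf.strand == "+":
                    start += shrink
                else:
                    end -= shrink
            preds.append(
                OrfPrediction(genome_id, caller, orf.strand, start, end)
            )
            taken_anchors.add((orf.strand, orf.stop_anchor()))
        n_fp = rng.poisson(fp_rate.get(caller, 0.0) * genome_length / 1000.0)
        made = 0
        while made < n_fp:
            fp_len = 3 * int(rng.integers(40, 200))
            fp_start = int(rng.integers(1, genome_length - fp_len))
            strand = "+" if rng.random() < 0.5 else "-"
            anchor = fp_start + fp_len - 1 if strand == "+" else fp_start
            if (strand, anchor) in taken_anchors:
                continue
            taken_anchors.add((strand, anchor))
            preds.append(
                OrfPrediction(
                    genome_id, caller, strand, fp_start, fp_start + fp_len - 1
                )
            )
            made += 1
        out[caller] = sorted(preds, key=lambda p: (p.strand, p.stop_anchor()))
    return out


# ---------------------------------------------------------------------------
# Exact agreement-structure fixture
# ---------------------------------------------------------------------------

#: Venn cells reproducing the case-study five-caller agreement aggregates.
SEAO1_AGREEMENT_CELLS: dict[frozenset[str], int] = {
    frozenset(DEFAULT_CALLERS): 90,
    frozenset({"AMIGene", "MetaGeneAnnotator", "Phanotate", "Prodigal"}): 96,
    frozenset({"Glimmer"}): 47,
    frozenset({"Phanotate"}): 30,
    frozenset({"Glimmer", "Phanotate"}): 4,
    frozenset({"Glimmer", "MetaGeneAnnotator"}): 3,
    frozenset({"AMIGene", "Phanotate"}): 5,
    frozenset({"MetaGeneAnnotator", "Phanotate"}): 4,
    frozenset({"Phanotate", "Prodigal"}): 4,
    frozenset({"AMIGene", "MetaGeneAnnotator", "Prodigal"}): 3,
    frozenset({"AMIGene", "Prodigal"}): 2,
    frozenset({"MetaGeneAnnotator"}): 2,
}


def build_agreement_fixture(
    cells: Mapping[frozenset[str], int],
    callers: Sequence[str] = DEFAULT_CALLERS,
    per_caller_totals: Optional[Mapping[str, int]] = None,
    full_intersection: Optional[int] = None,
    orf_length: int = 300,
    spacing: int = 400,
    genome_id: str = "agreement_fixture",
) -> dict[str, list[OrfPrediction]]:
    """Emit per-caller prediction sets realizing an exact Venn structure.

    ``cells`` maps each caller subset to the number of ORFs predicted by
    exactly that subset.  Optional ``per_caller_totals`` and
    ``full_intersection`` are cross-checked against the cells and an
    infeasible specification raises a configuration error naming the
    violated constraint.
    """
    callers = list(callers)
    for subset, count in cells.items():
        if count < 0:
            raise ConfigurationError(f"negative cell count for {sorted(subset)}")
        if not subset or not subset <= set(callers):
            raise ConfigurationError(
                f"cell subset {sorted(subset)} not within callers {callers}"
            )
    implied_totals = {
        c: sum(n for sub, n in cells.items() if c in sub) for c in callers
    }
    if per_caller_totals is not None:
        if full_intersection is not None:
            low = min(per_caller_totals.values())
            if full_intersection > low:
                raise ConfigurationError(
                    f"full intersection {full_intersection} exceeds the "
                    f"smallest per-caller total {low}"
                )
        for c, want in per_caller_totals.items():
            if implied_totals.get(c) != want:
                raise ConfigurationError(
                    f"cells imply {implied_totals.get(c)} predictions for "
                    f"{c}, requested total is {want}"
                )
    if full_intersection is not None:
        got = cells.get(frozenset(callers), 0)
        if got != full_intersection:
            raise ConfigurationError(
                f"cells assign {got} to the full intersection, "
                f"requested {full_intersection}"
            )
    out: dict[str, list[OrfPrediction]] = {c: [] for c in callers}
    idx = 0
    for subset in sorted(cells, key=lambda s: sorted(s)):
        for _ in range(cells[subset]):
            start = 1 + idx * spacing
            end = start + orf_length - 1
            for rank, caller in enumerate(c for c in callers if c in subset):
                # vary the start in-frame per caller: same stop anchor
                out[caller].append(
                    OrfPrediction(
                        genome_id, caller, "+", start + 3 * rank, end
                    )
                )
            idx += 1
    return out


def seao1_agreement_fixture() -> dict[str, list[OrfPrediction]]:
    """The packaged default agreement fixture."""
    return build_agreement_fixture(SEAO1_AGREEMENT_CELLS)


# ---------------------------------------------------------------------------
# Hit-table generator
# ---------------------------------------------------------------------------

_CATEGORIES = (
    "head and packaging", "tail", "lysis", "connector",
    "DNA, RNA, and nucleotide metabolism", "transcription regulation",
    "moron, auxiliary metabolic gene and host takeover", "other",
)


def make_hit_table(
    query_ids: Sequence[str],
    affiliated_fraction: float = 0.6,
    seed: int = 0,
    strong_prob: tuple[float, float] = (85.0, 100.0),
    strong_log10_evalue: tuple[float, float] = (-30.0, -5.0),
    weak_prob: tuple[float, float] = (5.0, 70.0),
    weak_log10_evalue: tuple[float, float] = (-3.0, 1.0),
    unknown_fraction_of_strong: float = 0.3,
) -> list[ProfileHit]:
    """One family-database best hit per query.

    A fraction ``affiliated_fraction`` of queries receives a
    threshold-passing hit (probability and E-value inside the acceptance
    region); the rest receive sub-threshold hits.  Among passing hits, a
    fraction keeps the "unknown function" annotation (affiliated families
    of unknown function exist in the database).
    """
    rng = np.random.default_rng(seed)
    hits = []
    for i, q in enumerate(query_ids):
        strong = rng.random() < affiliated_fraction
        fam = f"phrog_{int(rng.integers(10, 40000))}"
        if strong:
            prob = float(rng.uniform(*strong_prob))
            evalue = float(10 ** rng.uniform(*strong_log10_evalue))
            if rng.random() < unknown_fraction_of_strong:
                annotation, category = UNKNOWN, UNKNOWN
            else:
                annotation = f"predicted_protein_{i}"
                category = str(rng.choice(_CATEGORIES))
        else:
            prob = float(rng.uniform(*weak_prob))
            evalue = float(10 ** rng.uniform(*weak_log10_evalue))
            annotation, category = UNKNOWN, UNKNOWN
        hits.append(
            ProfileHit(
                query_id=q, subject_id=fam, database="phrog",
                probability=prob, evalue=evalue,
                coverage=float(rng.uniform(0.5, 1.0)),
                annotation=annotation, category=category,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# Similarity-matrix generator (planted partitions)
# ---------------------------------------------------------------------------


def make_similarity_matrix(
    genus_blocks: Sequence[Sequence[int]] = ((3, 2, 1), (2, 2, 1), (2, 2), (2, 1)),
    seed: int = 0,
    within_species: tuple[float, float] = (96.0, 99.9),
    within_genus: tuple[float, float] = (75.0, 90.0),
    between_genera: tuple[float, float] = (20.0, 50.0),
) -> tuple[SimilarityMatrix, list[list[str]], list[list[str]]]:
    """A pairwise similarity matrix with planted genus and species blocks.

    ``genus_blocks`` lists, per genus, the sizes of its species clusters;
    the default plants 4 genera and 10 species over 18 genomes.  Returns the
    matrix and the true species and genus partitions.
    """
    rng = np.random.default_rng(seed)
    ids: list[str] = []
    species: list[list[str]] = []
    genera: list[list[str]] = []
    for gi, block in enumerate(genus_blocks, start=1):
        genus_members: list[str] = []
        for si, size in enumerate(block, start=1):
            members = [f"G{gi}S{si}R{k}" for k in range(1, size + 1)]
            species.append(members)
            genus_members.extend(members)
            ids.extend(members)
        genera.append(genus_members)
    n = len(ids)
    values = np.zeros((n, n))
    sp_of = {m: i for i, sp in enumerate(species) for m in sp}
    ge_of = {m: i for i, ge in enumerate(genera) for m in ge}
    for i in range(n):
        values[i, i] = 100.0
        for j in range(i + 1, n):
            a, b = ids[i], ids[j]
            if sp_of[a] == sp_of[b]:
                v = rng.uniform(*within_species)
            elif ge_of[a] == ge_of[b]:
                v = rng.uniform(*within_genus)
            else:
                v = rng.uniform(*between_genera)
            values[i, j] = values[j, i] = v
    return SimilarityMatrix(genome_ids=ids, values=values), species, genera


# ---------------------------------------------------------------------------
# Packaged-fixture loaders
# ---------------------------------------------------------------------------


def load_acr_candidates() -> list[AcrCandidate]:
    """The packaged anti-CRISPR candidate table (28 retained predictions
    across 10 genomes; query covers are synthetic placeholders)."""
    df = pd.read_csv(fixture_path("table6_acr.tsv"), sep="\t", comment="#")
    return [
        AcrCandidate(
            genome_id=row.genome_id,
            protein_id=row.protein_id,
            family_id=row.family_id,
            length_aa=int(row.length_aa),
            score_a=float(row.score_a),
            score_b=float(row.score_b),
            homolog_id=row.homolog_id,
            query_cover=float(row.query_cover),
            crispr_type=row.crispr_type,
            genus=row.genus,
        )
        for row in df.itertuples()
    ]


def acr_distractors() -> list[AcrCandidate]:
    """Synthetic candidates failing the stated filters, one per rule."""
    return [
        AcrCandidate("SeF1", "Gp_900", "phrog_90001", 250, 0.9, -0.5,
                     "Acr00001", 95.0, "I-E", genus="Jerseyvirus"),
        AcrCandidate("SeF1", "Gp_901", "phrog_90002", 80, 0.9, -0.5,
                     "Acr00002", 30.0, "I-E", genus="Jerseyvirus"),
        AcrCandidate("SeAO1", "Gp_902", "phrog_90003", 90, 0.2, -6.0,
                     "Acr00003", 80.0, "II-A", genus="Kuttervirus"),
        AcrCandidate("Se_F2", "Gp_903", "phrog_90004", 100, 0.1, -7.0,
                     "Acr00004", 70.0, "I-D", genus="Chivirus"),
    ]


def load_marker_content() -> dict[str, list[FunctionalAssignment]]:
    """Per-genome lifestyle-marker assignments (10 genomes; exactly one
    carries an integrase family)."""
    df = pd.read_csv(fixture_path("marker_content.tsv"), sep="\t", comment="#")
    out: dict[str, list[FunctionalAssignment]] = {}
    for row in df.itertuples():
        out.setdefault(row.genome_id, [])
        if row.family_id == "-":
            continue
        out[row.genome_id].append(
            FunctionalAssignment(
                query_id=f"{row.genome_id}_{row.family_id}",
                family_id=row.family_id,
                product=row.role,
                category="integration and excision",
                source="phrog",
            )
        )
    return out


@dataclass
class CurationCase:
    """One packaged curation scenario."""

    name: str
    orfs: list[ConsensusOrf]
    trnas: list[TrnaRecord]
    assignments: dict[str, FunctionalAssignment]
    orf_names: dict[str, str]  # feature id -> printed gene name


def load_curation_cases() -> dict[str, CurationCase]:
    """The three packaged curation scenarios as ready-to-curate objects."""
    from .curation import orf_feature_id

    df = pd.read_csv(
        fixture_path("curation_cases.tsv"), sep="\t", comment="#", dtype=str
    )
    cases: dict[str, CurationCase] = {}
    for name, group in df.groupby("case", sort=False):
        orfs: list[ConsensusOrf] = []
        trnas: list[TrnaRecord] = []
        assignments: dict[str, FunctionalAssignment] = {}
        names: dict[str, str] = {}
        for row in group.itertuples():
            start, end = int(row.start), int(row.end)
            if row.feature_type == "trna":
                trnas.append(
                    TrnaRecord("curation_fixture", start, end, row.strand,
                               row.isotype)
                )
                continue
            orf = ConsensusOrf(
                genome_id="curation_fixture",
                strand=row.strand,
                stop_anchor=end if row.strand == "+" else start,
                supporting_callers=frozenset({"Phanotate"}),
                selected_start=start,
                selected_end=end,
                variants={"Phanotate": (start, end)},
            )
            orfs.append(orf)
            oid = orf_feature_id(orf)
            names[oid] = row.feature_id
            if row.family_id == "-":
                assignments[oid] = assign_phrog(None, query_id=row.feature_id)
            else:
                hit = ProfileHit(
                    query_id=row.feature_id, subject_id=row.family_id,
                    database="phrog", probability=float(row.probability),
                    evalue=float(row.evalue), coverage=0.9,
                    annotation="predicted protein", category="other",
                )
                assignments[oid] = assign_phrog(hit)
        cases[name] = CurationCase(name, orfs, trnas, assignments, names)
    return cases
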
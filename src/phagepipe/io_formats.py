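"""Readers and writers for every external representation the pipeline touches.

Conventions
-----------
* Coordinates are 1-based inclusive throughout (GFF3/GenBank convention).
* Genes spanning the extremity of a circular-permuted contig are represented
  internally with ``end = start + len - 1`` possibly exceeding the genome
  length; the GFF3 writer emits them as a two-part feature sharing one ID,
  and the reader rejoins such parts using the ``##sequence-region`` pragma.
* Hit-table coverage is stored as a fraction of the *query* aligned.  Whether
  the upstream profile search measured query or subject coverage is not
  recoverable from the table; query coverage is assumed.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation_transfer import ProfileHit
from .consensus import OrfPrediction
from .errors import ParseError, StateError, ValidationError

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """An assembled phage contig."""

    id: str
    sequence: str
    topology: str = "linear"  # "linear" or "circular-permuted"
    packaging: Optional[str] = None  # "pac-headful", "cos", "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("genome id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"genome {self.id!r} has empty sequence")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValidationError(
                f"genome {self.id!r} contains non-DNA characters {sorted(bad)}"
            )
        if self.topology not in ("linear", "circular-permuted"):
            raise ValidationError(f"unknown topology {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TrnaRecord:
    """A tRNA gene (predicted upstream; consumed as input)."""

    genome_id: str
    start: int
    end: int
    strand: str
    isotype: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValidationError(
                f"invalid tRNA coordinates {self.start}-{self.end} "
                f"on {self.genome_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SimilarityMatrix:
    """Square matrix of pairwise intergenomic similarity in percent."""

    genome_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.genome_ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} genome ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValidationError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 100.0, atol=1e-6):
            raise ValidationError("similarity matrix diagonal must be 100")

    def similarity(self, a: str, b: str) -> float:
        i, j = self.genome_ids.index(a), self.genome_ids.index(b)
        return float(self.values[i, j])


@dataclass
class GeneRecord:
    """A finalized annotated feature with its curation audit trail."""

    feature_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    product: str = "unknown function"
    family_id: str = "singleton"
    category: str = "unknown function"
    locus_tag: Optional[str] = None
    curation_action: str = "keep"  # keep | discard
    curation_rule: str = "no-conflict"
    supporting_callers: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """The complete annotation of one genome."""

    genome_id: str
    genome_length: int
    genes: list[GeneRecord] = field(default_factory=list)
    trnas: list[TrnaRecord] = field(default_factory=list)

    @property
    def kept_genes(self) -> list[GeneRecord]:
        return [g for g in self.genes if g.curation_action == "keep"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_genomes_fasta(path: str | Path) -> list[GenomeSequence]:
    genomes = [
        GenomeSequence(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate genome ids in {path}")
    return genomes


def write_genomes_fasta(genomes: Sequence[GenomeSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Caller predictions (GFF3 or normalized TSV)
# ---------------------------------------------------------------------------


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = urllib.parse.unquote(value.strip())
    return attrs


def _collapse_duplicates(
    predictions: list[OrfPrediction],
) -> list[OrfPrediction]:
    """Collapse same-caller duplicates sharing (strand, stop anchor): longest wins."""
    best: dict[tuple[str, int], OrfPrediction] = {}
    for p in predictions:
        key = (p.strand, p.stop_anchor())
        if key not in best or p.length > best[key].length:
            best[key] = p
    return sorted(best.values(), key=lambda p: (p.strand, p.stop_anchor()))


def read_caller_predictions(
    path: str | Path, dialect: str, caller: str
) -> list[OrfPrediction]:
    """Read one gene caller's ORF predictions.

    Caller-native output dialects are not parsed; the ingestion contract is
    GFF3 (CDS features, 1-based inclusive) or a normalized four-column TSV
    ``genome_id  start  end  strand``.  Records are tagged with ``caller``,
    sorted by (strand, stop anchor), and same-caller duplicates sharing a
    stop anchor are collapsed to the longest extent.
    """
    path = Path(path)
    if dialect == "gff3":
        return _read_gff3_predictions(path, caller)
    if dialect == "tsv":
        return _read_tsv_predictions(path, caller)
    raise ParseError(f"unsupported dialect {dialect!r}")


def _read_gff3_predictions(path: Path, caller: str) -> list[OrfPrediction]:
    region_length: dict[str, int] = {}
    # parts of multi-segment (wrap-around) features, grouped by (seqid, ID)
    parts: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    singles: list[OrfPrediction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                fields = line.split()
                if len(fields) == 4:
                    region_length[fields[1]] = int(fields[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            if ftype.upper() != "CDS":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinate "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            if end < start:
                raise ParseError(
                    f"{path}:{lineno}: start > end ({start} > {end}) "
                    "on a linear feature"
                )
            attrs = _parse_gff3_attributes(attr_s)
            fid = attrs.get("ID")
            if fid:
                parts.setdefault((seqid, fid), []).append((start, end, strand))
            else:
                singles.append(
                    OrfPrediction(
                        genome_id=seqid, caller=caller, strand=strand,
                        start=start, end=end,
                    )
                )
    predictions = list(singles)
    for (seqid, fid), segs in parts.items():
        if len(segs) == 1:
            start, end, strand = segs[0]
            predictions.append(
                OrfPrediction(
                    genome_id=seqid, caller=caller, strand=strand,
                    start=start, end=end,
                )
            )
        elif len(segs) == 2 and seqid in region_length:
            # wrap-around feature: [a..L] + [1..b] -> start=a, end=L+b
            length = region_length[seqid]
            segs = sorted(segs)
            (s1, e1, strand1), (s2, e2, strand2) = segs
            if strand1 != strand2 or s1 != 1 or e2 != length:
                raise ParseError(
                    f"{path}: feature {fid!r} has inconsistent segments"
                )
            predictions.append(
                OrfPrediction(
                    genome_id=seqid, caller=caller, strand=strand1,
                    start=s2, end=length + e1,
                )
            )
        else:
            raise ParseError(
                f"{path}: feature {fid!r} has {len(segs)} segments but no "
                "##sequence-region pragma to rejoin them"
            )
    return _collapse_duplicates(predictions)


def _read_tsv_predictions(path: Path, caller: str) -> list[OrfPrediction]:
    predictions = []
    with open(path) as fh:
        header: Optional[list[str]] = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if header is None:
                header = cols
                required = {"genome_id", "start", "end", "strand"}
                if not required <= set(header):
                    raise ParseError(
                        f"{path}:{lineno}: missing columns "
                        f"{sorted(required - set(header))}"
                    )
                continue
            row = dict(zip(header, cols))
            try:
                start, end = int(row["start"]), int(row["end"])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from None
            if row["strand"] not in ("+", "-"):
                raise ParseError(
                    f"{path}:{lineno}: unknown strand {row['strand']!r}"
                )
            if end < start:
                raise ParseError(
                    f"{path}:{lineno}: start > end ({start} > {end}) "
                    "on a linear genome without wrap flag"
                )
            predictions.append(
                OrfPrediction(
                    genome_id=row["genome_id"], caller=caller,
                    strand=row["strand"], start=start, end=end,
                )
            )
    return _collapse_duplicates(predictions)


def write_caller_predictions_tsv(
    predictions: Sequence[OrfPrediction], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tstart\tend\tstrand\n")
        for p in predictions:
            fh.write(f"{p.genome_id}\t{p.start}\t{p.end}\t{p.strand}\n")


# ---------------------------------------------------------------------------
# Profile hit tables
# ---------------------------------------------------------------------------

_HIT_COLUMNS = [
    "query_id", "subject_id", "probability", "evalue",
    "coverage", "annotation", "category",
]


def read_hit_table(path: str | Path, database_tag: str) -> list[ProfileHit]:
    """Read a per-protein best-hit table (family or structure database).

    TSV columns: query_id, subject_id, probability (percent), evalue
    (scientific notation accepted), coverage (fraction of the query in
    [0, 1]), annotation, category.  An empty file yields an empty list.
    """
    if database_tag not in ("phrog", "pdb"):
        raise ValidationError(f"unknown database tag {database_tag!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.empty and set(df.columns) == set():
        return []
    missing = set(_HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    hits = []
    for i, row in enumerate(df.itertuples(), start=2):
        try:
            probability = float(row.probability)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}:{i}: unparsable probability {row.probability!r}"
            ) from None
        try:
            evalue = float(row.evalue)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}:{i}: unparsable evalue {row.evalue!r}"
            ) from None
        try:
            coverage = float(row.coverage)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}:{i}: unparsable coverage {row.coverage!r}"
            ) from None
        hits.append(
            ProfileHit(
                query_id=row.query_id,
                subject_id=row.subject_id,
                database=database_tag,
                probability=probability,
                evalue=evalue,
                coverage=coverage,
                annotation=row.annotation,
                category=row.category,
            )
        )
    return hits


def write_hit_table(hits: Sequence[ProfileHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.probability:g}\t"
                f"{h.evalue:g}\t{h.coverage:g}\t{h.annotation}\t{h.category}\n"
            )


# ---------------------------------------------------------------------------
# Similarity matrices
# ---------------------------------------------------------------------------


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    """Read a square intergenomic-similarity TSV with id header row/column.

    Values asymmetric by at most 0.01 (percentage points) are symmetrized by
    averaging; larger asymmetry is a validation error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ParseError(
            f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, not square"
        )
    if list(df.index) != list(df.columns):
        raise ParseError(f"{path}: row and column ids differ")
    values = df.to_numpy(dtype=float)
    asym = np.abs(values - values.T).max()
    if asym > 0.01:
        raise ValidationError(
            f"{path}: asymmetry {asym:.4g} exceeds tolerance 0.01"
        )
    values = (values + values.T) / 2.0
    return SimilarityMatrix(genome_ids=[str(i) for i in df.index], values=values)


def write_similarity_matrix(matrix: SimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        matrix.values, index=matrix.genome_ids, columns=matrix.genome_ids
    )
    df.to_csv(path, sep="\t", float_format="%.2f")


# ---------------------------------------------------------------------------
# Annotation output
# ---------------------------------------------------------------------------


def _gff3_escape(value: str) -> str:
    return urllib.parse.quote(value, safe=" _.:^*$@!+?|-")


def write_annotation(
    annotation: GenomeAnnotation, path: str | Path, format: str = "gff3"
) -> None:
    """Write a finalized annotation.

    * ``gff3``: kept CDS features (with product, family note and curation
      status attributes) and tRNA features; discarded genes are omitted.
      Wrap-around genes are emitted as two segments sharing one ID.
    * ``tsv``: the full audit export including discarded genes.
    * ``flat``: a human-readable GenBank-like feature table (no sequence).
    """
    if format == "gff3":
        _write_gff3(annotation, path)
    elif format == "tsv":
        _write_audit_tsv(annotation, path)
    elif format == "flat":
        _write_flat(annotation, path)
    else:
        raise ValidationError(f"unknown annotation format {format!r}")


def _require_locus_tags(annotation: GenomeAnnotation) -> None:
    untagged = [g.feature_id for g in annotation.kept_genes if not g.locus_tag]
    if untagged:
        raise StateError(
            f"genes without locus tags: {untagged[:5]}"
            + ("..." if len(untagged) > 5 else "")
        )


def _gene_attributes(g: GeneRecord) -> str:
    note = f"{g.family_id}: {g.product}"
    attrs = [
        f"ID={_gff3_escape(g.feature_id)}",
        f"locus_tag={_gff3_escape(g.locus_tag or '')}",
        f"product={_gff3_escape(g.product)}",
        f"note={_gff3_escape(note)}",
        f"curation_status={_gff3_escape(g.curation_rule)}",
    ]
    return ";".join(attrs)


def _write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    _require_locus_tags(annotation)
    L = annotation.genome_length
    lines = ["##gff-version 3", f"##sequence-region {annotation.genome_id} 1 {L}"]
    features: list[tuple[int, str]] = []
    for g in sorted(annotation.kept_genes, key=lambda g: (g.start, g.end)):
        attrs = _gene_attributes(g)
        if g.end > L:
            # wrap-around gene: two segments sharing one ID
            features.append((g.start, _gff3_line(annotation.genome_id, "CDS", g.start, L, g.strand, attrs)))
            features.append((g.start, _gff3_line(annotation.genome_id, "CDS", 1, g.end - L, g.strand, attrs)))
        else:
            features.append((g.start, _gff3_line(annotation.genome_id, "CDS", g.start, g.end, g.strand, attrs)))
    for i, t in enumerate(sorted(annotation.trnas, key=lambda t: t.start), 1):
        attrs = f"ID=trna{i};product=tRNA-{_gff3_escape(t.isotype)}"
        features.append((t.start, _gff3_line(annotation.genome_id, "tRNA", t.start, t.end, t.strand, attrs)))
    lines.extend(line for _start, line in sorted(features, key=lambda x: x[0]))
    Path(path).write_text("\n".join(lines) + "\n")


def _gff3_line(seqid: str, ftype: str, start: int, end: int, strand: str, attrs: str) -> str:
    return f"{seqid}\tphagepipe\t{ftype}\t{start}\t{end}\t.\t{strand}\t0\t{attrs}"


_AUDIT_COLUMNS = [
    "genome_id", "feature_id", "locus_tag", "start", "end", "strand",
    "product", "family_id", "category", "curation_action", "curation_rule",
    "supporting_callers",
]


def _write_audit_tsv(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_AUDIT_COLUMNS) + "\n")
        for g in sorted(annotation.genes, key=lambda g: (g.start, g.end)):
            fh.write(
                "\t".join(
                    [
                        g.genome_id, g.feature_id, g.locus_tag or "",
                        str(g.start), str(g.end), g.strand, g.product,
                        g.family_id, g.category, g.curation_action,
                        g.curation_rule, ",".join(g.supporting_callers),
                    ]
                )
                + "\n"
            )


def _write_flat(annotation: GenomeAnnotation, path: str | Path) -> None:
    _require_locus_tags(annotation)
    lines = [
        f"LOCUS       {annotation.genome_id}  {annotation.genome_length} bp  DNA",
        "FEATURES             Location/Qualifiers",
    ]
    for g in sorted(annotation.kept_genes, key=lambda g: (g.start, g.end)):
        loc = f"{g.start}..{g.end}"
        if g.strand == "-":
            loc = f"complement({loc})"
        lines.append(f"     CDS             {loc}")
        lines.append(f'                     /locus_tag="{g.locus_tag}"')
        lines.append(f'                     /product="{g.product}"')
        lines.append(f'                     /note="{g.family_id}: {g.product}"')
    for t in sorted(annotation.trnas, key=lambda t: t.start):
        loc = f"{t.start}..{t.end}"
        if t.strand == "-":
            loc = f"complement({loc})"
        lines.append(f"     tRNA            {loc}")
        lines.append(f'                     /product="tRNA-{t.isotype}"')
    Path(path).write_text("\n".join(lines) + "\n")
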
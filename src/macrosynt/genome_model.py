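"""Domain model and I/O for gene-order comparative genomics.

The central object is :class:`GenomeAnnotation`: an ordered set of scaffolds,
each carrying its gene loci sorted by start coordinate and numbered with
0-based *ordinals*.  Every synteny and colinearity statistic in this package
is a function of scaffold membership and ordinals, not of base-pair
positions, so the model deliberately stores gene-level spans only (no
exon/intron structure).

Coordinates are stored 0-based half-open throughout.  GFF3 I/O converts
from/to the format's 1-based inclusive convention; BED is native.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

Source = Union[str, Path, TextIO]

__all__ = [
    "GeneLocus",
    "GenomeAnnotation",
    "SimilarityRecord",
    "RepeatInterval",
    "GenomeModelError",
    "ParseError",
    "ValidationError",
    "read_gff3",
    "write_gff3",
    "read_fasta",
    "write_fasta",
    "read_blast_tab",
    "write_blast_tab",
    "read_bed",
    "write_bed",
    "read_lengths_tsv",
]


class GenomeModelError(Exception):
    """Base class for model and I/O errors."""


class ParseError(GenomeModelError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(GenomeModelError):
    """Parsed content violates a model invariant."""


@dataclass(frozen=True)
class GeneLocus:
    """A gene span on a scaffold.

    ``start``/``end`` are 0-based half-open; ``ordinal`` is the gene's rank
    among the genes of its scaffold ordered by (start, end, gene_id).
    """

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    ordinal: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"gene {self.gene_id}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class GenomeAnnotation:
    """Ordered gene loci per scaffold — the substrate of every statistic."""

    species_label: str
    scaffolds: list[tuple[str, int]]
    genes: list[GeneLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_loci(
        cls,
        species_label: str,
        scaffolds: Sequence[tuple[str, int]],
        loci: Iterable[tuple[str, str, int, int, str]],
    ) -> "GenomeAnnotation":
        """Build an annotation from unordered (gene_id, scaffold_id, start,
        end, strand) tuples, assigning ordinals by sorted start position.

        Ties on start are broken by (end, gene_id) so ordinals are
        deterministic regardless of input order.
        """
        by_scaffold: dict[str, list[tuple[str, str, int, int, str]]] = {
            sid: [] for sid, _ in scaffolds
        }
        for locus in loci:
            gene_id, scaffold_id, start, end, strand = locus
            if scaffold_id not in by_scaffold:
                raise ValidationError(
                    f"gene {gene_id}: unknown scaffold {scaffold_id!r}"
                )
            by_scaffold[scaffold_id].append(locus)
        genes: list[GeneLocus] = []
        for sid, _length in scaffolds:
            ranked = sorted(by_scaffold[sid], key=lambda t: (t[2], t[3], t[0]))
            for ordinal, (gene_id, scaffold_id, start, end, strand) in enumerate(ranked):
                genes.append(
                    GeneLocus(gene_id, scaffold_id, start, end, strand, ordinal)
                )
        return cls(species_label, list(scaffolds), genes)

    # -- accessors --------------------------------------------------------

    @property
    def scaffold_ids(self) -> list[str]:
        return [sid for sid, _ in self.scaffolds]

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return dict(self.scaffolds)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def genes_on(self, scaffold_id: str) -> list[GeneLocus]:
        """Genes of one scaffold in ordinal order."""
        return sorted(
            (g for g in self.genes if g.scaffold_id == scaffold_id),
            key=lambda g: g.ordinal,
        )

    def gene(self, gene_id: str) -> GeneLocus:
        try:
            return self._gene_index[gene_id]
        except KeyError:
            raise ValidationError(
                f"gene {gene_id!r} not present in annotation "
                f"{self.species_label!r}"
            ) from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._gene_index

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        ids = self.scaffold_ids
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate scaffold_id in annotation")
        lengths = self.scaffold_lengths
        seen: set[str] = set()
        per_scaffold: dict[str, list[int]] = {sid: [] for sid in ids}
        for g in self.genes:
            if g.gene_id in seen:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.scaffold_id not in lengths:
                raise ValidationError(
                    f"gene {g.gene_id}: unknown scaffold {g.scaffold_id!r}"
                )
            if g.end > lengths[g.scaffold_id]:
                raise ValidationError(
                    f"gene {g.gene_id}: end {g.end} exceeds scaffold "
                    f"{g.scaffold_id} length {lengths[g.scaffold_id]}"
                )
            per_scaffold[g.scaffold_id].append(g.ordinal)
        for sid, ords in per_scaffold.items():
            if sorted(ords) != list(range(len(ords))):
                raise ValidationError(
                    f"scaffold {sid}: ordinals are not 0..{len(ords) - 1}"
                )
        self._gene_index = {g.gene_id: g for g in self.genes}


@dataclass(frozen=True)
class SimilarityRecord:
    """One line of an all-vs-all protein similarity search."""

    query_id: str
    subject_id: str
    bitscore: float
    evalue: float
    pct_identity: float | None = None


@dataclass(frozen=True)
class RepeatInterval:
    """A repeat annotation span, 0-based half-open."""

    scaffold_id: str
    start: int
    end: int
    family: str = "repeat"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"repeat interval on {self.scaffold_id}: start must be < end "
                f"(got {self.start}, {self.end})"
            )


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def _open_text(source: Source) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "rt"), True
    return source, False


_SEQREGION = re.compile(r"^##sequence-region\s+(\S+)\s+(\d+)\s+(\d+)\s*$")


def read_gff3(
    source: Source,
    feature_type: str = "gene",
    id_attribute: str = "ID",
    species_label: str = "genome",
    scaffold_lengths: Mapping[str, int] | None = None,
) -> GenomeAnnotation:
    """Read gene loci from a GFF3 file into a :class:`GenomeAnnotation`.

    Scaffold lengths are taken from ``##sequence-region`` pragmas unless an
    explicit ``scaffold_lengths`` mapping is supplied (a TSV fallback can be
    loaded with :func:`read_lengths_tsv`).  Only features of ``feature_type``
    are kept; gene identity comes from ``id_attribute`` (JGI and GenBank GFF
    dialects differ, hence configurable).
    """
    handle, owned = _open_text(source)
    lengths: dict[str, int] = dict(scaffold_lengths or {})
    order: list[str] = list(lengths)
    loci: list[tuple[str, str, int, int, str]] = []
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            m = _SEQREGION.match(line)
            if m:
                sid, lo, hi = m.group(1), int(m.group(2)), int(m.group(3))
                if sid not in lengths:
                    order.append(sid)
                lengths[sid] = hi - lo + 1
                continue
            if line.startswith("#"):
                continue
            feat = feature_from_line(line)
            if feat.featuretype != feature_type:
                continue
            attrs = feat.attributes.get(id_attribute)
            if not attrs:
                raise ParseError(
                    f"line {lineno}: feature lacks attribute "
                    f"{id_attribute!r}: {line}"
                )
            # GFF3 1-based inclusive -> 0-based half-open
            loci.append((attrs[0], feat.seqid, feat.start - 1, feat.end, feat.strand))
    finally:
        if owned:
            handle.close()
    if not lengths:
        raise ParseError(
            "no ##sequence-region pragmas found and no scaffold_lengths given"
        )
    scaffolds = [(sid, lengths[sid]) for sid in order]
    return GenomeAnnotation.from_loci(species_label, scaffolds, loci)


def write_gff3(annot: GenomeAnnotation, dest: Source) -> None:
    handle, owned = (open(dest, "wt"), True) if isinstance(dest, (str, Path)) else (dest, False)
    try:
        handle.write("##gff-version 3\n")
        for sid, length in annot.scaffolds:
            handle.write(f"##sequence-region {sid} 1 {length}\n")
        for sid, _ in annot.scaffolds:
            for g in annot.genes_on(sid):
                handle.write(
                    f"{sid}\tmacrosynt\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}\n"
                )
    finally:
        if owned:
            handle.close()


def read_fasta(source: Source) -> tuple[dict[str, str], dict[str, int]]:
    """Read FASTA into (id -> sequence, id -> length).

    Identifiers are the first whitespace-delimited token of the header.
    Duplicate identifiers and empty records are errors.
    """
    handle, owned = _open_text(source)
    seqs: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seqs:
                raise ParseError(f"duplicate FASTA identifier {rec.id!r}")
            seq = str(rec.seq).upper()
            if not seq:
                raise ParseError(f"empty FASTA record {rec.id!r}")
            seqs[rec.id] = seq
    finally:
        if owned:
            handle.close()
    return seqs, {sid: len(s) for sid, s in seqs.items()}


def write_fasta(sequences: Mapping[str, str], dest: Source, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in sequences.items()
    ]
    if isinstance(dest, (str, Path)):
        with open(dest, "wt") as fh:
            SeqIO.write(records, fh, "fasta")
    else:
        SeqIO.write(records, dest, "fasta")


_BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(source: Source) -> list[SimilarityRecord]:
    """Read 12-column BLAST tabular (outfmt 6) similarity records.

    Extra columns are ignored.  Duplicate (query, subject) rows are
    collapsed keeping the maximum bitscore (at equal bitscore, the lower
    e-value).
    """
    handle, owned = _open_text(source)
    try:
        df = pd.read_csv(
            handle, sep="\t", header=None, comment="#", dtype=str,
            skip_blank_lines=True, keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        return []
    finally:
        if owned:
            handle.close()
    if df.shape[1] < 12:
        raise ParseError(
            f"expected >= 12 tab-separated columns, got {df.shape[1]}"
        )
    df = df.iloc[:, :12]
    df.columns = _BLAST_COLUMNS
    for col in ("bitscore", "evalue", "pident"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            lineno = int(bad.idxmax()) + 1
            raise ParseError(
                f"line {lineno}: non-numeric {col} value {df[col][bad.idxmax()]!r}"
            )
        df[col] = converted
    # keep the best-scoring row per (query, subject)
    df = df.sort_values(
        ["qseqid", "sseqid", "bitscore", "evalue"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).drop_duplicates(["qseqid", "sseqid"], keep="first")
    return [
        SimilarityRecord(
            query_id=row.qseqid,
            subject_id=row.sseqid,
            bitscore=float(row.bitscore),
            evalue=float(row.evalue),
            pct_identity=float(row.pident),
        )
        for row in df.itertuples(index=False)
    ]


def write_blast_tab(records: Iterable[SimilarityRecord], dest: Source) -> None:
    handle, owned = (open(dest, "wt"), True) if isinstance(dest, (str, Path)) else (dest, False)
    try:
        for r in records:
            pident = r.pct_identity if r.pct_identity is not None else 0.0
            handle.write(
                f"{r.query_id}\t{r.subject_id}\t{pident:.1f}\t0\t0\t0\t"
                f"0\t0\t0\t0\t{r.evalue:g}\t{r.bitscore:g}\n"
            )
    finally:
        if owned:
            handle.close()


def read_bed(source: Source) -> list[RepeatInterval]:
    """Read BED3+ repeat intervals; the optional name column becomes the
    repeat family (defaulting to "repeat")."""
    handle, owned = _open_text(source)
    intervals: list[RepeatInterval] = []
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"line {lineno}: non-integer BED coordinates"
                ) from None
            family = fields[3] if len(fields) > 3 and fields[3] else "repeat"
            if start >= end:
                raise ValidationError(
                    f"line {lineno}: BED start {start} >= end {end}"
                )
            intervals.append(RepeatInterval(fields[0], start, end, family))
    finally:
        if owned:
            handle.close()
    return intervals


def write_bed(intervals: Iterable[RepeatInterval], dest: Source) -> None:
    handle, owned = (open(dest, "wt"), True) if isinstance(dest, (str, Path)) else (dest, False)
    try:
        for iv in intervals:
            handle.write(f"{iv.scaffold_id}\t{iv.start}\t{iv.end}\t{iv.family}\n")
    finally:
        if owned:
            handle.close()


def read_lengths_tsv(source: Source) -> dict[str, int]:
    """Two-column TSV fallback for scaffold lengths: scaffold_id, length."""
    handle, owned = _open_text(source)
    try:
        df = pd.read_csv(handle, sep="\t", header=None, names=["scaffold_id", "length"])
    finally:
        if owned:
            handle.close()
    return dict(zip(df.scaffold_id.astype(str), df.length.astype(int)))
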
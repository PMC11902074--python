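"""Readers and writers for the pipeline's external formats.

Gene loci come in as GFF3 (gene features only), transcript/CDS sequences as
FASTA, counts as TSV with ``<stage>_<rep>`` columns.  Internally all
coordinates are 0-based half-open; GFF3 I/O converts from/to the 1-based
inclusive convention.  Every path may be plain text or gzipped.

Typed record tables (homoeologs, specific genes, DEG results, bias calls)
round-trip through :func:`write_table` / :func:`read_table`, which derive the
column schema from the record dataclass.
"""

from __future__ import annotations

import dataclasses
import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence, TypeVar

import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import CountMatrix, SampleDesign

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass(frozen=True)
class GeneModel:
    """One gene locus: 0-based half-open span on a chromosome of one subgenome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    subgenome: str
    sequence_key: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.gene_id}: invalid span [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.subgenome not in ("A", "B"):
            raise ValueError(f"{self.gene_id}: subgenome must be A or B")
        if not self.sequence_key:
            object.__setattr__(self, "sequence_key", self.gene_id)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """All gene models of one subgenome, per chromosome in coordinate order,
    plus their transcript/CDS sequences keyed by gene id."""

    subgenome: str
    genes: dict[str, list[GeneModel]] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, models in self.genes.items():
            self.genes[chrom] = sorted(models, key=lambda g: (g.start, g.end, g.gene_id))
        ids = [g.gene_id for g in self.iter_genes()]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene ids in annotation")
        self._by_id = {g.gene_id: g for g in self.iter_genes()}

    def iter_genes(self) -> Iterable[GeneModel]:
        for chrom in sorted(self.genes):
            yield from self.genes[chrom]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.iter_genes()]

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.genes.values())

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def sequence_of(self, gene_id: str) -> str:
        return self.sequences[self.gene(gene_id).sequence_key]

    def ranks(self) -> dict[str, int]:
        """Gene-order index along each chromosome (0-based)."""
        out: dict[str, int] = {}
        for chrom in sorted(self.genes):
            for i, g in enumerate(self.genes[chrom]):
                out[g.gene_id] = i
        return out

    def validate_sequences(self) -> None:
        missing = [g.gene_id for g in self.iter_genes() if g.sequence_key not in self.sequences]
        if missing:
            raise ValueError(f"genes without sequences: {missing[:5]}...")


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_gff3(path: str | Path, subgenome: str = "A", feature_type: str = "gene") -> GenomeAnnotation:
    """Parse gene features from a GFF3 file into a :class:`GenomeAnnotation`.

    Only rows whose type equals ``feature_type`` are kept (which feature level
    carries the gene models is configurable; "gene" is the default).  GFF3
    1-based inclusive coordinates become 0-based half-open.  Sequences are not
    populated here; pair with :func:`read_fasta`.
    """
    genes: dict[str, list[GeneModel]] = {}
    seen: set[str] = set()
    n = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns, got {len(cols)}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype != feature_type:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise ParseError(f"{path}: line {lineno}: invalid coordinates {start1}..{end1}")
            if strand not in STRANDS:
                raise ParseError(f"{path}: line {lineno}: invalid strand {strand!r}")
            gene_id = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("ID="):
                    gene_id = part[3:]
                    break
            if not gene_id:
                raise ParseError(f"{path}: line {lineno}: {feature_type} feature without ID attribute")
            if gene_id in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            genes.setdefault(chrom, []).append(
                GeneModel(gene_id=gene_id, chrom=chrom, start=start1 - 1, end=end1,
                          strand=strand, subgenome=subgenome)
            )
            n += 1
    if n == 0:
        logger.warning("no %s features found in %s", feature_type, path)
    return GenomeAnnotation(subgenome=subgenome, genes=genes)


def write_gff3(annotation: GenomeAnnotation, path: str | Path, feature_type: str = "gene") -> Path:
    """Write gene features back out as GFF3 (1-based inclusive)."""
    path = Path(path)
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.iter_genes():
            fh.write(
                f"{g.chrom}\thomeodyn\t{feature_type}\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as ``{id: uppercased sequence}``; id = first token."""
    sequences: dict[str, str] = {}
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in sequences:
                raise ParseError(f"{path}: duplicate FASTA id {record.id!r}")
            seq = str(record.seq).upper()
            if not seq:
                raise ParseError(f"{path}: empty sequence for {record.id!r}")
            sequences[record.id] = seq
    return sequences


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with _open_text(path, "wt") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def read_counts(path: str | Path, design: SampleDesign) -> CountMatrix:
    """Read a featureCounts-style TSV (gene_id + one column per design sample).

    An optional ``length`` column provides gene lengths for FPKM.  Sample
    columns must exactly cover the design; counts must be non-negative
    integers.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t")
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: missing gene_id column")
    df = df.set_index("gene_id")
    lengths = None
    if "length" in df.columns:
        lengths = df.pop("length").astype(float)
    expected = set(design.sample_ids)
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise ParseError(f"{path}: unknown sample columns {unknown}")
    missing = [c for c in design.sample_ids if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing design samples {missing}")
    values = df.to_numpy()
    try:
        as_int = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric counts") from exc
    if not (as_int == as_int.round()).all():
        raise ParseError(f"{path}: non-integer counts")
    if (as_int < 0).any():
        raise ParseError(f"{path}: negative counts")
    return CountMatrix(counts=df.astype(np.int64), design=design, gene_lengths=lengths)


def write_counts(matrix: CountMatrix, path: str | Path) -> Path:
    df = matrix.counts.copy()
    if matrix.gene_lengths is not None:
        df.insert(0, "length", matrix.gene_lengths.astype(int))
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index_label="gene_id")
    return Path(path)


R = TypeVar("R")


def write_table(records: Sequence, path: str | Path, record_type: type | None = None) -> Path:
    """Write a list of dataclass records as a UTF-8 TSV with header.

    An empty list needs ``record_type`` to know the header.
    """
    if not records and record_type is None:
        raise ValueError("record_type required to write an empty table")
    rtype = record_type or type(records[0])
    fields = [f.name for f in dataclasses.fields(rtype)]
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=fields)
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)
    return Path(path)


def _coerce(value, target):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if target is bool:
        if isinstance(value, bool):
            return value
        return str(value).strip().lower() in ("true", "1")
    return target(value)


def read_table(path: str | Path, record_type: type[R]) -> list[R]:
    """Read a TSV written by :func:`write_table` back into typed records."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t")
    fields = dataclasses.fields(record_type)
    hints = {}
    for f in fields:
        t = f.type if isinstance(f.type, type) else None
        if t is None:
            name = str(f.type).replace("typing.Optional[", "").rstrip("]")
            name = name.split("|")[0].strip()
            t = {"str": str, "int": int, "float": float, "bool": bool}.get(name, str)
        hints[f.name] = t
    records: list[R] = []
    for _, row in df.iterrows():
        kwargs = {f.name: _coerce(row[f.name], hints[f.name]) for f in fields if f.name in df.columns}
        records.append(record_type(**kwargs))
    return records
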
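"""Genome and annotation I/O plus assembly-level descriptors.

Genomes are held as :class:`GenomeRecord` (ordered contigs over the IUPAC
nucleotide alphabet); annotations as lists of :class:`GeneFeature` with
1-based inclusive GFF3 coordinates. Descriptors are the whole-assembly
summary statistics used for between-strain comparison: total length, contig
count, GC%, and per-base composition, with GC% and base fractions computed
over unambiguous (A/C/G/T) bases only so that runs of N do not dilute the
composition — the same stance the k-mer profiling takes toward ambiguity.

Two scalar similarity measures operate on these descriptors:

* ``size_similarity`` — 100 x min(L_a, L_b) / max(L_a, L_b);
* ``composition_similarity`` — 100 minus the mean absolute difference of the
  four base fractions (in percentage points).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from cyanokit.errors import DomainError, ParseError

IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeRecord:
    """An ordered collection of contigs, the substrate of all sequence work.

    Case is preserved as read; computations uppercase internally. Contig ids
    must be unique and sequences non-empty over the IUPAC nucleotide codes.
    """

    contigs: list[Contig]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("GenomeRecord requires at least one contig")
        seen: set[str] = set()
        for contig in self.contigs:
            if contig.id in seen:
                raise ValueError(f"duplicate contig id {contig.id!r}")
            seen.add(contig.id)
            if not contig.sequence:
                raise ValueError(f"contig {contig.id!r} has an empty sequence")
            bad = set(contig.sequence.upper()) - IUPAC_NUCLEOTIDES
            if bad:
                raise ValueError(
                    f"contig {contig.id!r} contains non-IUPAC characters: "
                    f"{', '.join(sorted(bad))}"
                )

    def __iter__(self):
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(f"no contig named {contig_id!r}")

    def contig_ids(self) -> list[str]:
        return [c.id for c in self.contigs]


@dataclass(frozen=True)
class GenomeDescriptors:
    """Assembly-level summary: length, contig count, GC%, base composition.

    ``base_fractions`` are percentages of the unambiguous base total and sum
    to 100; ``gc_percent`` equals fraction(G) + fraction(C) by construction.
    """

    total_length: int
    contig_count: int
    gc_percent: float
    base_fractions: dict[str, float]  # keys A, C, G, T; percent
    ambiguous_count: int


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature with 1-based inclusive coordinates.

    ``strand`` is "+" or "-"; ``gene_name``, ``product`` and ``locus_tag``
    may be empty strings when the annotation does not provide them.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    feature_type: str = "CDS"
    gene_name: str = ""
    product: str = ""
    locus_tag: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"require 1 <= start <= end, got start={self.start}, end={self.end}"
            )


def read_fasta(path: str | Path) -> GenomeRecord:
    """Read a (multi-record) FASTA file into a :class:`GenomeRecord`.

    The header token before the first whitespace becomes the contig id; the
    remainder is kept as the description. Raises :class:`ParseError` on an
    empty file, duplicate ids, or characters outside the IUPAC nucleotide
    alphabet (the error names the offending character and its line).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError("file not found", path=str(path))
    contigs: list[Contig] = []
    seen: set[str] = set()
    with path.open() as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in seen:
                raise ParseError(f"duplicate contig id {record.id!r}", path=str(path))
            seen.add(record.id)
            seq = str(record.seq)
            bad = set(seq.upper()) - IUPAC_NUCLEOTIDES
            if bad:
                char = sorted(bad)[0]
                raise ParseError(
                    f"non-IUPAC nucleotide character {char!r} in record "
                    f"{record.id!r} (line {_locate_char(path, record.id, bad)})",
                    path=str(path),
                )
            if not seq:
                raise ParseError(f"record {record.id!r} has an empty sequence", path=str(path))
            description = record.description
            if description.startswith(record.id):
                description = description[len(record.id):].strip()
            contigs.append(Contig(id=record.id, sequence=seq, description=description))
    if not contigs:
        raise ParseError("no FASTA records found", path=str(path))
    return GenomeRecord(contigs=contigs)


def _locate_char(path: Path, record_id: str, bad: set[str]) -> int:
    """Find the 1-based line of the first offending character within a record."""
    in_record = False
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(">"):
                token = line[1:].split()[0] if line[1:].split() else ""
                in_record = token == record_id
                continue
            if in_record and (set(line.strip().upper()) & bad):
                return lineno
    return 0


def write_fasta(genome: GenomeRecord, path: str | Path, width: int = 70) -> None:
    """Write a genome back to FASTA with fixed line wrapping (deterministic)."""
    path = Path(path)
    with path.open("w") as handle:
        for contig in genome:
            header = contig.id if not contig.description else f"{contig.id} {contig.description}"
            handle.write(f">{header}\n")
            seq = contig.sequence
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


_GFF_KEPT_TYPES = frozenset({"CDS", "gene"})


def read_gff(path: str | Path, feature_types: Iterable[str] = _GFF_KEPT_TYPES) -> list[GeneFeature]:
    """Read GFF3 features of the requested types (default CDS and gene).

    Coordinates stay 1-based inclusive per the GFF3 convention. The gene name
    is taken from the first of the ``gene``, ``Name``, ``locus_tag``
    attributes present; the product from ``product``. Malformed lines
    (wrong column count, end < start, unknown strand) raise
    :class:`ParseError` with the line number.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError("file not found", path=str(path))
    kept = set(feature_types)
    features: list[GeneFeature] = []
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"expected 9 tab-delimited columns, found {len(cols)}",
                    path=str(path),
                    line=lineno,
                )
            contig_id, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = cols
            if ftype not in kept:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", path=str(path), line=lineno)
            if end < start:
                raise ParseError(
                    f"end ({end}) precedes start ({start})", path=str(path), line=lineno
                )
            if strand not in ("+", "-"):
                raise ParseError(f"unknown strand symbol {strand!r}", path=str(path), line=lineno)
            attributes = _parse_attributes(attrs)
            gene_name = (
                attributes.get("gene")
                or attributes.get("Name")
                or attributes.get("locus_tag")
                or ""
            )
            features.append(
                GeneFeature(
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand=strand,
                    feature_type=ftype,
                    gene_name=gene_name,
                    product=attributes.get("product", ""),
                    locus_tag=attributes.get("locus_tag", ""),
                )
            )
    return features


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, value = part.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def write_gff(features: Iterable[GeneFeature], path: str | Path) -> None:
    """Write features as GFF3 (source column fixed to 'cyanokit')."""
    path = Path(path)
    with path.open("w") as handle:
        handle.write("##gff-version 3\n")
        for f in features:
            attrs = []
            if f.locus_tag:
                attrs.append(f"ID={f.locus_tag}")
                attrs.append(f"locus_tag={f.locus_tag}")
            if f.gene_name:
                attrs.append(f"gene={f.gene_name}")
            if f.product:
                attrs.append(f"product={f.product}")
            handle.write(
                "\t".join(
                    [
                        f.contig_id,
                        "cyanokit",
                        f.feature_type,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        "0",
                        ";".join(attrs) or ".",
                    ]
                )
                + "\n"
            )


def compute_descriptors(genome: GenomeRecord) -> GenomeDescriptors:
    """Compute assembly descriptors: length, contig count, GC%, composition.

    Counting is case-insensitive. GC% and base fractions use unambiguous
    bases (A/C/G/T) as the denominator; every other IUPAC code counts toward
    ``ambiguous_count`` only.
    """
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    ambiguous = 0
    total = 0
    for contig in genome:
        seq = contig.sequence.upper()
        total += len(seq)
        for base in counts:
            counts[base] += seq.count(base)
    ambiguous = total - sum(counts.values())
    unambiguous = sum(counts.values())
    if unambiguous == 0:
        fractions = {b: 0.0 for b in counts}
        gc = 0.0
    else:
        fractions = {b: 100.0 * n / unambiguous for b, n in counts.items()}
        gc = fractions["G"] + fractions["C"]
    return GenomeDescriptors(
        total_length=total,
        contig_count=len(genome),
        gc_percent=gc,
        base_fractions=fractions,
        ambiguous_count=ambiguous,
    )


def size_similarity(length_a: int, length_b: int) -> float:
    """Percent size similarity: 100 x min/max of the two assembly lengths."""
    if length_a <= 0 or length_b <= 0:
        raise DomainError("assembly lengths must be positive")
    return 100.0 * min(length_a, length_b) / max(length_a, length_b)


def composition_similarity(d_a: GenomeDescriptors, d_b: GenomeDescriptors) -> float:
    """Percent composition similarity from per-base fraction differences.

    Defined as 100 minus the mean absolute difference (in percentage points)
    of the A, C, G, T fractions; symmetric, and 100 exactly when the two
    compositions coincide.
    """
    diffs = [
        abs(d_a.base_fractions[b] - d_b.base_fractions[b]) for b in ("A", "C", "G", "T")
    ]
    return 100.0 - sum(diffs) / 4.0


def descriptors_table(named: dict[str, GenomeDescriptors]) -> "pandas.DataFrame":
    """Assemble a descriptor table (one row per genome) for TSV export."""
    import pandas as pd

    rows = []
    for genome_id, d in named.items():
        rows.append(
            {
                "genome_id": genome_id,
                "total_length": d.total_length,
                "contig_count": d.contig_count,
                "gc_percent": round(d.gc_percent, 4),
                "frac_A": round(d.base_fractions["A"], 4),
                "frac_C": round(d.base_fractions["C"], 4),
                "frac_G": round(d.base_fractions["G"], 4),
                "frac_T": round(d.base_fractions["T"], 4),
                "ambiguous_count": d.ambiguous_count,
            }
        )
    return pd.DataFrame(rows)
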
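"""I/O for the standard formats the pipeline touches, plus strand-aware
window extraction.

Coordinate conventions
----------------------
All coordinates are 0-based, half-open ``[start, end)`` internally (the BED
convention).  Tables using 1-based positions must be converted at the
boundary by the caller.  Sequences are handled as RNA (``A C G U``)
internally; DNA input is transcribed (``T`` -> ``U``) on read.

A CPA *site* is a single base: the cleavage position.  A window of flank
``f`` around a site spans ``[site - f, site + f)``, so the site base is the
first base of the downstream half.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = "ACGU"
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

SITES_TABLE_COLUMNS = ["chrom", "position", "strand", "gene_id", "pse", "mean_rpm"]


class SequenceIOError(ValueError):
    """Raised for malformed input files or out-of-bounds requests."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA sequence (A<->U, C<->G)."""
    return seq.translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a stranded chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be non-negative, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene represented by its longest-isoform pre-mRNA span.

    ``three_prime_utr``, when present, must be contained in ``span``.
    """

    gene_id: str
    span: GenomicInterval
    three_prime_utr: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.three_prime_utr is not None and not self.span.contains(
            self.three_prime_utr
        ):
            raise ValueError(
                f"3'UTR of {self.gene_id} not contained in its gene span"
            )


@dataclass(frozen=True)
class CPASite:
    """A cleavage-and-polyadenylation site with usage metadata.

    ``pse`` is the percentage of samples in which the site is expressed
    (0-100); ``mean_rpm`` the mean supporting reads per million.  The
    product ``pse * mean_rpm`` serves as a usage significance score used to
    pick the constitutive site of each gene.
    """

    gene_id: str
    position: GenomicInterval  # single base
    pse: float
    mean_rpm: float

    def __post_init__(self) -> None:
        if len(self.position) != 1:
            raise ValueError("CPA site position must be a single base")
        if not 0.0 <= self.pse <= 100.0:
            raise ValueError(f"PSE must be in [0, 100], got {self.pse}")
        if self.mean_rpm < 0:
            raise ValueError(f"mean RPM must be >= 0, got {self.mean_rpm}")

    @property
    def significance(self) -> float:
        return self.pse * self.mean_rpm

    @property
    def base(self) -> int:
        """0-based coordinate of the cleavage base."""
        return self.position.start


def read_fasta(path: str | Path | io.TextIOBase, rna: bool = True) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping.

    Sequences are uppercased; with ``rna=True`` (default) ``T`` is
    transcribed to ``U``.  Duplicate record ids and empty files are errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in records:
            raise SequenceIOError(f"duplicate FASTA id: {rec.id!r}")
        seq = str(rec.seq).upper()
        if rna:
            seq = seq.replace("T", "U")
        records[rec.id] = seq
    if not records:
        raise SequenceIOError(f"no FASTA records found in {path!r}")
    return records


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def extract_window(
    genome: Mapping[str, str], center: GenomicInterval, flank: int
) -> str:
    """Extract the ``2 * flank`` window around a single-base site.

    The returned sequence reads 5'->3' on the transcribed strand: minus
    strand requests are reverse-complemented.  On both strands the site base
    sits at offset ``flank`` of the result.  Windows that would run off the
    chromosome raise rather than clip.
    """
    if len(center) != 1:
        raise ValueError("center must be a single-base interval")
    try:
        chrom_seq = genome[center.chrom]
    except KeyError:
        raise SequenceIOError(f"chromosome {center.chrom!r} absent from genome") from None
    site = center.start
    if center.strand == "+":
        lo, hi = site - flank, site + flank
    else:
        # mirrored so that after reverse complementing the site base (as read
        # on the transcribed strand) lands at offset `flank`
        lo, hi = site - flank + 1, site + flank + 1
    if lo < 0 or hi > len(chrom_seq):
        raise SequenceIOError(
            f"window [{lo}, {hi}) around {center.chrom}:{site} exceeds "
            f"chromosome bounds [0, {len(chrom_seq)})"
        )
    window = chrom_seq[lo:hi]
    if center.strand == "-":
        window = reverse_complement(window)
    return window


def read_sites_table(path: str | Path) -> list[CPASite]:
    """Read a TSV of CPA sites (chrom, position, strand, gene_id, pse, mean_rpm).

    ``position`` is the 0-based cleavage base.  Raises on missing columns or
    PSE outside [0, 100].
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SITES_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SequenceIOError(f"sites table missing column(s): {', '.join(missing)}")
    sites = []
    for row in df.itertuples(index=False):
        try:
            site = CPASite(
                gene_id=str(row.gene_id),
                position=GenomicInterval(
                    str(row.chrom), int(row.position), int(row.position) + 1, str(row.strand)
                ),
                pse=float(row.pse),
                mean_rpm=float(row.mean_rpm),
            )
        except ValueError as exc:
            raise SequenceIOError(f"invalid site row {tuple(row)}: {exc}") from exc
        sites.append(site)
    return sites


def write_sites_table(sites: Iterable[CPASite], path: str | Path) -> None:
    rows = [
        {
            "chrom": s.position.chrom,
            "position": s.position.start,
            "strand": s.position.strand,
            "gene_id": s.gene_id,
            "pse": s.pse,
            "mean_rpm": s.mean_rpm,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=SITES_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_bed(path: str | Path) -> list[tuple[str, GenomicInterval]]:
    """Read a BED6 file into (name, interval) pairs."""
    out: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise SequenceIOError(
                    f"{path}:{line_no}: expected >= 6 BED columns, got {len(parts)}"
                )
            chrom, start, end, name, _score, strand = parts[:6]
            out.append((name, GenomicInterval(chrom, int(start), int(end), strand)))
    return out


def write_bed(
    entries: Iterable[tuple[str, GenomicInterval, float]], path: str | Path
) -> None:
    """Write (name, interval, score) triples as BED6."""
    with open(path, "w", newline="\n") as fh:
        for name, iv, score in entries:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


def read_gene_models(
    span_bed: str | Path, utr_bed: str | Path | None = None
) -> list[GeneModel]:
    """Assemble gene models from a span BED6 plus an optional 3'UTR BED6.

    UTR entries are matched to spans by name; genes without a UTR entry get
    ``three_prime_utr=None``.
    """
    spans = read_bed(span_bed)
    utrs: dict[str, GenomicInterval] = {}
    if utr_bed is not None:
        for name, iv in read_bed(utr_bed):
            utrs[name] = iv
    return [
        GeneModel(gene_id=name, span=iv, three_prime_utr=utrs.get(name))
        for name, iv in spans
    ]
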
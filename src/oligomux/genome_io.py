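"""Genome, annotation and signal-track I/O plus the shared coordinate model.

All coordinates inside the package are 0-based half-open (``[start, end)``).
GFF3 input (1-based inclusive) is converted on read; the manifest writers
re-apply the per-table printing conventions (see :mod:`oligomux.manifest_export`).

Soft-masked (lower-case) bases are upper-cased on read, but a per-base mask
is retained so probe mining can optionally skip masked regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval: 0-based start (inclusive), end (exclusive)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def to_gff3(self) -> tuple[int, int]:
        """Convert to GFF3 1-based inclusive (start, end)."""
        return self.start + 1, self.end

    @classmethod
    def from_gff3(cls, chrom: str, start: int, end: int) -> "GenomicInterval":
        """Build from GFF3 1-based inclusive coordinates."""
        return cls(chrom, start - 1, end)


class GenomeAssembly:
    """Ordered collection of named chromosome sequences.

    Sequences are stored upper-case over {A,C,G,T,N}; a boolean mask records
    which bases were soft-masked (lower-case) in the source FASTA.
    """

    def __init__(
        self,
        chromosomes: Mapping[str, str],
        masks: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        self.chromosomes: dict[str, str] = {}
        self.masks: dict[str, np.ndarray] = {}
        for name, seq in chromosomes.items():
            if name in self.chromosomes:
                raise ValueError(f"duplicate chromosome name {name!r}")
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            upper = seq.upper()
            bad = set(upper) - VALID_BASES
            if bad:
                raise ParseError(
                    f"chromosome {name!r} contains illegal character(s) "
                    f"{sorted(bad)}; allowed: A,C,G,T,N"
                )
            self.chromosomes[name] = upper
            if masks is not None and name in masks:
                mask = np.asarray(masks[name], dtype=bool)
                if mask.shape != (len(upper),):
                    raise ValueError(f"mask length mismatch for {name!r}")
            else:
                mask = np.fromiter(
                    (c.islower() for c in seq), dtype=bool, count=len(seq)
                )
            self.masks[name] = mask

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __len__(self) -> int:
        return len(self.chromosomes)

    def sequence(self, interval: GenomicInterval) -> str:
        """Plus-strand sequence of an interval, validated against lengths."""
        self.validate_interval(interval)
        return self.chromosomes[interval.chrom][interval.start : interval.end]

    def validate_interval(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self.chromosomes:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        length = len(self.chromosomes[interval.chrom])
        if interval.end > length:
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome length {length}"
            )


@dataclass
class SignalTrack:
    """Fixed-bin signal over one chromosome; NaN marks bins with no data."""

    chrom: str
    bin_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")

    @property
    def n_bins(self) -> int:
        return len(self.values)


@dataclass
class GeneAnnotation:
    """Gene records: (interval, unique identifier) pairs."""

    records: list[tuple[GenomicInterval, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for _, ident in self.records:
            if ident in seen:
                raise ParseError(f"duplicate gene identifier {ident!r}")
            seen.add(ident)

    def __len__(self) -> int:
        return len(self.records)


def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a FASTA file into a :class:`GenomeAssembly`.

    Sequences are upper-cased; characters outside A/C/G/T/N (after
    upper-casing) are rejected with an error naming the record and the
    offending character. Soft-masking is retained in the assembly masks.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header '>' "
                    f"before sequence data"
                )
            break
        else:
            raise ParseError(f"{path}: empty FASTA file")

    chromosomes: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chromosomes:
            raise ParseError(f"{path}: duplicate record name {record.id!r}")
        raw = str(record.seq)
        bad = set(raw.upper()) - VALID_BASES
        if bad:
            raise ParseError(
                f"{path}: record {record.id!r} contains illegal character "
                f"{sorted(bad)[0]!r}"
            )
        chromosomes[record.id] = raw
    return GenomeAssembly(chromosomes)


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 60) -> None:
    """Write an assembly as FASTA in assembly order, wrapped at `width` columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in assembly.chromosomes.items()
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(records)


def read_signal_track(
    path: str | Path,
    bin_size: int,
    lengths: Mapping[str, int],
) -> dict[str, SignalTrack]:
    """Read a bedGraph of fixed-bin values into per-chromosome tracks.

    Every interval must start on a bin boundary and span exactly one bin
    (the final bin of a chromosome may be short). Bins absent from the file
    are NaN (no data); a bin covered by more than one line is an error.
    """
    path = Path(path)
    tracks = {
        chrom: np.full(math.ceil(length / bin_size), np.nan)
        for chrom, length in lengths.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("track", "#", "browser")):
                continue
            fields = stripped.split("\t") if "\t" in stripped else stripped.split()
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 bedGraph fields")
            chrom, start_s, end_s, value_s = fields[:4]
            if chrom not in tracks:
                raise ParseError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            start, end = int(start_s), int(end_s)
            length = lengths[chrom]
            if start % bin_size != 0:
                raise ParseError(
                    f"{path}: line {lineno}: interval {start}-{end} not aligned "
                    f"to {bin_size}-bp bin grid"
                )
            expected_end = min(start + bin_size, length)
            if end != expected_end:
                raise ParseError(
                    f"{path}: line {lineno}: interval {start}-{end} must cover "
                    f"exactly one bin (expected end {expected_end})"
                )
            idx = start // bin_size
            if not np.isnan(tracks[chrom][idx]):
                raise ParseError(
                    f"{path}: line {lineno}: bin {idx} of {chrom} listed twice"
                )
            tracks[chrom][idx] = float(value_s)
    return {
        chrom: SignalTrack(chrom, bin_size, values) for chrom, values in tracks.items()
    }


def write_signal_track(
    tracks: Mapping[str, SignalTrack] | Iterable[SignalTrack],
    path: str | Path,
    lengths: Mapping[str, int],
) -> None:
    """Write tracks as bedGraph; NaN bins are omitted."""
    if isinstance(tracks, Mapping):
        tracks = list(tracks.values())
    with open(path, "w") as fh:
        for track in tracks:
            length = lengths[track.chrom]
            for i, value in enumerate(track.values):
                if np.isnan(value):
                    continue
                start = i * track.bin_size
                end = min(start + track.bin_size, length)
                fh.write(f"{track.chrom}\t{start}\t{end}\t{value:g}\n")


def _read_annotation_gff3(path: Path) -> list[tuple[GenomicInterval, str]]:
    import gffutils

    records: list[tuple[GenomicInterval, str]] = []
    for feature in gffutils.DataIterator(str(path)):
        if feature.featuretype != "gene":
            continue
        idents = feature.attributes.get("ID") or feature.attributes.get("gene_id")
        if not idents:
            raise ParseError(f"{path}: gene feature at {feature.seqid}:"
                             f"{feature.start} lacks an ID attribute")
        records.append(
            (GenomicInterval.from_gff3(feature.seqid, feature.start, feature.end),
             idents[0])
        )
    return records


def _read_annotation_bed(path: Path) -> list[tuple[GenomicInterval, str]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ParseError(f"{path}: BED requires at least 3 columns")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        name = str(row[3]) if df.shape[1] >= 4 else f"gene_{i}"
        records.append((GenomicInterval(row[0], int(row[1]), int(row[2])), name))
    return records


def read_annotation(
    path: str | Path,
    dialect: str = "gff3",
    lengths: Mapping[str, int] | None = None,
) -> GeneAnnotation:
    """Read gene records from GFF3 (features of type ``gene``) or BED.

    GFF3 coordinates are converted to the internal 0-based half-open
    convention; BED is taken as-is. With `lengths` supplied, intervals
    exceeding their chromosome raise an error.
    """
    path = Path(path)
    if dialect == "gff3":
        records = _read_annotation_gff3(path)
    elif dialect == "bed":
        records = _read_annotation_bed(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if lengths is not None:
        for interval, ident in records:
            if interval.chrom not in lengths:
                raise ParseError(f"{path}: gene {ident!r} on unknown chromosome "
                                 f"{interval.chrom!r}")
            if interval.end > lengths[interval.chrom]:
                raise ParseError(
                    f"{path}: gene {ident!r} interval {interval.chrom}:"
                    f"{interval.start}-{interval.end} exceeds chromosome length "
                    f"{lengths[interval.chrom]}"
                )
    return GeneAnnotation(records)
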
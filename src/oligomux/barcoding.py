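"""Orthogonal 20-bp barcode generation and primary-oligo assembly.

A primary oligo carries the 80-nt genomic homology flanked by two
whole-chromosome universal barcodes and up to two sub-chromosomal (stripe or
chromatin-state) barcodes, for a total of 120/140/160 nt. During PCR-based
library amplification, a secondary-oligo binding site is appended so that
fluorophore-bearing secondary oligos can be hybridized to the paint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .genome_io import reverse_complement
from .probe_mining import CandidateProbe, gc_fraction, max_homopolymer_run

BARCODE_LENGTH = 20
MAX_SUBLIBRARY_BARCODES = 2
MAX_PRIMARY_LENGTH = 160


class BarcodeRole(str, Enum):
    UNIVERSAL_5P = "universal_5p"
    UNIVERSAL_3P = "universal_3p"
    SUBLIBRARY = "sublibrary"


@dataclass(frozen=True)
class Barcode:
    """A 20-nt non-genomic index sequence."""

    id: str
    sequence: str
    role: BarcodeRole = BarcodeRole.SUBLIBRARY

    def __post_init__(self) -> None:
        if len(self.sequence) != BARCODE_LENGTH:
            raise ValueError(
                f"barcode {self.id!r} must be exactly {BARCODE_LENGTH} nt, "
                f"got {len(self.sequence)}"
            )
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"barcode {self.id!r} contains non-ACGT characters")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


class BarcodeGenerationError(RuntimeError):
    pass


def generate_barcodes(
    n: int,
    length: int = BARCODE_LENGTH,
    min_hamming: int = 8,
    gc_range: tuple[float, float] = (0.25, 0.75),
    max_homopolymer: int = 4,
    seed: int = 0,
    max_attempts: int | None = None,
    role: BarcodeRole = BarcodeRole.SUBLIBRARY,
) -> list[Barcode]:
    """Rejection-sample `n` mutually orthogonal barcodes, deterministic per seed.

    Orthogonality: pairwise Hamming distance >= `min_hamming` over all pairs,
    including every pair (b_i, reverse_complement(b_j)) — i = j included, so a
    barcode is also held away from its own reverse complement. Candidates must
    satisfy the GC range and homopolymer cap.

    Raises :class:`BarcodeGenerationError` when the attempt budget (default
    20000 * n draws) is exhausted, reporting how many barcodes were found.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if min_hamming > length:
        raise ValueError("min_hamming cannot exceed barcode length")
    if max_attempts is None:
        max_attempts = 20_000 * n
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    accepted: list[str] = []
    attempts = 0
    while len(accepted) < n and attempts < max_attempts:
        attempts += 1
        cand = "".join(bases[rng.integers(0, 4, size=length)])
        gc = gc_fraction(cand)
        if not (gc_range[0] <= gc <= gc_range[1]):
            continue
        if max_homopolymer_run(cand) > max_homopolymer:
            continue
        rc_cand = reverse_complement(cand)
        if hamming(cand, rc_cand) < min_hamming:
            continue
        ok = True
        for prev in accepted:
            if (
                hamming(cand, prev) < min_hamming
                or hamming(cand, reverse_complement(prev)) < min_hamming
                or hamming(rc_cand, prev) < min_hamming
            ):
                ok = False
                break
        if ok:
            accepted.append(cand)
    if len(accepted) < n:
        raise BarcodeGenerationError(
            f"could not find {n} barcodes of length {length} with "
            f"min_hamming={min_hamming} within {max_attempts} attempts; "
            f"found {len(accepted)}"
        )
    if length != BARCODE_LENGTH:
        # Barcode type enforces the standard 20-nt length; shorter/longer
        # experimental sets are returned as plain records.
        return [
            _RelaxedBarcode(id=f"bc{i:03d}", sequence=s, role=role)
            for i, s in enumerate(accepted)
        ]
    return [Barcode(id=f"bc{i:03d}", sequence=s, role=role) for i, s in enumerate(accepted)]


@dataclass(frozen=True)
class _RelaxedBarcode:
    """Barcode-shaped record for non-standard lengths (testing/exploration)."""

    id: str
    sequence: str
    role: BarcodeRole = BarcodeRole.SUBLIBRARY


@dataclass(frozen=True)
class OligoSegment:
    role: str                   # universal_5p | sublibrary | homology | universal_3p
    name: str
    sequence: str


@dataclass(frozen=True)
class PrimaryOligo:
    """An orderable oligo: homology flanked by universal and sub-library barcodes."""

    probe: CandidateProbe
    layout: tuple[OligoSegment, ...]

    @property
    def sequence(self) -> str:
        return "".join(seg.sequence for seg in self.layout)

    @property
    def length(self) -> int:
        return sum(len(seg.sequence) for seg in self.layout)

    @property
    def sublibrary_barcodes(self) -> tuple[str, ...]:
        return tuple(seg.name for seg in self.layout if seg.role == "sublibrary")

    def __post_init__(self) -> None:
        if self.length > MAX_PRIMARY_LENGTH:
            raise ValueError(
                f"primary oligo length {self.length} exceeds {MAX_PRIMARY_LENGTH} nt"
            )


@dataclass(frozen=True)
class AmplifiedOligo:
    """A primary oligo with the secondary-oligo binding site appended by PCR."""

    primary: PrimaryOligo
    secondary_site: str
    full_sequence: str

    def __post_init__(self) -> None:
        if self.primary.sequence not in self.full_sequence:
            raise ValueError("full_sequence must contain the primary sequence")


def assemble_primary(
    probe: CandidateProbe,
    universal_pair: tuple[Barcode, Barcode],
    sublibrary_barcodes: Sequence[Barcode] = (),
) -> PrimaryOligo:
    """Assemble one primary oligo.

    Layout: universal_5p | sub1? | homology | sub2? | universal_3p. A single
    sub-library barcode is placed 5' of the homology (the symmetric choice is
    configurable upstream by passing it second alongside an explicit first
    barcode); more than two sub-library barcodes is an error.
    """
    if len(sublibrary_barcodes) > MAX_SUBLIBRARY_BARCODES:
        raise ValueError(
            f"at most {MAX_SUBLIBRARY_BARCODES} sub-library barcodes allowed, "
            f"got {len(sublibrary_barcodes)}"
        )
    u5, u3 = universal_pair
    for bc in (u5, u3, *sublibrary_barcodes):
        if len(bc.sequence) != BARCODE_LENGTH:
            raise ValueError(f"barcode {bc.id!r} is not {BARCODE_LENGTH} nt")
    segments = [OligoSegment("universal_5p", u5.id, u5.sequence)]
    if len(sublibrary_barcodes) >= 1:
        bc = sublibrary_barcodes[0]
        segments.append(OligoSegment("sublibrary", bc.id, bc.sequence))
    segments.append(
        OligoSegment("homology", _probe_name(probe), probe.sequence)
    )
    if len(sublibrary_barcodes) == 2:
        bc = sublibrary_barcodes[1]
        segments.append(OligoSegment("sublibrary", bc.id, bc.sequence))
    segments.append(OligoSegment("universal_3p", u3.id, u3.sequence))
    return PrimaryOligo(probe=probe, layout=tuple(segments))


def _probe_name(probe: CandidateProbe) -> str:
    iv = probe.interval
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def assemble_library(
    probes: Iterable[CandidateProbe],
    universal_pair: tuple[Barcode, Barcode],
    assignments: dict | None = None,
) -> list[PrimaryOligo]:
    """Assemble primary oligos for a probe set.

    `assignments` maps a probe's interval to its sub-library barcodes
    (0–2 each); probes without an entry get only the universal pair. Each
    barcode is checked against every homology region: a barcode occurring as
    an exact substring of any homology sequence voids orthogonality and is
    an error.
    """
    probes = list(probes)
    assignments = assignments or {}
    all_barcodes: dict[str, Barcode] = {
        universal_pair[0].id: universal_pair[0],
        universal_pair[1].id: universal_pair[1],
    }
    for subs in assignments.values():
        for bc in subs:
            all_barcodes[bc.id] = bc
    for bc in all_barcodes.values():
        for probe in probes:
            if bc.sequence in probe.sequence or (
                reverse_complement(bc.sequence) in probe.sequence
            ):
                raise ValueError(
                    f"barcode {bc.id!r} occurs within homology sequence at "
                    f"{_probe_name(probe)}; regenerate barcodes"
                )
    return [
        assemble_primary(p, universal_pair, tuple(assignments.get(p.interval, ())))
        for p in probes
    ]


def select_by_barcode(library: Sequence[PrimaryOligo], barcode_id: str) -> list[PrimaryOligo]:
    """Oligos carrying the given sub-library barcode (PCR selection model)."""
    return [o for o in library if barcode_id in o.sublibrary_barcodes]


def emit_amplification_primers(
    library: Sequence[PrimaryOligo],
    sublibrary_barcode: Barcode,
    secondary_site: str,
) -> tuple[str, str, list[AmplifiedOligo]]:
    """Model the barcode-selective PCR that appends the secondary-oligo site.

    Returns (forward_primer, reverse_primer, amplified oligos). The forward
    primer is the sub-library barcode itself; the reverse primer is the
    reverse complement of the universal 3' barcode with the secondary-oligo
    binding site appended 5', so each product gains the reverse complement of
    the secondary site at its 3' end.
    """
    selected = select_by_barcode(library, sublibrary_barcode.id)
    if not selected:
        available = sorted({b for o in library for b in o.sublibrary_barcodes})
        raise ValueError(
            f"barcode {sublibrary_barcode.id!r} not present in library; "
            f"available sub-library barcodes: {available or 'none'}"
        )
    u3 = selected[0].layout[-1]
    forward = sublibrary_barcode.sequence
    reverse = secondary_site + reverse_complement(u3.sequence)
    amplified = [
        AmplifiedOligo(
            primary=o,
            secondary_site=secondary_site,
            full_sequence=o.sequence + reverse_complement(secondary_site),
        )
        for o in selected
    ]
    return forward, reverse, amplified
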
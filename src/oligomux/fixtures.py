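"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emulate the study's real inputs at desk scale: genomes with
planted exact repeats (where no unique probe can exist), 10-kb windowed
ChIP-like tracks with planted active/inactive domains, and multinomial
cytological count tables. Each generator draws from an independent
substream of a master seed keyed by the generator's name, so adding a
generator never perturbs another's output.

Default synthetic scale is 2 chromosomes x 500 kb with 10-kb bins: large
enough to exercise 50-kb windowing and stripe logic, small enough for
sub-second tests.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import GenomeAssembly, GenomicInterval, SignalTrack
from .sublibraries import ChromatinDomain, STATE_ACTIVE, STATE_INACTIVE

_BASES = np.array(list("ACGT"))


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Independent RNG substream for (master seed, generator name)."""
    return np.random.default_rng([master_seed, zlib.crc32(name.encode()) & 0x7FFFFFFF])


@dataclass(frozen=True)
class RepeatSpec:
    """One repeat unit pasted verbatim at several positions."""

    unit_length: int
    positions: tuple[tuple[str, int], ...]   # (chrom, 0-based insertion offset)


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 500_000, "chr2": 500_000}
    )
    gc: float = 0.4
    repeats: tuple[RepeatSpec, ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class SyntheticTrackSpec:
    """Planted active/inactive domains rendered as a noisy binned signal.

    Defaults give a 4:1 signal-to-noise ratio: state means +/-2.0 around a
    zero threshold with additive Gaussian noise of SD 0.5 per 10-kb bin.
    """

    chrom: str = "chr1"
    length: int = 500_000
    domains: tuple[tuple[int, int, str], ...] = ()   # (start, end, state), tiling
    positive_mean: float = 2.0    # CENP-T enriched = inactive
    negative_mean: float = -2.0   # CENP-T depleted = active
    noise_sd: float = 0.5
    bin_size: int = 10_000
    seed: int = 0


def make_genome(spec: SyntheticGenomeSpec) -> tuple[GenomeAssembly, list[GenomicInterval]]:
    """Random genome with planted exact repeats.

    Returns the assembly plus the truth record: the interval of every repeat
    copy (no probe lying wholly inside any of them can be genome-unique).
    Overlapping repeat insertions are an error.
    """
    if not (0 < spec.gc < 1):
        raise ValueError("gc must be in (0, 1)")
    rng = substream(spec.seed, "genome")
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    chroms: dict[str, np.ndarray] = {
        name: rng.choice(4, size=length, p=p)
        for name, length in spec.lengths.items()
    }
    truth: list[GenomicInterval] = []
    for rep in spec.repeats:
        for chrom, pos in rep.positions:
            if chrom not in chroms:
                raise ValueError(f"repeat position on unknown chromosome {chrom!r}")
            if pos < 0 or pos + rep.unit_length > len(chroms[chrom]):
                raise ValueError("repeat does not fit within its chromosome")
            truth.append(GenomicInterval(chrom, pos, pos + rep.unit_length))
    for i, a in enumerate(truth):
        for b in truth[i + 1 :]:
            if a.overlaps(b):
                raise ValueError(f"overlapping repeat insertions: {a} and {b}")
    for rep in spec.repeats:
        unit = rng.choice(4, size=rep.unit_length, p=p)
        for chrom, pos in rep.positions:
            chroms[chrom][pos : pos + rep.unit_length] = unit
    assembly = GenomeAssembly(
        {name: "".join(_BASES[codes]) for name, codes in chroms.items()}
    )
    return assembly, truth


def make_track(spec: SyntheticTrackSpec) -> tuple[SignalTrack, list[ChromatinDomain]]:
    """Noisy binned signal around planted state means, plus the truth domains.

    Domains must tile [0, length); inactive domains take `positive_mean`
    (CENP-T enriched), active take `negative_mean`, and seeded Gaussian
    noise is added per bin.
    """
    domains = spec.domains
    if not domains:
        raise ValueError("spec.domains must tile the chromosome")
    cursor = 0
    truth: list[ChromatinDomain] = []
    for start, end, state in domains:
        if start != cursor:
            raise ValueError(f"domains must tile the chromosome; gap at {cursor}")
        if state not in (STATE_ACTIVE, STATE_INACTIVE):
            raise ValueError(f"unknown state {state!r}")
        truth.append(ChromatinDomain(GenomicInterval(spec.chrom, start, end), state))
        cursor = end
    if cursor != spec.length:
        raise ValueError("domains must end at the chromosome length")
    if spec.positive_mean == spec.negative_mean:
        warnings.warn(
            "positive and negative means are equal; planted states are "
            "unidentifiable from the signal",
            stacklevel=2,
        )
    rng = substream(spec.seed, "track")
    n_bins = -(-spec.length // spec.bin_size)
    values = np.empty(n_bins)
    for i in range(n_bins):
        mid = min(i * spec.bin_size + spec.bin_size // 2, spec.length - 1)
        state = next(d.state for d in truth if d.interval.start <= mid < d.interval.end)
        mean = spec.positive_mean if state == STATE_INACTIVE else spec.negative_mean
        values[i] = mean
    values += rng.normal(0.0, spec.noise_sd, size=n_bins)
    return SignalTrack(spec.chrom, spec.bin_size, values), truth


def boundary_recovery(
    called: list[ChromatinDomain],
    truth: list[ChromatinDomain],
    tolerance: int = 50_000,
) -> float:
    """Fraction of true internal state boundaries recovered within `tolerance`.

    A truth boundary is a position where the planted state changes; it counts
    as recovered when some called internal boundary lies within `tolerance`
    bp. Returns 1.0 trivially when the truth has no internal boundary.
    """
    def internal_boundaries(doms: list[ChromatinDomain]) -> list[int]:
        doms = sorted(doms, key=lambda d: d.interval)
        return [d.interval.end for d in doms[:-1]]

    true_b = internal_boundaries(truth)
    if not true_b:
        return 1.0
    called_b = internal_boundaries(called)
    hits = sum(
        1 for tb in true_b if any(abs(tb - cb) <= tolerance for cb in called_b)
    )
    return hits / len(true_b)


def make_counts(
    probabilities,
    n_cells: int,
    n_replicates: int = 1,
    seed: int = 0,
    categories: list[str] | None = None,
) -> pd.DataFrame:
    """Multinomial cytological count tables, one row per replicate."""
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 1 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("probabilities must be non-negative and sum to 1")
    if categories is None:
        categories = [f"category_{i}" for i in range(len(p))]
    rng = substream(seed, "counts")
    draws = rng.multinomial(n_cells, p, size=n_replicates)
    return pd.DataFrame(draws, columns=categories)
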
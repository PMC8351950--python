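"""Partitioning chromosome paints into stripe and chromatin-state sub-libraries.

Stripe schemes label the first (tel1), middle (mid) and last (tel2) segment
of a paint. Chromatin-state schemes derive from windowed CENP-T ChIP signal:
the 10-kb input track is averaged over 50-kb windows, windows above the
threshold are CENP-T enriched (transcriptionally inactive), windows at or
below it are CENP-T depleted (active), and the negative set is subtracted
from the positive set to give the final inactive domains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genome_io import GeneAnnotation, GenomicInterval, SignalTrack
from .probe_mining import CandidateProbe

STATE_ACTIVE = "active"
STATE_INACTIVE = "inactive"


@dataclass(frozen=True)
class StripeScheme:
    """First/middle/last stripe partition of one chromosome paint."""

    chrom: str
    tel1: GenomicInterval
    mid: GenomicInterval
    tel2: GenomicInterval
    nominal_size: int

    def __post_init__(self) -> None:
        for iv in (self.tel1, self.mid, self.tel2):
            if iv.chrom != self.chrom:
                raise ValueError("stripe intervals must share the scheme chromosome")
        if not (self.tel1.end <= self.mid.start and self.mid.end <= self.tel2.start):
            raise ValueError("stripes must be disjoint and ordered tel1 < mid < tel2")
        for name, iv in self.items():
            if abs(iv.length - self.nominal_size) > 0.15 * self.nominal_size:
                raise ValueError(
                    f"stripe {name} size {iv.length} deviates more than 15% "
                    f"from nominal {self.nominal_size}"
                )

    def items(self) -> list[tuple[str, GenomicInterval]]:
        return [("tel1", self.tel1), ("mid", self.mid), ("tel2", self.tel2)]


@dataclass(frozen=True)
class ChromatinDomain:
    """A contiguous active (CENP-T depleted) or inactive (enriched) domain."""

    interval: GenomicInterval
    state: str

    def __post_init__(self) -> None:
        if self.state not in (STATE_ACTIVE, STATE_INACTIVE):
            raise ValueError(f"unknown chromatin state {self.state!r}")


@dataclass(frozen=True)
class DomainCallParams:
    """Windowing and thresholding for CENP-T domain calling.

    `threshold` separates CENP-T-positive from negative 50-kb windows; the
    default 0 suits a log2-enrichment-like signal and should be set
    explicitly for other signal scales. `min_run` is the minimum run of
    like-signed windows kept as a domain.
    """

    in_bin: int = 10_000
    out_window: int = 50_000
    threshold: float = 0.0
    min_run: int = 1

    def __post_init__(self) -> None:
        if self.out_window % self.in_bin != 0:
            raise ValueError("out_window must be an integer multiple of in_bin")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")


def define_stripes(
    paint: GenomicInterval,
    nominal_size: int | None = None,
    probes: Sequence[CandidateProbe] | None = None,
    explicit: tuple[GenomicInterval, GenomicInterval, GenomicInterval] | None = None,
) -> StripeScheme:
    """Build a tel1/mid/tel2 stripe scheme over a paint.

    With `explicit` intervals they pass through unmodified (nominal defaults
    to their mean size). Otherwise tel1 is anchored at the paint start, tel2
    at the paint end, and mid is centered on the paint midpoint; when probes
    are supplied every internal boundary is snapped to the nearest probe
    start/end so stripes never split a probe.
    """
    if explicit is not None:
        tel1, mid, tel2 = explicit
        if tel1.start != paint.start:
            raise ValueError("tel1 must be anchored at the paint start")
        if tel2.end != paint.end:
            raise ValueError("tel2 must end at the paint end")
        if nominal_size is None:
            nominal_size = round((tel1.length + mid.length + tel2.length) / 3)
        return StripeScheme(paint.chrom, tel1, mid, tel2, nominal_size)

    if nominal_size is None:
        raise ValueError("nominal_size is required for automatic placement")
    if paint.length < 3 * nominal_size:
        raise ValueError(
            f"paint length {paint.length} is too short for three "
            f"{nominal_size}-bp stripes (minimum {3 * nominal_size})"
        )
    boundaries = None
    if probes:
        boundaries = sorted(
            {p.interval.start for p in probes} | {p.interval.end for p in probes}
        )

    def snap(pos: int) -> int:
        if not boundaries:
            return pos
        idx = int(np.searchsorted(boundaries, pos))
        best = min(
            (b for b in boundaries[max(0, idx - 1) : idx + 1]),
            key=lambda b: (abs(b - pos), b),
            default=pos,
        )
        return best

    tel1 = GenomicInterval(paint.chrom, paint.start, snap(paint.start + nominal_size))
    tel2 = GenomicInterval(paint.chrom, snap(paint.end - nominal_size), paint.end)
    center = (paint.start + paint.end) // 2
    mid = GenomicInterval(
        paint.chrom, snap(center - nominal_size // 2), snap(center + (nominal_size + 1) // 2)
    )
    return StripeScheme(paint.chrom, tel1, mid, tel2, nominal_size)


def average_track(track: SignalTrack, params: DomainCallParams = DomainCallParams()) -> SignalTrack:
    """Average an in_bin-resolution track over out_window windows.

    No-data (NaN) bins are ignored within a window; a window with all bins
    missing stays NaN. A trailing partial window averages its available bins.
    """
    if track.bin_size != params.in_bin:
        raise ValueError(
            f"track bin_size {track.bin_size} does not match params.in_bin "
            f"{params.in_bin}"
        )
    factor = params.out_window // params.in_bin
    values = track.values
    n_out = -(-len(values) // factor)
    padded = np.full(n_out * factor, np.nan)
    padded[: len(values)] = values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        means = np.nanmean(padded.reshape(n_out, factor), axis=1)
    return SignalTrack(track.chrom, params.out_window, means)


def _runs_to_intervals(
    chrom: str,
    flags: np.ndarray,
    window: int,
    min_run: int,
    chrom_len: int,
) -> list[GenomicInterval]:
    intervals: list[GenomicInterval] = []
    i = 0
    n = len(flags)
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j < n and flags[j]:
            j += 1
        if j - i >= min_run:
            intervals.append(
                GenomicInterval(chrom, i * window, min(j * window, chrom_len))
            )
        i = j
    return intervals


def _subtract(
    minuend: list[GenomicInterval], subtrahend: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Set difference of two sorted disjoint interval lists on one chromosome."""
    result: list[GenomicInterval] = []
    for iv in minuend:
        pieces = [(iv.start, iv.end)]
        for sub in subtrahend:
            if sub.end <= iv.start or sub.start >= iv.end:
                continue
            new_pieces = []
            for s, e in pieces:
                if sub.end <= s or sub.start >= e:
                    new_pieces.append((s, e))
                    continue
                if sub.start > s:
                    new_pieces.append((s, sub.start))
                if sub.end < e:
                    new_pieces.append((sub.end, e))
            pieces = new_pieces
        result.extend(GenomicInterval(iv.chrom, s, e) for s, e in pieces)
    return sorted(result)


def call_domains(
    avg_track: SignalTrack,
    paint: GenomicInterval,
    params: DomainCallParams = DomainCallParams(),
) -> list[ChromatinDomain]:
    """Call active/inactive chromatin domains from a window-averaged track.

    Windows with value > threshold are CENP-T positive (inactive chromatin);
    windows <= threshold are negative. Runs of at least `min_run` like
    windows become domains; the negative set is subtracted from the positive
    set to give the inactive domains and the negative set itself gives the
    active domains. Domains are clipped to the paint; an edge domain whose
    boundary window contains the paint edge is extended to the exact paint
    coordinate (matching probe-level paint edges). No-data windows belong to
    neither state and leave gaps.
    """
    if avg_track.bin_size != params.out_window:
        raise ValueError("avg_track must be at out_window resolution")
    values = avg_track.values
    if len(values) == 0 or np.all(np.isnan(values)):
        raise ValueError("cannot call domains on an empty track")
    with_data = ~np.isnan(values)
    positive = with_data & (values > params.threshold)
    negative = with_data & (values <= params.threshold)
    window = params.out_window
    chrom_len_proxy = len(values) * window
    pos_iv = _runs_to_intervals(
        avg_track.chrom, positive, window, params.min_run, chrom_len_proxy
    )
    neg_iv = _runs_to_intervals(
        avg_track.chrom, negative, window, params.min_run, chrom_len_proxy
    )
    inactive = _subtract(pos_iv, neg_iv)
    active = neg_iv

    domains = sorted(
        [ChromatinDomain(iv, STATE_INACTIVE) for iv in inactive]
        + [ChromatinDomain(iv, STATE_ACTIVE) for iv in active],
        key=lambda d: d.interval,
    )
    # clip to the paint
    clipped: list[ChromatinDomain] = []
    for dom in domains:
        s = max(dom.interval.start, paint.start)
        e = min(dom.interval.end, paint.end)
        if s < e:
            clipped.append(
                ChromatinDomain(GenomicInterval(paint.chrom, s, e), dom.state)
            )
    if not clipped:
        raise ValueError("no domains overlap the paint")
    # Edge behavior falls out of clipping: when the window containing a paint
    # edge has data, its window-aligned domain is clipped to the exact paint
    # coordinate; when it is no-data, the gap is preserved.
    # merge adjacent like-state domains (subtraction can split runs)
    merged: list[ChromatinDomain] = []
    for dom in clipped:
        if (
            merged
            and merged[-1].state == dom.state
            and merged[-1].interval.end == dom.interval.start
        ):
            merged[-1] = ChromatinDomain(
                GenomicInterval(
                    paint.chrom, merged[-1].interval.start, dom.interval.end
                ),
                dom.state,
            )
        else:
            merged.append(dom)
    return merged


@dataclass
class ProbeAssignment:
    """Probes per partition element plus those that fell in gaps or straddled."""

    assigned: dict[str, list[CandidateProbe]]
    unassigned: list[CandidateProbe]

    @property
    def straddle_count(self) -> int:
        return len(self.unassigned)


def _partition_elements(
    partition: StripeScheme | Sequence[ChromatinDomain],
) -> list[tuple[str, GenomicInterval]]:
    if isinstance(partition, StripeScheme):
        return partition.items()
    return [
        (f"{dom.state}:{dom.interval.start + 1}-{dom.interval.end}", dom.interval)
        for dom in partition
    ]


def assign_probes(
    probes: Sequence[CandidateProbe],
    partition: StripeScheme | Sequence[ChromatinDomain],
) -> ProbeAssignment:
    """Assign each probe to the partition element that fully contains it.

    Probes straddling a boundary or lying in gaps are unassigned. Assignment
    depends only on coordinates, so permuting the input order does not change
    the result (output lists are coordinate-sorted).
    """
    elements = _partition_elements(partition)
    assigned: dict[str, list[CandidateProbe]] = {name: [] for name, _ in elements}
    unassigned: list[CandidateProbe] = []
    for probe in sorted(probes, key=lambda p: p.interval):
        for name, iv in elements:
            if iv.contains(probe.interval):
                assigned[name].append(probe)
                break
        else:
            unassigned.append(probe)
    return ProbeAssignment(assigned=assigned, unassigned=unassigned)


def gene_density(annotation: GeneAnnotation, interval: GenomicInterval) -> float:
    """Genes per Mb: count of gene midpoints inside the interval / length in Mb.

    Midpoint membership (rather than any-overlap) makes densities additive
    across a partition.
    """
    if interval.length <= 0:
        raise ValueError("interval length must be positive")
    count = sum(
        1
        for iv, _ in annotation.records
        if iv.chrom == interval.chrom and interval.start <= iv.midpoint < interval.end
    )
    return count / (interval.length / 1e6)


def stripe_gene_ratio(annotation: GeneAnnotation, scheme: StripeScheme) -> float:
    """tel1:tel2 gene-density ratio of a stripe scheme."""
    d2 = gene_density(annotation, scheme.tel2)
    if d2 == 0:
        raise ValueError("tel2 gene density is zero; ratio undefined")
    return gene_density(annotation, scheme.tel1) / d2
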
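"""Library manifests and order-ready output files.

Two size conventions coexist in the published tables and are reproduced
explicitly rather than unified: the whole-chromosome paint manifest reports
``size_painted = paint_stop - paint_start`` on the printed (1-based)
coordinates, while the chromatin-domain report uses
``size = stop - start + 1``. Each writer names its convention in a header
comment. Stripe sizes in Mb are rendered at two decimals with round-half-even
by default; a truncation mode exists because some published cells only match
under truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_DOWN, ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .barcoding import PrimaryOligo
from .genome_io import GenomicInterval
from .probe_mining import CandidateProbe
from .sublibraries import ChromatinDomain, StripeScheme


@dataclass
class PaintLibrary:
    """One chromosome's paint: probes, assembled oligos and metadata."""

    chrom: str
    chrom_size: int
    paint: GenomicInterval
    nominal_density: float
    probes: list[CandidateProbe] = field(default_factory=list)
    oligos: list[PrimaryOligo] = field(default_factory=list)
    gene_density: float | None = None

    @property
    def total_oligos(self) -> int:
        return len(self.oligos) if self.oligos else len(self.probes)

    @property
    def achieved_density(self) -> float:
        return self.total_oligos / (self.paint.length / 1000.0)


def summarize(libraries: Sequence[PaintLibrary]) -> pd.DataFrame:
    """Per-chromosome manifest mirroring the whole-chromosome paint table.

    Printed coordinates are 1-based; ``size_painted_bp`` is computed as
    paint_stop − paint_start on those printed values (the published
    convention), which equals the internal interval length minus one.
    """
    rows = []
    for lib in libraries:
        if lib.total_oligos < 1:
            raise ValueError(f"library for {lib.chrom!r} has no probes")
        start_printed = lib.paint.start + 1
        stop_printed = lib.paint.end
        rows.append(
            {
                "chrom": lib.chrom,
                "chromosome_size_bp": lib.chrom_size,
                "size_painted_bp": stop_printed - start_printed,
                "paint_start": start_printed,
                "paint_stop": stop_printed,
                "density_probes_per_kb": lib.nominal_density,
                "achieved_density_probes_per_kb": round(lib.achieved_density, 3),
                "total_oligos": lib.total_oligos,
                "gene_density_per_mb": lib.gene_density,
            }
        )
    return pd.DataFrame(rows)


def format_stripe_size(start: int, stop: int, mode: str = "round") -> str:
    """Stripe size in Mb at two decimals from printed 1-based coordinates.

    ``mode='round'`` uses round-half-even; ``mode='trunc'`` truncates toward
    zero. The published table mixes both conventions, so both are offered.
    """
    if stop <= start:
        raise ValueError("stop must exceed start")
    mb = Decimal(stop - start) / Decimal(10**6)
    rounding = {"round": ROUND_HALF_EVEN, "trunc": ROUND_DOWN}[mode]
    return str(mb.quantize(Decimal("0.01"), rounding=rounding))


def domain_report(domains: Sequence[ChromatinDomain]) -> pd.DataFrame:
    """Domain report mirroring the published chromatin-domain tables.

    Printed coordinates are 1-based inclusive; ``size = stop - start + 1``
    equals the internal interval length.
    """
    rows = []
    for dom in domains:
        start_printed = dom.interval.start + 1
        stop_printed = dom.interval.end
        rows.append(
            {
                "domain": dom.state,
                "start": start_printed,
                "stop": stop_printed,
                "size": stop_printed - start_printed + 1,
            }
        )
    return pd.DataFrame(rows)


def probes_to_bed(probes: Sequence[CandidateProbe]) -> pd.DataFrame:
    """Probe set as BED6 records (score = Tm x 10, integer)."""
    return pd.DataFrame(
        {
            "chrom": [p.interval.chrom for p in probes],
            "start": [p.interval.start for p in probes],
            "end": [p.interval.end for p in probes],
            "name": [f"{p.interval.chrom}:{p.interval.start}-{p.interval.end}"
                     for p in probes],
            "score": [int(round(p.tm * 10)) for p in probes],
            "strand": ["+"] * len(probes),
        }
    )


def probes_from_bed(path: str | Path, assembly) -> list[CandidateProbe]:
    """Re-hydrate a probe set from BED6 against its assembly."""
    from .probe_mining import compute_tm, gc_fraction

    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    probes = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        seq = assembly.sequence(iv)
        probes.append(
            CandidateProbe(iv, seq, gc_fraction(seq), compute_tm(seq), unique=True)
        )
    return probes


def order_sheet(oligos: Sequence[PrimaryOligo]) -> pd.DataFrame:
    """Synthesis order sheet: one row per primary oligo."""
    rows = []
    for i, oligo in enumerate(oligos):
        iv = oligo.probe.interval
        rows.append(
            {
                "id": f"oligo_{i:06d}",
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "layout": "|".join(f"{seg.role}={seg.name}" for seg in oligo.layout),
                "full_sequence": oligo.sequence,
            }
        )
    return pd.DataFrame(rows)


def partition_to_bed(
    partition: StripeScheme | Sequence[ChromatinDomain],
) -> pd.DataFrame:
    """Partition as BED4 (name = tel1/mid/tel2 or active/inactive)."""
    if isinstance(partition, StripeScheme):
        items = partition.items()
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for _, iv in items],
                "start": [iv.start for _, iv in items],
                "end": [iv.end for _, iv in items],
                "name": [name for name, _ in items],
            }
        )
    return pd.DataFrame(
        {
            "chrom": [d.interval.chrom for d in partition],
            "start": [d.interval.start for d in partition],
            "end": [d.interval.end for d in partition],
            "name": [d.state for d in partition],
        }
    )


def write_outputs(
    library: PaintLibrary,
    out_prefix: str | Path,
    partitions: Mapping[str, StripeScheme | Sequence[ChromatinDomain]] | None = None,
    run_config: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write all deliverables for one paint library, byte-deterministically.

    Emits: probe BED6, homology FASTA, order TSV (when oligos are
    assembled), manifest TSV, one partition BED + domain report per named
    partition, and a plain key=value run-config record.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    bed_path = Path(f"{out_prefix}.probes.bed")
    probes_to_bed(library.probes).to_csv(bed_path, sep="\t", header=False, index=False)
    written["probes_bed"] = bed_path

    fasta_path = Path(f"{out_prefix}.homology.fa")
    with open(fasta_path, "w") as fh:
        for p in library.probes:
            iv = p.interval
            fh.write(f">{iv.chrom}:{iv.start}-{iv.end}\n{p.sequence}\n")
    written["homology_fasta"] = fasta_path

    if library.oligos:
        order_path = Path(f"{out_prefix}.order.tsv")
        order_sheet(library.oligos).to_csv(order_path, sep="\t", index=False)
        written["order_tsv"] = order_path

    manifest_path = Path(f"{out_prefix}.manifest.tsv")
    with open(manifest_path, "w") as fh:
        fh.write("# size_painted_bp = paint_stop - paint_start (printed 1-based coordinates)\n")
        summarize([library]).to_csv(fh, sep="\t", index=False)
    written["manifest_tsv"] = manifest_path

    for name, part in (partitions or {}).items():
        part_path = Path(f"{out_prefix}.{name}.bed")
        partition_to_bed(part).to_csv(part_path, sep="\t", header=False, index=False)
        written[f"partition_{name}"] = part_path
        if not isinstance(part, StripeScheme):
            report_path = Path(f"{out_prefix}.{name}.domains.tsv")
            with open(report_path, "w") as fh:
                fh.write("# size = stop - start + 1 (printed 1-based inclusive coordinates)\n")
                domain_report(part).to_csv(fh, sep="\t", index=False)
            written[f"domain_report_{name}"] = report_path

    config_path = Path(f"{out_prefix}.runconfig.txt")
    with open(config_path, "w") as fh:
        fh.write(f"chrom={library.chrom}\n")
        fh.write(f"paint={library.paint.chrom}:{library.paint.start}-{library.paint.end}\n")
        fh.write(f"nominal_density={library.nominal_density}\n")
        for key in sorted(run_config or {}):
            fh.write(f"{key}={run_config[key]}\n")
    written["run_config"] = config_path
    return written
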
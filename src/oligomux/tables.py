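"""Published B. mori Oligopaint coordinate tables, shipped as package data.

Three tables describe the silkworm paint libraries this toolkit reproduces:
whole-chromosome paints (seven chromosomes with paint coordinates, nominal
densities and oligo totals), tel1/mid/tel2 stripe sub-libraries (five
chromosomes), and active/inactive chromatin-domain sub-libraries (ch7, ch15,
ch16). Printed coordinates are 1-based inclusive; conversion helpers return
the internal 0-based half-open intervals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genome_io import GenomicInterval
from .sublibraries import ChromatinDomain, StripeScheme

DOMAIN_TABLE_CHROMS = ("7", "15", "16")


def _load(name: str) -> pd.DataFrame:
    with resources.files("oligomux.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def load_paint_table() -> pd.DataFrame:
    """Whole-chromosome paint table: one row per painted chromosome."""
    return _load("bmori_paints.tsv")


def load_stripe_table() -> pd.DataFrame:
    """Stripe sub-library table: tel1/mid/tel2 coordinates and printed Mb sizes."""
    return _load("bmori_stripes.tsv")


def load_domain_table(chrom: str) -> pd.DataFrame:
    """Active/inactive chromatin-domain table for ch7, ch15 or ch16."""
    if chrom not in DOMAIN_TABLE_CHROMS:
        raise ValueError(
            f"domain tables exist for chromosomes {DOMAIN_TABLE_CHROMS}, got {chrom!r}"
        )
    return _load(f"bmori_domains_ch{chrom}.tsv")


def paint_interval(chrom: str) -> GenomicInterval:
    """Internal interval of a whole-chromosome paint (printed start − 1, stop)."""
    df = load_paint_table()
    row = df[df["chrom"] == chrom]
    if row.empty:
        raise KeyError(f"no paint table row for chromosome {chrom!r}")
    start = int(row["paint_start"].iloc[0]) - 1
    stop = int(row["paint_stop"].iloc[0])
    return GenomicInterval(chrom, start, stop)


def stripe_scheme(chrom: str) -> StripeScheme:
    """Stripe scheme with internal coordinates for one tabulated chromosome."""
    df = load_stripe_table()
    rows = df[df["chrom"] == chrom].set_index("stripe")
    if len(rows) != 3:
        raise KeyError(f"no stripe rows for chromosome {chrom!r}")
    ivs = {
        name: GenomicInterval(
            chrom, int(rows.loc[name, "paint_start"]) - 1, int(rows.loc[name, "paint_stop"])
        )
        for name in ("tel1", "mid", "tel2")
    }
    paint = GenomicInterval(chrom, ivs["tel1"].start, ivs["tel2"].end)
    from .sublibraries import define_stripes

    return define_stripes(paint, explicit=(ivs["tel1"], ivs["mid"], ivs["tel2"]))


def chromatin_domains(chrom: str) -> list[ChromatinDomain]:
    """Chromatin domains with internal coordinates for ch7, ch15 or ch16."""
    df = load_domain_table(chrom)
    return [
        ChromatinDomain(
            GenomicInterval(chrom, int(row.start) - 1, int(row.stop)), row.domain
        )
        for row in df.itertuples(index=False)
    ]
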
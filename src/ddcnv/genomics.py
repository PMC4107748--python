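"""CNV regions at blood-pressure GWAS loci and SNP-overlap arithmetic.

Coordinates are 1-based with both endpoints inclusive (UCSC browser
display style), so a region's length is ``end - start + 1``.  The
convention is pinned by the two published segment lengths reproduced in
the test suite (553,635 bp for esv27061 and 224,588 bp for dgv1306e1).
BED export converts to the 0-based half-open convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GenomicRegion",
    "DEFAULT_REGIONS",
    "region_length",
    "snp_in_region",
    "load_region_table",
    "regions_to_tsv",
    "regions_to_bed",
]

REGION_TSV_COLUMNS = ["cnv_id", "chrom", "start", "end", "assay_id"]


@dataclass(frozen=True)
class GenomicRegion:
    """A copy-number-variable segment, hg19, 1-based inclusive."""

    cnv_id: str
    chromosome: str
    start: int
    end: int
    assay_id: str = ""

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError("chromosome must be non-empty")
        if self.start > self.end:
            raise ValueError(f"{self.cnv_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.cnv_id}: 1-based start must be >= 1")


#: The eight CNVs at the four blood-pressure GWAS loci genotyped by this
#: pipeline's duplex assays (hg19 coordinates).  Overlapping CNVs at one
#: locus share a single TaqMan assay.
DEFAULT_REGIONS: tuple[GenomicRegion, ...] = (
    GenomicRegion("esv27061", "chr1", 112_692_629, 113_246_263, "Hs01327571"),
    GenomicRegion("esv2757747", "chr1", 113_157_135, 116_741_372, "Hs01327571"),
    GenomicRegion("nsv483076", "chr11", 10_193_294, 10_352_897, "Hs04399968"),
    GenomicRegion("dgv976e1", "chr17", 44_083_914, 45_277_333, "Hs00313538"),
    GenomicRegion("esv2656635", "chr17", 44_281_452, 45_168_501, "Hs00313538"),
    GenomicRegion("nsv908562", "chr17", 44_828_931, 45_102_413, "Hs00313538"),
    GenomicRegion("dgv986e1", "chr17", 44_971_360, 45_277_333, "Hs00313538"),
    GenomicRegion("dgv1306e1", "chr20", 10_892_138, 11_116_725, "Hs03126928"),
)


def region_length(region: GenomicRegion) -> int:
    """Length in base pairs under the 1-based inclusive convention."""
    return region.end - region.start + 1


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def snp_in_region(chromosome: str, position: int, region: GenomicRegion) -> bool:
    """True iff a SNP (1-based) falls inside the region, endpoints inclusive.

    Chromosome names are compared with the optional ``chr`` prefix
    stripped; the same genome build is assumed on both sides.
    """
    return (_norm_chrom(chromosome) == _norm_chrom(region.chromosome)
            and region.start <= position <= region.end)


def _parse_coord(value) -> int:
    # accept comma-grouped digits as printed in genome-browser landmarks
    return int(str(value).replace(",", "").strip())


def load_region_table(path: str | Path) -> list[GenomicRegion]:
    """Read a region TSV (cnv_id, chrom, start, end, assay_id).

    Comma-grouped coordinates ("112,692,629") are accepted.  An empty
    file yields an empty list; malformed or inverted coordinates raise.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing = set(REGION_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    regions = []
    for r in df.itertuples(index=False):
        regions.append(GenomicRegion(
            cnv_id=r.cnv_id, chromosome=r.chrom,
            start=_parse_coord(r.start), end=_parse_coord(r.end),
            assay_id="" if pd.isna(r.assay_id) else str(r.assay_id)))
    return regions


def regions_to_tsv(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.cnv_id, r.chromosome, r.start, r.end, r.assay_id) for r in regions],
        columns=REGION_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def regions_to_bed(regions: Sequence[GenomicRegion], path: str | Path) -> None:
    """Export regions as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{r.cnv_id}\n")
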
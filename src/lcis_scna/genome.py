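"""Reference genome model used throughout the package.

A deliberately compact genome: the ten chromosomes that carry the recurrent
lobular-carcinoma copy-number aberrations (1q gain, 16q loss, 17p loss,
11q13 amplification, 6q/8p23/22q13 losses, Xp11/20p12/17q11 gains), with
hg19-scale lengths and centromere positions. Coordinates are 1-based
inclusive everywhere in memory; BED input is converted at the parser.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

# chrom -> (length, centromere midpoint), hg19 scale, rounded to 100 kb
CHROMOSOMES: dict[str, tuple[int, int]] = {
    "chr1": (249_200_000, 125_000_000),
    "chr2": (243_200_000, 93_300_000),
    "chr3": (198_000_000, 91_000_000),
    "chr4": (191_200_000, 50_400_000),
    "chr5": (180_900_000, 48_400_000),
    "chr6": (171_100_000, 61_000_000),
    "chr7": (159_100_000, 59_900_000),
    "chr8": (146_400_000, 45_600_000),
    "chr9": (141_200_000, 49_000_000),
    "chr10": (135_500_000, 40_200_000),
    "chr11": (135_000_000, 53_700_000),
    "chr12": (133_900_000, 35_800_000),
    "chr13": (115_200_000, 17_900_000),
    "chr14": (107_300_000, 17_600_000),
    "chr15": (102_500_000, 19_000_000),
    "chr16": (90_300_000, 36_800_000),
    "chr17": (81_200_000, 24_000_000),
    "chr18": (78_100_000, 17_200_000),
    "chr19": (59_100_000, 26_500_000),
    "chr20": (63_000_000, 27_500_000),
    "chr21": (48_100_000, 13_200_000),
    "chr22": (51_300_000, 14_700_000),
    "chrX": (155_300_000, 60_600_000),
}


@dataclass(frozen=True)
class Region:
    """A named 1-based inclusive genomic interval."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.name}: end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def arm_table(chromosomes: dict[str, tuple[int, int]] | None = None) -> pd.DataFrame:
    """Chromosome-arm definition table: columns chrom, arm, start, end."""
    chromosomes = chromosomes or CHROMOSOMES
    rows = []
    for chrom, (length, cen) in chromosomes.items():
        rows.append({"chrom": chrom, "arm": chrom.removeprefix("chr") + "p",
                     "start": 1, "end": cen})
        rows.append({"chrom": chrom, "arm": chrom.removeprefix("chr") + "q",
                     "start": cen + 1, "end": length})
    return pd.DataFrame(rows)


# Recurrent aberration regions.  Arm-level regions span the arm; the focal
# regions follow the cohort analysis (cytoband-scale intervals), padded to
# >= 2 Mb so they remain resolvable at the default 100 kb probe spacing.
REGIONS: dict[str, Region] = {
    "16q": Region("16q", "chr16", 36_800_001, 90_300_000),
    "16p": Region("16p", "chr16", 1, 36_800_000),
    "1q": Region("1q", "chr1", 125_000_001, 249_200_000),
    "17p": Region("17p", "chr17", 1, 24_000_000),
    "19p": Region("19p", "chr19", 1, 26_500_000),
    "6q14-27": Region("6q14-27", "chr6", 82_400_000, 171_100_000),
    "8p23": Region("8p23", "chr8", 2_200_000, 12_800_000),
    "22q13": Region("22q13", "chr22", 47_700_000, 51_300_000),
    "11q13": Region("11q13", "chr11", 68_900_000, 71_600_000),
    "17q11-RAB11FIP4": Region("17q11-RAB11FIP4", "chr17", 28_800_000, 30_900_000),
    "20p12-MACROD2": Region("20p12-MACROD2", "chr20", 13_700_000, 16_200_000),
    "Xp11-KLF8": Region("Xp11-KLF8", "chrX", 55_600_000, 57_700_000),
}
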
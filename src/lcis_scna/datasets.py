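"""Published study counts used as analysis inputs.

These are the printed cohort tallies of the LCIS SNP-array study (group
sizes, region-by-group SCNA counts, and the cyclin D1 validation-set
outcomes), entered as data.  The per-patient validation sheet is a
synthetic reconstruction: individual scores are invented so that the
published aggregate counts are reproduced exactly; no per-patient value
is a measured one.
"""

from __future__ import annotations

import pandas as pd

from .cohort import CohortTable, RegionQuery

GROUP_ORDER = ("pure-cLCIS", "inv-cLCIS", "cILC")
GROUP_SIZES = {"pure-cLCIS": 27, "inv-cLCIS": 28, "cILC": 25}

# discovery-set attrition: samples submitted vs with adequate DNA
SAMPLES_SUBMITTED = {"pure-cLCIS": 30, "inv-cLCIS": 30, "cILC": 30}
# samples excluded from the sub-clonality analysis (unresolvable CN1/2/3 clusters)
SUBCLONE_EXCLUSIONS = {"pure-cLCIS": 5, "inv-cLCIS": 3, "cILC": 3}

# 1q gain/cnLOH counts per group
CHR1Q_GAIN_COUNTS = {"pure-cLCIS": 21, "inv-cLCIS": 25, "cILC": 21}

# Differentially frequent SCNA regions: (name, chrom, start, end, type,
# affected counts per group in GROUP_ORDER order)
_DIFF_REGIONS = [
    ("5p13.1-LOC101926940", "chr5", 39_436_375, 39_620_648, "gain", (4, 0, 3)),
    ("5q23.3-q31.1", "chr5", 129_741_359, 131_422_972, "gain", (4, 0, 2)),
    ("6q14.1-q27", "chr6", 82_391_438, 171_115_067, "loss", (0, 2, 10)),
    ("8p23.2-p23.1", "chr8", 5_412_833, 8_927_086, "loss", (1, 2, 9)),
    ("10q22.2", "chr10", 75_541_103, 76_515_425, "gain", (2, 0, 5)),
    ("11q13.3-q13.4-CCND1", "chr11", 68_961_001, 71_551_048, "gain", (0, 4, 6)),
    ("17q11.2-RAB11FIP4", "chr17", 29_779_560, 29_899_917, "gain", (5, 0, 0)),
    ("18p11.32-YES1", "chr18", 727_180, 742_194, "gain", (7, 2, 0)),
    ("Xp11.21-KLF8", "chrX", 55_670_623, 57_693_679, "gain", (10, 0, 1)),
    ("20p12.1-MACROD2", "chr20", 14_695_735, 15_225_214, "gain", (6, 0, 1)),
    ("22q13.31-q13.3", "chr22", 47_751_337, 51_304_566, "loss", (2, 4, 13)),
]


def differential_region_tables() -> list[CohortTable]:
    """The published region-by-group SCNA counts as CohortTable objects."""
    tables = []
    for name, chrom, start, end, scna_type, counts in _DIFF_REGIONS:
        region = RegionQuery(name, chrom, start, end, scna_type)
        tables.append(CohortTable(region, {
            g: (aff, GROUP_SIZES[g]) for g, aff in zip(GROUP_ORDER, counts)
        }))
    return tables


def ccnd1_validation_sheet() -> pd.DataFrame:
    """Synthetic per-patient sheet reproducing the published validation-set
    aggregates: 32 pure-LCIS patients with long-term follow up, 4
    ipsilateral and 4 contralateral invasive recurrences (the latter
    excluded from association analyses), high cyclin D1 IHC (total >= 6)
    in 4/4 ipsilateral recurrers and 8/24 non-recurrers, CCND1 FISH
    amplification in 1 recurrer and gain in 1 non-recurrer.
    """
    rows = []

    def add(n, prefix, proportion, intensity, outcome, laterality, fish_ratio=None):
        for i in range(n):
            rows.append({
                "sample": f"{prefix}-{len(rows):02d}",
                "proportion_fraction": proportion,
                "intensity": intensity,
                "fish_ratio": fish_ratio,
                "outcome": outcome,
                "laterality": laterality,
                "followup_months": 81,
            })

    # 4 ipsilateral recurrers, all high IHC (5 + 3 = 8); one CCND1-amplified
    add(1, "rec", 0.8, 3, "invasive_recurrence", "ipsilateral", fish_ratio=3.0)
    add(3, "rec", 0.8, 3, "invasive_recurrence", "ipsilateral", fish_ratio=1.2)
    # 24 non-recurrers: 8 high (one with FISH gain), 16 not high
    add(1, "ctrl", 0.8, 3, "none", "ipsilateral", fish_ratio=2.0)
    add(7, "ctrl", 0.8, 3, "none", "ipsilateral", fish_ratio=1.2)
    add(8, "ctrl", 0.2, 2, "none", "ipsilateral")   # total 5, intermediate
    add(8, "ctrl", 0.0, 0, "none", "ipsilateral")   # total 0, low
    # 4 contralateral recurrences, excluded from association analyses
    add(4, "contra", 0.2, 2, "invasive_recurrence", "contralateral")
    return pd.DataFrame(rows)
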
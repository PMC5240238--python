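"""Readers and writers for the pipeline's text formats.

SEG-like tables and probe tables are 1-based inclusive, tab-separated;
BED blacklists are 0-based half-open on disk and converted to 1-based
inclusive at the parser.  All readers fail with file:line context on
malformed rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .cn_calling import SampleModel
from .segmentation import Segment, segments_to_frame

PROBE_COLUMNS = ["chrom", "pos", "lrr", "baf", "is_het"]
SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_probes", "mean_lrr", "ai"]


class ParseError(ValueError):
    pass


def read_probe_tsv(path) -> pd.DataFrame:
    """Probe table; '#'-prefixed header lines (echoed generator settings)
    are skipped."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PROBE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: probe table missing columns {sorted(missing)}")
    return df[PROBE_COLUMNS + [c for c in df.columns if c not in PROBE_COLUMNS]]


def write_seg(path, segments: list[Segment] | pd.DataFrame) -> None:
    df = segments if isinstance(segments, pd.DataFrame) else segments_to_frame(segments)
    df.to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: SEG table missing columns {sorted(missing)}")
    if (df["end"] < df["start"]).any():
        bad = df.index[(df["end"] < df["start"])][0]
        raise ParseError(f"{path}: line {bad + 2}: end < start")
    return df


def seg_frame_to_segments(df: pd.DataFrame) -> list[Segment]:
    segs = []
    for row in df.itertuples(index=False):
        acn = getattr(row, "acn", None)
        minor = getattr(row, "minor_cn", None)
        cls = getattr(row, "scna_class", None)
        segs.append(Segment(
            chrom=row.chrom, start=int(row.start), end=int(row.end),
            n_probes=int(row.n_probes), mean_lrr=float(row.mean_lrr),
            ai=float(row.ai),
            acn=None if pd.isna(acn) else int(acn),
            minor_cn=None if pd.isna(minor) else int(minor),
            scna_class=None if pd.isna(cls) else str(cls),
            sample_id=None if pd.isna(row.sample) else str(row.sample),
        ))
    return segs


def read_bed(path) -> list[tuple[str, int, int]]:
    """BED intervals converted to 1-based inclusive (start+1, end)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end < start:
                raise ParseError(f"{path}:{lineno}: invalid interval {start}-{end}")
            intervals.append((chrom, start + 1, end))
    return intervals


def read_sample_sheet(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ParseError(f"{path}: sample sheet needs a 'sample' column")
    missing = set(required) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {sorted(missing)}")
    return df


def write_model_json(path, model: SampleModel, sample_id: str | None = None) -> None:
    payload = {
        "sample": sample_id,
        "usable": model.usable,
        "wgd": model.wgd,
        "modal_cn": model.modal_cn,
        "purity_estimate": model.purity_estimate,
        "diploid_centroid": model.diploid_centroid,
        "lrr_scale": model.lrr_scale,
        "ai_scale": model.ai_scale,
        "reason": model.reason,
        "clusters": [
            {"cn": c.cn, "minor": c.minor, "center": list(c.center), "weight": c.weight}
            for c in model.clusters
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def subclone_calls_to_frame(calls_by_sample: dict) -> pd.DataFrame:
    rows = []
    for sample, calls in calls_by_sample.items():
        for c in calls:
            rows.append({
                "sample": sample, "chrom": c.segment.chrom,
                "start": c.segment.start, "end": c.segment.end,
                "proportion": c.proportion, "threshold": c.threshold,
                "clonality": c.clonality,
                "est_cell_fraction": c.est_cell_fraction,
                "is_reference": c.is_reference,
            })
    return pd.DataFrame(rows, columns=[
        "sample", "chrom", "start", "end", "proportion", "threshold",
        "clonality", "est_cell_fraction", "is_reference"])
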
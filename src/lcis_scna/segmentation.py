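"""Probe-level segmentation into runs of constant copy-number signal.

Penalised recursive binary splitting on two channels: the log-R ratio of
every probe and the folded B-allele frequency |BAF - 0.5| of heterozygous
probes.  Both channels are standardised by a robust first-difference noise
estimate so the breakpoint penalty is noise-scale free.  A split is kept
when the residual-sum-of-squares reduction exceeds the penalty and both
sides retain at least ``min_probes`` probes; the greedy split tree is
nested, so lowering the penalty can only add breakpoints.

This is a deliberately simple stand-in for a production segmenter: the
downstream copy-number and sub-clonality analyses consume segments, not
the segmentation algorithm itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

SCNA_CLASSES = ("neutral", "loss", "gain", "amplification", "cnLOH")


@dataclass
class Segment:
    """A contiguous genomic run: 1-based inclusive coordinates, probe
    count, mean LRR and allelic-imbalance score (0 = balanced, ~1 = clonal
    LOH); absolute/minor copy number and SCNA class are set by the caller
    stage."""

    chrom: str
    start: int
    end: int
    n_probes: int
    mean_lrr: float
    ai: float
    acn: int | None = None
    minor_cn: int | None = None
    scna_class: str | None = None
    low_confidence: bool = False
    sample_id: str | None = None
    cluster_id: int | None = None  # index into the sample model's clusters

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("segment end < start")
        if self.scna_class is not None and self.scna_class not in SCNA_CLASSES:
            raise ValueError(f"unknown scna_class {self.scna_class!r}")

    @property
    def point(self) -> tuple[float, float]:
        return (self.mean_lrr, self.ai)


def _robust_noise_sd(values: np.ndarray) -> float:
    """Noise sd from the median absolute first difference (Gaussian:
    median|X1-X2| = sd * sqrt(2) * 0.6745)."""
    d = np.abs(np.diff(values))
    d = d[np.isfinite(d)]
    if d.size < 2:
        return 1.0
    med = float(np.median(d))
    return max(med / (math.sqrt(2.0) * 0.6745), 1e-6)


def _best_split(csum, csum2, cnt, lo, hi, min_probes):
    """Best split index and total RSS reduction over the stacked channels.

    csum/csum2/cnt are per-channel cumulative sums of values, squared
    values and finite counts over probes lo..hi (exclusive hi).
    """
    n = hi - lo
    ks = np.arange(lo + min_probes, hi - min_probes + 1)
    if ks.size == 0:
        return None, 0.0
    gain = np.zeros(ks.size)
    for s1, _s2, c in zip(csum, csum2, cnt):
        tot = s1[hi] - s1[lo]
        ctot = c[hi] - c[lo]
        if ctot < 2:
            continue
        left = s1[ks] - s1[lo]
        cleft = c[ks] - c[lo]
        right = tot - left
        cright = ctot - cleft
        ok = (cleft > 0) & (cright > 0)
        contrib = np.zeros(ks.size)
        contrib[ok] = (left[ok] ** 2 / cleft[ok] + right[ok] ** 2 / cright[ok]
                       - tot ** 2 / ctot)
        gain += contrib
    i = int(np.argmax(gain))
    return int(ks[i]), float(gain[i])


def _best_window(csum, cnt, lo, hi, min_probes):
    """Best interior window to carve out of [lo, hi): the single-split scan
    misses focal events flanked by the same level on both sides, so windows
    of doubling widths are tested against the carve-out RSS reduction."""
    n = hi - lo
    best_k, best_w, best_gain = None, None, 0.0
    w = min_probes
    while lo + min_probes + w + min_probes <= hi:
        ks = np.arange(lo + min_probes, hi - min_probes - w + 1)
        gain = np.zeros(ks.size)
        for s1, c in zip(csum, cnt):
            tot = s1[hi] - s1[lo]
            ctot = c[hi] - c[lo]
            if ctot < 2:
                continue
            inside = s1[ks + w] - s1[ks]
            cin = c[ks + w] - c[ks]
            outside = tot - inside
            cout = ctot - cin
            ok = (cin > 0) & (cout > 0)
            contrib = np.zeros(ks.size)
            contrib[ok] = (inside[ok] ** 2 / cin[ok] + outside[ok] ** 2 / cout[ok]
                           - tot ** 2 / ctot)
            gain += contrib
        i = int(np.argmax(gain))
        if gain[i] > best_gain:
            best_k, best_w, best_gain = int(ks[i]), w, float(gain[i])
        w *= 2
    return best_k, best_w, best_gain


def _segment_chrom(pos, lrr, fold, het, min_probes, penalty):
    n = pos.size
    z_lrr = lrr / _robust_noise_sd(lrr)
    fold_het = fold[het]
    s_fold = _robust_noise_sd(fold_het) if fold_het.size >= 3 else 1.0
    z_fold = np.where(het, fold / s_fold, 0.0)
    cnt_fold = het.astype(float)

    def cs(x):
        return np.concatenate([[0.0], np.cumsum(x)])

    csum = (cs(z_lrr), cs(z_fold))
    csum2 = (cs(z_lrr**2), cs(z_fold**2))
    cnt = (cs(np.ones(n)), cs(cnt_fold))

    breaks = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 2 * min_probes:
            continue
        k, gain = _best_split(csum, csum2, cnt, lo, hi, min_probes)
        if k is not None and gain > penalty:
            breaks.append(k)
            stack.append((lo, k))
            stack.append((k, hi))
            continue
        wk, ww, wgain = _best_window(csum, cnt, lo, hi, min_probes)
        if wk is not None and wgain > penalty:
            breaks.extend([wk, wk + ww])
            stack.append((lo, wk))
            stack.append((wk, wk + ww))
            stack.append((wk + ww, hi))
    edges = [0] + sorted(breaks) + [n]
    return edges


def segment_probes(
    probes: pd.DataFrame,
    min_probes: int = 10,
    penalty: float | None = None,
    sample_id: str | None = None,
) -> list[Segment]:
    """Partition a probe table (columns chrom, pos, lrr, baf, is_het) into
    segments.

    ``penalty`` is a free parameter (the upstream vendor threshold is not
    public); the default ``6 * ln(n_probes_on_chromosome)`` holds the
    expected number of spurious breakpoints per chromosome well below one
    at the generator's default noise.  Probes must be sorted by
    (chrom, pos); chromosomes with fewer than ``min_probes`` probes come
    back as a single low-confidence segment.  Segments tile each
    chromosome from first to last probe, splitting between probes at the
    midpoint.
    """
    required = {"chrom", "pos", "lrr", "baf", "is_het"}
    if not required.issubset(probes.columns):
        raise ValueError(f"probe table missing columns {required - set(probes.columns)}")
    chrom_vals = probes["chrom"].to_numpy()
    first_idx = pd.unique(chrom_vals)
    # chromosome blocks must be contiguous and positions ascending within
    codes = pd.Series(chrom_vals).map({c: i for i, c in enumerate(first_idx)}).to_numpy()
    if np.any(np.diff(codes) < 0):
        raise ValueError("probes not sorted: chromosome blocks interleaved")

    segments: list[Segment] = []
    for chrom in first_idx:
        sub = probes[chrom_vals == chrom]
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"probes not sorted by position on {chrom}")
        lrr = sub["lrr"].to_numpy(dtype=float)
        baf = sub["baf"].to_numpy(dtype=float)
        het = sub["is_het"].to_numpy(dtype=bool)
        fold = np.abs(baf - 0.5)
        n = pos.size
        if n < min_probes:
            segments.append(_make_segment(chrom, pos, lrr, fold, het, 0, n,
                                          int(pos[0]), int(pos[-1]),
                                          low_confidence=True, sample_id=sample_id))
            continue
        pen = penalty if penalty is not None else 6.0 * math.log(n)
        edges = _segment_chrom(pos, lrr, fold, het, min_probes, pen)
        for j, (lo, hi) in enumerate(zip(edges, edges[1:])):
            start = int(pos[lo]) if j == 0 else int((pos[lo - 1] + pos[lo]) // 2 + 1)
            end = int(pos[hi - 1]) if hi == n else int((pos[hi - 1] + pos[hi]) // 2)
            segments.append(_make_segment(chrom, pos, lrr, fold, het, lo, hi,
                                          start, end, sample_id=sample_id))
    return segments


def _make_segment(chrom, pos, lrr, fold, het, lo, hi, start, end,
                  low_confidence=False, sample_id=None) -> Segment:
    sl = slice(lo, hi)
    fold_het = fold[sl][het[sl]]
    if fold_het.size:
        ai = float(np.clip(2.0 * np.median(fold_het), 0.0, 1.0))
    else:
        ai = 0.0
        low_confidence = True
    return Segment(
        chrom=str(chrom), start=start, end=end, n_probes=hi - lo,
        mean_lrr=float(np.mean(lrr[sl])), ai=ai,
        low_confidence=low_confidence, sample_id=sample_id,
    )


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    """SEG-like table (1-based inclusive coordinates)."""
    return pd.DataFrame([{
        "sample": s.sample_id, "chrom": s.chrom, "start": s.start, "end": s.end,
        "n_probes": s.n_probes, "mean_lrr": s.mean_lrr, "ai": s.ai,
        "acn": s.acn, "minor_cn": s.minor_cn, "scna_class": s.scna_class,
    } for s in segments])
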
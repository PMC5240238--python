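"""Absolute copy-number assignment from segment clusters.

Segments live in the (mean LRR, allelic imbalance) plane, where each
absolute copy-number state of a sample with purity ``f`` occupies a
predictable position: CN1 at (log2(1 - f/2), f/(2-f)), balanced CN2 at
(0, ~0), copy-neutral LOH at (0, f), CN3 at (log2(1 + f/2), f/(2+f)),
and so on.  The caller

1. clusters segments in that plane (probe-count weighted; 1-D gap
   clustering on LRR, then an allelic-imbalance split within each LRR
   level),
2. identifies the modal cluster and tests which ploidy rung it sits on
   (diploid, triploid or tetraploid background) using the inter-cluster
   spacing and the allelic-imbalance signature of the neighbouring rungs,
3. labels every cluster with the (total, minor) state nearest its centre
   under the implied purity, and
4. reports the sample unusable when the three anchor clusters around the
   modal state cannot be resolved -- mirroring the exclusion rule applied
   to poor-quality hybridisations.

This is a deliberately simplified cluster-based caller: downstream
analyses need its outputs (CN labels, the diploid centroid and the 2-D
segment coordinates), not a full purity/ploidy inference engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .segmentation import Segment

_MIN_SEGMENTS = 20
_LRR_BANDWIDTH = 0.08  # KDE bandwidth on the LRR axis (baseline-wave scale)
_AI_BANDWIDTH = 0.05   # KDE bandwidth on the allelic-imbalance axis
_MIN_PEAK_MASS = 15.0  # minimum probe mass for a density peak
_MAX_CN = 8


@dataclass
class Cluster:
    cn: int | None
    minor: int | None
    center: tuple[float, float]
    weight: float
    members: list[int] = field(default_factory=list)


@dataclass
class SampleModel:
    """Per-sample calibration: labelled clusters, the diploid centroid and
    the diploid-cluster spreads used to standardise distances."""

    clusters: list[Cluster] = field(default_factory=list)
    diploid_centroid: tuple[float, float] | None = None
    lrr_scale: float = 1.0
    ai_scale: float = 1.0
    usable: bool = False
    wgd: bool = False
    modal_cn: int | None = None
    detected_modal_cn: int | None = None  # modal ploidy before any correction
    purity_estimate: float | None = None
    reason: str = ""

    @property
    def aneuploid(self) -> bool:
        detected = self.detected_modal_cn or self.modal_cn
        return detected is not None and detected != 2

    @property
    def diploid_cluster_id(self) -> int | None:
        if not self.clusters:
            return None
        return self.clusters.index(
            _diploid_cluster(self.clusters, self.modal_cn or 2))

    @property
    def cluster_centers(self) -> dict[int, tuple[float, float]]:
        """Heaviest cluster centre per copy-number state."""
        out: dict[int, tuple[float, float]] = {}
        best: dict[int, float] = {}
        for c in self.clusters:
            if c.cn is None:
                continue
            if c.weight > best.get(c.cn, -1.0):
                best[c.cn] = c.weight
                out[c.cn] = c.center
        return out

    def standardise(self, point: tuple[float, float]) -> np.ndarray:
        return np.array([point[0] / self.lrr_scale, point[1] / self.ai_scale])


def _density_peak_clusters(lrr: np.ndarray, ai: np.ndarray,
                           w: np.ndarray) -> list[np.ndarray]:
    """Weighted kernel-density peak clustering in bandwidth-standardised
    (LRR, AI) space.

    Segments straddling event boundaries produce bridge points between
    copy-number states; density peaks are insensitive to such bridges
    (unlike linkage clustering, which they chain together).  Peaks below
    ``_MIN_PEAK_MASS`` probes of local mass are ignored; each segment is
    assigned to the nearest surviving peak."""
    x = lrr / _LRR_BANDWIDTH
    y = ai / _AI_BANDWIDTH
    step = 0.5  # grid step in bandwidth units
    gx = np.arange(x.min() - 2, x.max() + 2 + step, step)
    gy = np.arange(max(y.min() - 2, -2), y.max() + 2 + step, step)
    # density on the grid: sum of per-segment Gaussian kernels, probe-weighted
    dx = gx[:, None] - x[None, :]
    dy = gy[:, None] - y[None, :]
    kx = np.exp(-0.5 * dx**2)
    ky = np.exp(-0.5 * dy**2)
    dens = np.einsum("is,js,s->ij", kx, ky, w)

    peaks = []
    ni, nj = dens.shape
    for i in range(ni):
        for j in range(nj):
            v = dens[i, j]
            if v < _MIN_PEAK_MASS:
                continue
            window = dens[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2]
            if v >= window.max():
                peaks.append((gx[i], gy[j], v))
    if not peaks:
        return [np.arange(x.size)]
    # merge peaks closer than 1.5 bandwidths, keeping the denser one
    peaks.sort(key=lambda p: -p[2])
    kept: list[tuple[float, float, float]] = []
    for p in peaks:
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 > 1.5**2 for q in kept):
            kept.append(p)
    px = np.array([p[0] for p in kept])
    py = np.array([p[1] for p in kept])
    d2 = (x[:, None] - px[None, :]) ** 2 + (y[:, None] - py[None, :]) ** 2
    labels = np.argmin(d2, axis=1)
    return [np.where(labels == k)[0] for k in range(len(kept))
            if np.any(labels == k)]


def _mixture(cn: float, f: float) -> float:
    return f * cn + 2.0 * (1.0 - f)


def _state_position(cn: int, minor: int, f: float, modal_cn: int) -> tuple[float, float]:
    mix = max(_mixture(cn, f), 0.05)
    lrr = math.log2(mix / _mixture(modal_cn, f))
    ai = f * (cn - 2 * minor) / mix
    return lrr, ai


def _purity_from_spacing(modal_cn: int, rung_cn: int, lrr_offset: float) -> float | None:
    """Purity implied by a cluster sitting ``lrr_offset`` away from the
    modal cluster if it occupies copy-number rung ``rung_cn`` while the
    modal cluster occupies ``modal_cn``:
    2^offset = mix(rung)/mix(modal) with mix(k) = f*k + 2(1-f)."""
    rho = 2.0 ** lrr_offset
    denom = rho * (modal_cn - 2) - (rung_cn - 2)
    if abs(denom) < 1e-9:
        return None
    f = 2.0 * (1.0 - rho) / denom
    if not 0.05 <= f <= 1.0:
        return None
    return f


def fit_sample_model(segments: list[Segment]) -> SampleModel:
    """Cluster segments in (LRR, AI) space and label the copy-number ladder.

    Returns an unusable model (never raises) when fewer than 20 segments
    are supplied, when only one cluster is separable (e.g. pure noise), or
    when the three anchor states around the modal cluster are missing.
    """
    model = SampleModel()
    if len(segments) < _MIN_SEGMENTS:
        model.reason = f"too few segments ({len(segments)} < {_MIN_SEGMENTS})"
        return model

    lrr = np.array([s.mean_lrr for s in segments])
    ai = np.array([s.ai for s in segments])
    w = np.array([max(s.n_probes, 1) for s in segments], dtype=float)

    clusters: list[Cluster] = []
    for members in _density_peak_clusters(lrr, ai, w):
        ww = w[members]
        center = (float(np.average(lrr[members], weights=ww)),
                  float(np.average(ai[members], weights=ww)))
        clusters.append(Cluster(None, None, center, float(ww.sum()),
                                list(map(int, members))))
    clusters.sort(key=lambda c: c.center[0])
    model.clusters = clusters
    if len(clusters) < 2:
        model.reason = "only one separable cluster"
        return model

    modal = max(clusters, key=lambda c: c.weight)

    # Which rung of the ploidy ladder is the modal cluster on, and at what
    # purity?  Candidate purities come from the LRR spacing between the
    # modal cluster and every other substantial cluster, tried on nearby
    # rungs; each (rung, purity) hypothesis is scored by how well the full
    # ladder explains the observed cluster centres (sub-clonal clusters sit
    # between rungs and score poorly under every hypothesis, so they cannot
    # steer the choice).
    heavy = [c for c in clusters if c is not modal and c.weight >= 30]
    best: tuple[float, int, float] | None = None  # (score, modal_cn, purity)
    scorable = [c for c in clusters if c.weight >= 30] or clusters
    for m in (2, 3, 4):
        candidates = []
        for c in heavy:
            offset = c.center[0] - modal.center[0]
            for rung in range(max(m - 2, 0), m + 3):
                if rung == m:
                    continue
                f = _purity_from_spacing(m, rung, offset)
                if f is not None:
                    candidates.append(f)
        for f in candidates:
            score = _hypothesis_score(scorable, m, f)
            if best is None or score < best[0]:
                best = (score, m, f)
    if best is None:
        model.reason = "no consistent purity for any ploidy hypothesis"
        return model
    _, modal_cn, purity = best
    model.modal_cn = modal_cn
    model.detected_modal_cn = modal_cn
    model.purity_estimate = purity

    for c in clusters:
        c.cn, c.minor = _nearest_state(c.center, purity, modal_cn)

    # anchor requirement: the modal state plus a resolvable cluster on the
    # rung below and above.  On a diploid background this is the strict
    # CN 1 / 2 / 3 requirement; on a duplicated background losses and
    # gains may sit two rungs out (e.g. a pre-duplication loss at CN 2 on
    # a tetraploid genome), so anchors within two rungs are accepted.
    present = {c.cn for c in clusters}
    if modal_cn == 2:
        below_ok = {1} & present
        above_ok = {3} & present
    else:
        below_ok = {modal_cn - 1, modal_cn - 2} & present
        above_ok = {modal_cn + 1, modal_cn + 2} & present
    if modal_cn not in present or not below_ok or not above_ok:
        model.reason = (f"anchor copy-number clusters missing around modal "
                        f"CN {modal_cn} (have {sorted(present)})")
        return model
    centers = model.cluster_centers
    if not (centers[max(below_ok)][0] < centers[modal_cn][0]
            < centers[min(above_ok)][0]):
        model.reason = "cluster centres not ordered in LRR"
        return model

    diploid = _diploid_cluster(clusters, modal_cn)
    members = np.asarray(diploid.members)
    ww = w[members]
    model.diploid_centroid = (float(np.average(lrr[members], weights=ww)),
                              float(np.average(ai[members], weights=ww)))
    model.lrr_scale = max(float(np.sqrt(np.cov(lrr[members], aweights=ww)))
                          if members.size > 2 else 0.05, 0.02)
    model.ai_scale = max(float(np.sqrt(np.cov(ai[members], aweights=ww)))
                         if members.size > 2 else 0.02, 0.01)
    model.usable = True
    return model


def _hypothesis_score(clusters: list[Cluster], modal_cn: int, f: float) -> float:
    """Goodness of a (modal ploidy, purity) reading of the cluster ladder.

    The base term is the probe-weighted mean squared distance from each
    cluster centre to its nearest predicted copy-number state.  Prior
    terms break the inherent degeneracies of the ladder (a fully even-CN
    genome at background ploidy 4 is mathematically identical to a
    diploid genome at purity 2f/(1+f); a sub-clonal loss cluster heavier
    than the clonal one can drag the purity to the sub-clonal fraction):
    probe mass explained as homozygous deletion is heavily penalised,
    higher background ploidies carry a small parsimony cost, and readings
    that fail to resolve the anchor rungs either side of the modal state
    -- the structure the downstream procedure requires -- are disfavoured.
    """
    total = sum(c.weight for c in clusters)
    score = 0.0
    mass_cn0 = 0.0
    labels = set()
    for c in clusters:
        best = None
        for cn in range(0, _MAX_CN + 1):
            for minor in range(0, cn // 2 + 1):
                p = _state_position(cn, minor, f, modal_cn)
                d2 = (c.center[0] - p[0]) ** 2 + (c.center[1] - p[1]) ** 2
                if best is None or d2 < best[0]:
                    best = (d2, cn)
        score += c.weight * best[0]
        labels.add(best[1])
        if best[1] == 0:
            mass_cn0 += c.weight
    score /= total
    score += 0.5 * mass_cn0 / total + 0.002 * (modal_cn - 2)
    if modal_cn == 2:
        anchor_sets = ({1}, {3})
    else:  # duplicated backgrounds: events may sit two rungs out
        anchor_sets = ({modal_cn - 1, modal_cn - 2}, {modal_cn + 1, modal_cn + 2})
    for side in anchor_sets:
        if not side & labels:
            score += 0.02
    return score


def _all_state_positions(f: float, modal_cn: int):
    for cn in range(0, _MAX_CN + 1):
        for minor in range(0, cn // 2 + 1):
            yield _state_position(cn, minor, f, modal_cn)


def _nearest_state(center, f, modal_cn) -> tuple[int, int]:
    best = None
    for cn in range(0, _MAX_CN + 1):
        for minor in range(0, cn // 2 + 1):
            p = _state_position(cn, minor, f, modal_cn)
            d2 = (center[0] - p[0]) ** 2 + (center[1] - p[1]) ** 2
            if best is None or d2 < best[0]:
                best = (d2, cn, minor)
    return best[1], best[2]


def _diploid_cluster(clusters: list[Cluster], modal_cn: int) -> Cluster:
    """The cluster whose segments the sub-clonality procedure treats as
    the diploid reference: the balanced modal cluster for an even modal
    ploidy, the true-CN2 cluster for a triploid background."""
    target_cn = modal_cn if modal_cn % 2 == 0 else 2
    target_minor = target_cn // 2
    candidates = [c for c in clusters if c.cn == target_cn]
    if candidates:
        balanced = [c for c in candidates if c.minor == target_minor]
        pool = balanced or candidates
        return max(pool, key=lambda c: c.weight)
    return max(clusters, key=lambda c: c.weight)


class UnusableModelError(ValueError):
    """Raised when absolute CN assignment is requested for an excluded sample."""


def assign_absolute_cn(segments: list[Segment], model: SampleModel) -> list[Segment]:
    """Label each segment with the state of its nearest cluster centre
    (Euclidean distance in diploid-spread-standardised space; ties broken
    toward the diploid cluster, which is searched first)."""
    if not model.usable:
        raise UnusableModelError(f"sample model unusable: {model.reason}")
    diploid = _diploid_cluster(model.clusters, model.modal_cn or 2)
    ordered = [diploid] + [c for c in model.clusters if c is not diploid]
    centers = np.array([model.standardise(c.center) for c in ordered])
    for seg in segments:
        z = model.standardise(seg.point)
        d = np.linalg.norm(centers - z, axis=1)
        c = ordered[int(np.argmin(d))]
        seg.acn, seg.minor_cn = c.cn, c.minor
        seg.cluster_id = model.clusters.index(c)
    return segments


def _round_half_down(x: float) -> int:
    return int(math.ceil(x - 0.5))


def correct_wgd(segments: list[Segment], model: SampleModel) -> tuple[list[Segment], SampleModel]:
    """Rescale an aneuploid-background sample to a diploid reference state.

    If the probe-weighted modal absolute CN is >= 4 (or more than half the
    probe mass sits at CN >= 4), the sample is treated as whole-genome
    duplicated: every CN is halved, rounding halves down, and the model is
    flagged ``wgd``.  A triploid background (modal CN 3) is likewise
    rescaled by 2/3 so the modal state reports CN 2, without the WGD flag;
    the detected ploidy stays available as ``detected_modal_cn`` /
    ``aneuploid``.  Idempotent; a diploid sample passes through unchanged.
    """
    if not model.usable:
        raise UnusableModelError(f"sample model unusable: {model.reason}")
    called = [s for s in segments if s.acn is not None]
    if not called:
        return segments, model
    weights: dict[int, float] = {}
    total = 0.0
    for s in called:
        weights[s.acn] = weights.get(s.acn, 0.0) + s.n_probes
        total += s.n_probes
    modal = max(weights, key=lambda k: weights[k])
    frac_ge4 = sum(v for k, v in weights.items() if k >= 4) / total
    if modal >= 4 or frac_ge4 > 0.5 or modal == 3:
        scale = 2.0 / (modal if modal >= 3 else 4)
        for s in called:
            s.acn = max(_round_half_down(s.acn * scale), 0)
            if s.minor_cn is not None:
                s.minor_cn = min(max(_round_half_down(s.minor_cn * scale), 0),
                                 s.acn // 2)
        for c in model.clusters:
            if c.cn is not None:
                c.cn = max(_round_half_down(c.cn * scale), 0)
                if c.minor is not None:
                    c.minor = min(max(_round_half_down(c.minor * scale), 0),
                                  c.cn // 2)
        if modal >= 4 or frac_ge4 > 0.5:
            model.wgd = True
        model.modal_cn = _round_half_down(modal * scale)
    return segments, model


def classify_scna(segment: Segment) -> str:
    """SCNA category from absolute CN: amplification (CN>=5), gain
    (3<=CN<5), loss (CN<=1), copy-neutral LOH (CN2 with no minor allele),
    else neutral."""
    if segment.acn is None:
        raise ValueError("segment has no absolute copy number assigned")
    acn = segment.acn
    if acn >= 5:
        cls = "amplification"
    elif acn >= 3:
        cls = "gain"
    elif acn <= 1:
        cls = "loss"
    elif segment.minor_cn == 0:
        cls = "cnLOH"
    else:
        cls = "neutral"
    segment.scna_class = cls
    return cls


def classify_segments(segments: list[Segment]) -> list[Segment]:
    for s in segments:
        classify_scna(s)
    return segments


def truth_segments(sample) -> list[Segment]:
    """Classified segments straight from a simulated sample's ground truth
    (for truth-level cohort statistics that do not need probe synthesis)."""
    spacing = sample.config.probe_spacing
    segs = []
    for ev in sample.truth:
        seg = Segment(
            chrom=ev.chrom, start=ev.start, end=ev.end,
            n_probes=max(ev.length // spacing if hasattr(ev, "length")
                         else (ev.end - ev.start + 1) // spacing, 1),
            mean_lrr=0.0, ai=0.0, acn=ev.total_cn, minor_cn=ev.minor_cn,
            sample_id=sample.sample_id,
        )
        classify_scna(seg)
        segs.append(seg)
    return segs
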
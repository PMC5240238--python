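"""Sub-clonality scoring of copy-number losses.

The idea: in the (LRR, allelic-imbalance) plane a loss carried by every
tumor cell sits at a fixed displacement from the diploid centroid, and a
loss carried by only a fraction of the tumor cells sits proportionally
closer.  The single-copy-loss segment most displaced from the diploid
centroid is taken as the clonal reference (assumed present in 100% of
tumor cells -- in the study cohort this is generally the 16q loss).  Every
other segment's displacement, expressed as a proportion of the reference
displacement, estimates the fraction of tumor cells carrying it.  A
per-sample noise threshold -- the 99th percentile of the proportions of
the segments called diploid -- separates real sub-clonal losses from
diploid scatter.

All distances are Euclidean in diploid-spread-standardised coordinates,
which makes the proportion invariant to rigid translation of the plane
and to common rescaling of both axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cn_calling import SampleModel
from .segmentation import Segment

_MIN_DIPLOID_SEGMENTS = 20
DEFAULT_CLONAL_MIN = 0.9
DEFAULT_PERCENTILE = 99.0


class NotScorableError(ValueError):
    """Sample cannot enter the sub-clonality analysis (no CN1 reference or
    too few diploid segments for a threshold)."""


@dataclass
class SubcloneCall:
    segment: Segment
    proportion: float
    threshold: float
    clonality: str  # diploid_noise | subclonal | clonal
    est_cell_fraction: float
    is_reference: bool = False


def _standardised_points(segments, model: SampleModel) -> np.ndarray:
    return np.array([model.standardise(s.point) for s in segments])


def select_reference_segment(segments: list[Segment], model: SampleModel) -> Segment:
    """The CN1 segment most displaced from the diploid centroid.

    'Lowest log2 ratio and highest allelic imbalance' are resolved as a
    single scalar -- maximum standardised Euclidean distance -- since both
    criteria grow monotonically with displacement."""
    cn1 = [s for s in segments if s.acn == 1]
    if not cn1:
        raise NotScorableError("no copy-number-1 segment to use as clonal reference")
    centroid = model.standardise(model.diploid_centroid)
    d = np.linalg.norm(_standardised_points(cn1, model) - centroid, axis=1)
    return cn1[int(np.argmax(d))]


def proportion_scores(
    segments: list[Segment], model: SampleModel, reference: Segment
) -> list[tuple[Segment, float]]:
    """Distance of each segment from the diploid centroid as a proportion
    of the reference segment's distance; the reference scores exactly 1."""
    centroid = model.standardise(model.diploid_centroid)
    ref_dist = float(np.linalg.norm(model.standardise(reference.point) - centroid))
    if ref_dist <= 0.0:
        raise NotScorableError("degenerate sample: reference coincides with diploid centroid")
    out = []
    for s in segments:
        if s is reference:
            out.append((s, 1.0))
        else:
            d = float(np.linalg.norm(model.standardise(s.point) - centroid))
            out.append((s, d / ref_dist))
    return out


def subclonality_threshold(diploid_proportions,
                           percentile: float = DEFAULT_PERCENTILE) -> float:
    """99th percentile (linear interpolation between order statistics) of
    the proportion scores of the segments the caller labelled diploid."""
    props = np.asarray(list(diploid_proportions), dtype=float)
    if props.size < _MIN_DIPLOID_SEGMENTS:
        raise NotScorableError(
            f"too few diploid segments ({props.size} < {_MIN_DIPLOID_SEGMENTS})")
    return float(np.percentile(props, percentile))


def _is_candidate_loss(seg: Segment, model: SampleModel, policy: str) -> bool:
    if seg.acn == 1:
        return True
    if policy == "cn1":
        return False
    centers = model.cluster_centers
    if 1 not in centers or 2 not in centers:
        return False
    lo, hi = sorted((centers[1][0], centers[2][0]))
    return lo < seg.mean_lrr < hi


def call_subclones(
    segments: list[Segment],
    model: SampleModel,
    reference: Segment | None = None,
    clonal_min: float = DEFAULT_CLONAL_MIN,
    candidate_policy: str = "intermediate",
    percentile: float = DEFAULT_PERCENTILE,
) -> list[SubcloneCall]:
    """Score candidate loss segments and classify their clonality.

    Candidates are segments called CN1, plus (under the default
    ``candidate_policy='intermediate'``) segments whose mean LRR falls
    between the CN1 and CN2 cluster centres -- losses too shallow for the
    caller to label CN1.  A proportion at or below the sample threshold is
    diploid noise; at or above ``clonal_min`` it is clonal; in between,
    sub-clonal.  ``clonal_min`` has no counterpart in the source
    procedure, which leaves the sub-clonal/clonal boundary undefined; 0.9
    is this package's documented default.  The estimated cell fraction is
    the proportion itself (the reference is assumed to be carried by all
    tumor cells), clipped to [0, 1].
    """
    if candidate_policy not in ("cn1", "intermediate"):
        raise ValueError("candidate_policy must be 'cn1' or 'intermediate'")
    if reference is None:
        reference = select_reference_segment(segments, model)
    scored = proportion_scores(segments, model, reference)
    # the noise distribution comes from the segments that belong to the
    # diploid cluster itself; CN2-labelled stragglers from other clusters
    # (e.g. shallow sub-clonal losses) must not widen the threshold
    did = model.diploid_cluster_id
    diploid_props = [p for s, p in scored if s is not reference
                     and ((s.cluster_id == did) if s.cluster_id is not None
                          else (s.acn == 2 and s.minor_cn != 0))]
    threshold = subclonality_threshold(diploid_props, percentile)

    calls = []
    for seg, prop in scored:
        if seg is not reference and not _is_candidate_loss(seg, model, candidate_policy):
            continue
        if seg is reference:
            clonality = "clonal"
        elif prop <= threshold:
            clonality = "diploid_noise"
        elif prop >= clonal_min:
            clonality = "clonal"
        else:
            clonality = "subclonal"
        calls.append(SubcloneCall(
            segment=seg, proportion=prop, threshold=threshold,
            clonality=clonality,
            est_cell_fraction=float(np.clip(prop, 0.0, 1.0)),
            is_reference=seg is reference,
        ))
    return calls


def count_subclonal_per_sample(calls: list[SubcloneCall]) -> int:
    """Number of sub-clonal loss segments in one sample's calls."""
    return sum(1 for c in calls if c.clonality == "subclonal")
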
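"""Cyclin D1 biomarker evaluation: Allred-style IHC scoring, CCND1 FISH
classification, and predictive-value / recurrence-association analysis.

IHC scores are inputs (read from a pathologist's sheet), never computed
from images.  The Allred-style total is a 0-5 stained-nuclei proportion
score plus a 0-3 intensity score, binned low (0-2), intermediate (3-5),
high (6-8).  FISH calls use the mean CCND1-to-CEP11 focus ratio over at
least 20 cells: gain for ratios in [1.5, 2.5], amplification above 2.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import FisherResult, fisher_2x2

# proportion-score bin upper edges; a boundary value takes the lower score
_PROPORTION_EDGES = (0.0, 1 / 100, 1 / 10, 1 / 3, 2 / 3)
HIGH_SCORE_MIN = 6


@dataclass(frozen=True)
class IHCScore:
    proportion_fraction: float
    proportion_score: int
    intensity: int
    total: int
    category: str  # low | intermediate | high


@dataclass(frozen=True)
class FISHCall:
    mean_ccnd1: float
    mean_cep11: float
    n_cells: int
    ratio: float
    category: str  # normal | gain | amplification


class InconsistentScoreError(ValueError):
    pass


def ihc_total_score(proportion_fraction: float, intensity: int) -> IHCScore:
    """Combine the stained-nuclei proportion and intensity into the
    Allred-style total and category.

    Proportion bins: 0 = none, 1 = <1/100, 2 = 1/100-1/10, 3 = 1/10-1/3,
    4 = 1/3-2/3, 5 = >2/3; exact boundary values fall into the lower bin.
    Intensity 0 with stained nuclei (or staining with none) is rejected as
    inconsistent."""
    if not 0.0 <= proportion_fraction <= 1.0:
        raise ValueError("proportion_fraction must be in [0, 1]")
    if intensity not in (0, 1, 2, 3):
        raise ValueError("intensity must be an integer 0-3")
    if (intensity > 0) != (proportion_fraction > 0):
        raise InconsistentScoreError(
            "intensity and stained-nuclei proportion disagree on whether "
            "any cell stains")
    pscore = 0
    for edge in _PROPORTION_EDGES:
        if proportion_fraction > edge:
            pscore += 1
    total = pscore + intensity
    category = "low" if total <= 2 else ("intermediate" if total <= 5 else "high")
    return IHCScore(proportion_fraction, pscore, intensity, total, category)


class InsufficientCellsError(ValueError):
    pass


def fish_classify(ccnd1_counts, cep11_counts) -> FISHCall:
    """Classify CCND1 status from per-cell focus counts (>= 20 cells)."""
    ccnd1 = np.asarray(ccnd1_counts, dtype=float)
    cep11 = np.asarray(cep11_counts, dtype=float)
    n = min(ccnd1.size, cep11.size)
    if n < 20:
        raise InsufficientCellsError(f"need >= 20 scored cells, got {n}")
    mean_ccnd1 = float(ccnd1.mean())
    mean_cep11 = float(cep11.mean())
    if mean_cep11 <= 0:
        raise ValueError("CEP11 mean count must be positive")
    ratio = mean_ccnd1 / mean_cep11
    if ratio > 2.5:
        category = "amplification"
    elif ratio >= 1.5:
        category = "gain"  # a ratio of exactly 2.5 is gain, not amplification
    else:
        category = "normal"
    return FISHCall(mean_ccnd1, mean_cep11, int(n), ratio, category)


def predictive_values(tp: int, fp: int, fn: int, tn: int) -> tuple[float | None, float | None]:
    """PPV and NPV of a binary marker for recurrence, as percentages
    rounded to the nearest integer.  An empty stratum yields None.
    Contralateral events must be excluded upstream (they do not represent
    clonal progression of the index lesion)."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    ppv = round(100.0 * tp / (tp + fp)) if tp + fp > 0 else None
    npv = round(100.0 * tn / (tn + fn)) if tn + fn > 0 else None
    return ppv, npv


def recurrence_association(marker_positive, recurred) -> FisherResult:
    """Fisher exact test of a binary marker against recurrence.

    Inputs are parallel boolean sequences (one entry per analysed
    patient)."""
    marker = np.asarray(marker_positive, dtype=bool)
    outcome = np.asarray(recurred, dtype=bool)
    if marker.shape != outcome.shape:
        raise ValueError("marker and outcome must have equal length")
    a = int(np.sum(marker & outcome))
    b = int(np.sum(~marker & outcome))
    c = int(np.sum(marker & ~outcome))
    d = int(np.sum(~marker & ~outcome))
    return fisher_2x2(a, b, c, d)


def confusion_from_calls(marker_positive, recurred) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) counts from boolean marker/outcome sequences."""
    marker = np.asarray(marker_positive, dtype=bool)
    outcome = np.asarray(recurred, dtype=bool)
    tp = int(np.sum(marker & outcome))
    fp = int(np.sum(marker & ~outcome))
    fn = int(np.sum(~marker & outcome))
    tn = int(np.sum(~marker & ~outcome))
    return tp, fp, fn, tn
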
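"""Parameter-recovery experiments on simulated cohorts.

Each experiment generates data with known ground truth, runs the relevant
pipeline stages end to end, and reports recovery metrics.  These are the
package's evidence that the copy-number caller and the sub-clonality
procedure recover what the generator put in; the test suite and the
acceptance script both run them.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from .cn_calling import (assign_absolute_cn, classify_segments, correct_wgd,
                         fit_sample_model)
from .genome import CHROMOSOMES, REGIONS
from .segmentation import Segment, segment_probes
from .subclones import NotScorableError, call_subclones
from .synthetic import (EventSpec, GroupProfile, SimulationConfig, TruthEvent,
                        make_event, simulate_cohort, simulate_microdissection,
                        simulate_sample)


def _truth_cn_for_segment(seg: Segment, truth, baseline: int) -> int:
    """Ground-truth total CN over a called segment: the CN of the event
    with majority overlap, else the baseline ploidy."""
    best_cn, best_ov = baseline, 0
    for ev in truth:
        if ev.chrom != seg.chrom:
            continue
        ov = min(seg.end, ev.end) - max(seg.start, ev.start) + 1
        if ov > best_ov:
            best_ov, best_cn = ov, ev.total_cn
    if best_ov * 2 < (seg.end - seg.start + 1):
        return baseline
    return best_cn


def _clonal_profile() -> GroupProfile:
    """Clonal-only event profile for copy-number recovery runs: every
    sample has the anchor loss and gain, plus recurrent optional events."""
    return GroupProfile((
        EventSpec(("16q_loss",), 1.0),
        EventSpec(("1q_gain",), 1.0),
        EventSpec(("17p_loss",), 0.3),
        EventSpec(("16p_gain",), 0.3),
        EventSpec(("8p23_loss",), 0.2),
        EventSpec(("22q13_loss",), 0.2),
        EventSpec(("11q13_amp",), 0.2),
        EventSpec(("6q_loss",), 0.3),
    ))


def cn_recovery_experiment(n_samples: int = 50, seed: int = 0,
                           purity_range=(0.5, 0.9),
                           min_probes_eval: int = 50) -> dict:
    """Absolute-CN recovery on clonal simulated samples.

    Returns the fraction of called segments (>= ``min_probes_eval``
    probes, usable samples only) whose absolute CN matches the ground
    truth, plus bookkeeping counts."""
    cohort = simulate_cohort({"sim": _clonal_profile()}, n_samples, seed=seed,
                             purity_range=purity_range)
    n_correct = n_total = n_excluded = 0
    for sample in cohort.samples:
        probes = sample.probes()
        segs = segment_probes(probes, sample_id=sample.sample_id)
        model = fit_sample_model(segs)
        if not model.usable:
            n_excluded += 1
            continue
        assign_absolute_cn(segs, model)
        correct_wgd(segs, model)
        for s in segs:
            if s.n_probes < min_probes_eval:
                continue
            truth_cn = _truth_cn_for_segment(s, sample.truth, 2)
            n_total += 1
            n_correct += int(s.acn == truth_cn)
    return {
        "accuracy": n_correct / n_total if n_total else float("nan"),
        "n_segments": n_total,
        "n_samples": n_samples,
        "n_excluded": n_excluded,
    }


_SUBCLONAL_LOSS_REGIONS = ("17p", "6q14-27", "22q13", "8p23")


def subclone_recovery_experiment(n_samples: int = 30, seed: int = 0,
                                 purity: float = 0.8,
                                 subclone_fraction: float = 0.6,
                                 clonal_min: float = 0.9) -> dict:
    """Sensitivity/specificity of the sub-clonality caller.

    Each sample carries the clonal reference losses (16q, always clonal)
    plus losses at ``subclone_fraction`` of the tumor cells on four other
    regions.  Reports the fraction of truth-sub-clonal loss segments
    called sub-clonal and the fraction of truth-clonal losses mis-called
    sub-clonal."""
    rng = np.random.default_rng(seed)
    subclonal_hits = subclonal_total = 0
    clonal_miscalls = clonal_total = 0
    n_excluded = 0
    for i in range(n_samples):
        events = [make_event("16q_loss", purity), make_event("1q_gain", purity)]
        truth_frac = {}
        for region in _SUBCLONAL_LOSS_REGIONS:
            r = REGIONS[region]
            events.append(TruthEvent(r.chrom, r.start, r.end, 1, 0,
                                     purity * subclone_fraction, name=region))
            truth_frac[(r.chrom, r.start)] = subclone_fraction
        config = SimulationConfig(purity=purity, events=tuple(events),
                                  seed=int(rng.integers(2**31)))
        probes, truth = simulate_sample(config)
        segs = segment_probes(probes)
        model = fit_sample_model(segs)
        if not model.usable:
            n_excluded += 1
            continue
        assign_absolute_cn(segs, model)
        correct_wgd(segs, model)
        classify_segments(segs)
        try:
            calls = call_subclones(segs, model, clonal_min=clonal_min)
        except NotScorableError:
            n_excluded += 1
            continue
        for c in calls:
            ev = _matching_event(c.segment, truth)
            if ev is None or ev.total_cn != 1:
                continue
            if ev.cell_fraction < purity:  # truth sub-clonal
                subclonal_total += 1
                subclonal_hits += int(c.clonality == "subclonal")
            else:
                clonal_total += 1
                clonal_miscalls += int(c.clonality == "subclonal")
    return {
        "sensitivity": subclonal_hits / subclonal_total if subclonal_total else float("nan"),
        "clonal_miscall_rate": (clonal_miscalls / clonal_total
                                if clonal_total else float("nan")),
        "n_subclonal_truth": subclonal_total,
        "n_clonal_truth": clonal_total,
        "n_excluded": n_excluded,
    }


def _matching_event(seg: Segment, truth):
    best, best_ov = None, 0
    for ev in truth:
        if ev.chrom != seg.chrom:
            continue
        ov = min(seg.end, ev.end) - max(seg.start, ev.start) + 1
        if ov > best_ov:
            best_ov, best = ov, ev
    if best is not None and best_ov * 2 >= (seg.end - seg.start + 1):
        return best
    return None


_SWEEP_CHROMS = ["chr2", "chr3", "chr4", "chr5", "chr7", "chr9", "chr10",
                 "chr12", "chr13", "chr14", "chr15", "chr18", "chr21"]


def fraction_sweep_experiment(n_samples: int = 16, seed: int = 0,
                              purity: float = 0.9,
                              fractions=(0.2, 1.0)) -> dict:
    """Monotonicity of the estimated cell fraction.

    Each sample carries a q-arm loss on thirteen chromosomes at tumor-cell
    fractions spread over ``fractions``, alongside the clonal 16q
    reference; Spearman correlation between the truth fraction and the
    estimated cell fraction is computed over all matched loss segments."""
    rng = np.random.default_rng(seed)
    truths, estimates = [], []
    for i in range(n_samples):
        events = [make_event("16q_loss", purity), make_event("1q_gain", purity)]
        for chrom in _SWEEP_CHROMS:
            frac = rng.uniform(*fractions)
            length, cen = CHROMOSOMES[chrom]
            events.append(TruthEvent(chrom, cen + 1, length, 1, 0,
                                     purity * frac))
        config = SimulationConfig(purity=purity, events=tuple(events),
                                  seed=int(rng.integers(2**31)))
        probes, truth = simulate_sample(config)
        segs = segment_probes(probes)
        model = fit_sample_model(segs)
        if not model.usable:
            continue
        assign_absolute_cn(segs, model)
        correct_wgd(segs, model)
        classify_segments(segs)
        try:
            calls = call_subclones(segs, model)
        except NotScorableError:
            continue
        for c in calls:
            ev = _matching_event(c.segment, truth)
            if ev is None or ev.total_cn != 1 or c.is_reference:
                continue
            truths.append(ev.cell_fraction / purity)
            estimates.append(c.est_cell_fraction)
    rho = spearmanr(truths, estimates).statistic if len(truths) > 2 else float("nan")
    return {"spearman_rho": float(rho), "n_segments": len(truths)}


def diploid_specificity_experiment(n_samples: int = 20, seed: int = 0,
                                   purity_range=(0.5, 0.9)) -> dict:
    """Fraction of truth-diploid segments whose proportion score exceeds
    the per-sample 99th-percentile threshold.

    By construction of a linearly interpolated percentile, a sample with n
    diploid segments has at most ~0.01*n + 1 exceeders, so the pooled
    fraction carries a deterministic small-sample excess of about
    n_samples / total; both the raw fraction and that bound are
    reported."""
    cohort = simulate_cohort({"sim": _clonal_profile()}, n_samples, seed=seed,
                             purity_range=purity_range)
    n_exceed = n_diploid = 0
    n_scored_samples = 0
    for sample in cohort.samples:
        probes = sample.probes()
        segs = segment_probes(probes)
        model = fit_sample_model(segs)
        if not model.usable:
            continue
        assign_absolute_cn(segs, model)
        correct_wgd(segs, model)
        classify_segments(segs)
        try:
            calls = call_subclones(segs, model, candidate_policy="intermediate")
        except NotScorableError:
            continue
        n_scored_samples += 1
        threshold = calls[0].threshold
        from .subclones import proportion_scores, select_reference_segment
        ref = select_reference_segment(segs, model)
        for s, prop in proportion_scores(segs, model, ref):
            if s is ref:
                continue
            if _truth_cn_for_segment(s, sample.truth, 2) != 2:
                continue
            if any(ev.chrom == s.chrom and s.start <= ev.end and ev.start <= s.end
                   for ev in sample.truth):
                continue  # straddles an event boundary; CN truth ambiguous
            n_diploid += 1
            n_exceed += int(prop > threshold)
    frac = n_exceed / n_diploid if n_diploid else float("nan")
    slack = n_scored_samples / n_diploid if n_diploid else float("nan")
    return {"exceed_fraction": frac, "n_diploid": n_diploid,
            "n_samples_scored": n_scored_samples,
            "small_sample_bound": 0.01 + slack}


def wgd_correction_experiment(seed: int = 0) -> dict:
    """Modal CN after diploid-state correction for simulated triploid and
    tetraploid (whole-genome duplicated) samples.

    The tetraploid genome carries a pre-duplication 16q loss (CN2 minor 0
    after doubling), a doubled 1q gain (CN6) and post-duplication
    single-copy arm losses -- the signature that makes duplication
    identifiable at all."""
    rng = np.random.default_rng(seed)
    r16, r1, r17, r6 = (REGIONS[k] for k in ("16q", "1q", "17p", "6q14-27"))
    out = {}
    tri = SimulationConfig(purity=0.85, baseline_ploidy=3,
                           seed=int(rng.integers(2**31)), events=(
        TruthEvent(r16.chrom, r16.start, r16.end, 2, 1, 0.85),
        TruthEvent(r1.chrom, r1.start, r1.end, 4, 1, 0.85)))
    tet = SimulationConfig(purity=0.85, baseline_ploidy=4,
                           seed=int(rng.integers(2**31)), events=(
        TruthEvent(r16.chrom, r16.start, r16.end, 2, 0, 0.85),
        TruthEvent(r1.chrom, r1.start, r1.end, 6, 2, 0.85),
        TruthEvent(r17.chrom, r17.start, r17.end, 3, 1, 0.85),
        TruthEvent(r6.chrom, r6.start, r6.end, 3, 1, 0.85)))
    for name, config in (("triploid", tri), ("tetraploid", tet)):
        probes, _ = simulate_sample(config)
        segs = segment_probes(probes)
        model = fit_sample_model(segs)
        if not model.usable:
            out[name] = {"usable": False, "reason": model.reason}
            continue
        assign_absolute_cn(segs, model)
        correct_wgd(segs, model)
        weights: dict[int, int] = {}
        for s in segs:
            weights[s.acn] = weights.get(s.acn, 0) + s.n_probes
        out[name] = {
            "usable": True,
            "modal_cn_after_correction": max(weights, key=lambda k: weights[k]),
            "detected_modal_cn": model.detected_modal_cn,
            "wgd_flag": model.wgd,
            "aneuploid": model.aneuploid,
        }
    return out


def microdissection_experiment(n_events: int = 50, n_regions: int = 10,
                               seed: int = 0, fractions=(0.6, 0.8)) -> dict:
    """Emulated microsatellite validation: sub-clonal losses at cell
    fraction p show LOH in a binomial fraction of microdissected regions.

    Returns the mean absolute deviation between each event's truth
    fraction and its observed LOH fraction, and the fraction of events
    whose observed LOH rate falls inside the exact binomial 99% interval."""
    from scipy.stats import binom
    rng = np.random.default_rng(seed)
    devs, inside = [], 0
    for _ in range(n_events):
        p = rng.uniform(*fractions)
        loh = simulate_microdissection(p, n_regions, rng)
        k = int(loh.sum())
        devs.append(abs(k / n_regions - p))
        lo, hi = binom.ppf(0.005, n_regions, p), binom.ppf(0.995, n_regions, p)
        inside += int(lo <= k <= hi)
    return {"mean_abs_deviation": float(np.mean(devs)),
            "fraction_in_binomial_99ci": inside / n_events}
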
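"""Synthetic SNP-array cohort generator with known ground truth.

Emulates molecular-inversion-probe array data from macrodissected lobular
carcinoma in situ / invasive lobular carcinoma samples: per-probe log-R
ratio (LRR, log2 total-intensity ratio) and B-allele frequency (BAF), for
samples carrying clonal and sub-clonal somatic copy-number aberrations at
known tumor purity, occasionally on a triploid or tetraploid (whole-genome
duplicated) background.

The signal model is the standard two-population mixture: a probe inside an
event carried by a cell fraction ``f`` (tumor purity x sub-clone fraction)
measures a DNA mixture ``f*cn + (1-f)*2``.  LRR is the log2 ratio of that
mixture to the sample's baseline mixture (so the modal ploidy sits at
LRR = 0, as array normalisation enforces); BAF at germline-heterozygous
probes is the B-allele share of the mixture, mirror-symmetrised because
either haplotype may carry the B allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import CHROMOSOMES, REGIONS

PROBE_COLUMNS = ["chrom", "pos", "lrr", "baf", "is_het"]

# FFPE-like defaults: heavy LRR noise, tight BAF bands, and slowly varying
# baseline waves (the GC/fixation artifact that fragments real array
# segmentation into hundreds of segments per genome).
DEFAULT_LRR_SD = 0.25
DEFAULT_BAF_SD = 0.03
DEFAULT_WAVE_SD = 0.13
DEFAULT_WAVE_LENGTH = 20  # autocorrelation length, in probes
DEFAULT_PROBE_SPACING = 50_000
DEFAULT_HET_FRACTION = 0.3

# floor for the DNA mixture before taking log2 (homozygous deletion at
# purity 1 would otherwise be -inf); chosen far below any callable state
_MIXTURE_FLOOR = 0.05


@dataclass(frozen=True)
class TruthEvent:
    """A latent copy-number event carried by a fraction of sampled cells.

    ``cell_fraction`` is the fraction of ALL cells in the specimen carrying
    the event, i.e. tumor purity times the sub-clone fraction within the
    tumor; a clonal event in a purity-0.8 sample has cell_fraction 0.8.
    """

    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int
    cell_fraction: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("event end < start")
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.minor_cn > self.total_cn - self.minor_cn:
            raise ValueError("minor_cn exceeds total_cn - minor_cn")
        if not 0.0 < self.cell_fraction <= 1.0:
            raise ValueError("cell_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Per-sample generator settings; ``baseline_ploidy`` 3 or 4 simulates
    an aneuploid/whole-genome-duplicated background."""

    purity: float = 0.7
    events: tuple[TruthEvent, ...] = ()
    baseline_ploidy: int = 2
    probe_spacing: int = DEFAULT_PROBE_SPACING
    het_probe_fraction: float = DEFAULT_HET_FRACTION
    lrr_sd: float = DEFAULT_LRR_SD
    baf_sd: float = DEFAULT_BAF_SD
    wave_sd: float = DEFAULT_WAVE_SD       # 0 disables baseline waves
    wave_length: int = DEFAULT_WAVE_LENGTH
    seed: int = 0
    chromosomes: tuple[tuple[str, int], ...] = tuple(
        (c, length) for c, (length, _cen) in CHROMOSOMES.items()
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")
        if self.lrr_sd <= 0 or self.baf_sd <= 0:
            raise ValueError("noise standard deviations must be > 0")
        if self.baseline_ploidy not in (2, 3, 4):
            raise ValueError("baseline_ploidy must be 2, 3 or 4")
        _check_non_overlapping(self.events)

    @property
    def wgd(self) -> bool:
        return self.baseline_ploidy >= 4


def _check_non_overlapping(events: tuple[TruthEvent, ...]) -> None:
    by_chrom: dict[str, list[TruthEvent]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for evs in by_chrom.values():
        evs = sorted(evs, key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping events on {a.chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


def expected_lrr(total_cn: int, cell_fraction: float, baseline_cn: int = 2) -> float:
    """Noise-free log-R ratio of a copy-number state diluted to cell_fraction.

    log2((f*cn + (1-f)*base) / base); 0 for the baseline state, -1 for a
    pure single-copy loss on a diploid baseline.
    """
    if total_cn < 0 or baseline_cn <= 0:
        raise ValueError("copy numbers must be non-negative (baseline > 0)")
    if not 0.0 <= cell_fraction <= 1.0:
        raise ValueError("cell_fraction must be in [0, 1]")
    mixture = cell_fraction * total_cn + (1.0 - cell_fraction) * baseline_cn
    if mixture <= 0.0:
        return -math.inf
    return math.log2(mixture / baseline_cn)


def expected_baf(total_cn: int, minor_cn: int, cell_fraction: float) -> float:
    """Noise-free B-allele frequency at a germline-heterozygous probe,
    taking the minor haplotype as the B allele (1 of the 2 normal copies).

    Returns 0.5 by convention when the mixture has no DNA (homozygous
    deletion at cell fraction 1)."""
    if total_cn < 0 or minor_cn < 0:
        raise ValueError("copy numbers must be non-negative")
    if minor_cn > total_cn - minor_cn:
        raise ValueError("minor_cn exceeds total_cn - minor_cn")
    if not 0.0 <= cell_fraction <= 1.0:
        raise ValueError("cell_fraction must be in [0, 1]")
    denom = cell_fraction * total_cn + (1.0 - cell_fraction) * 2.0
    if denom == 0.0:
        return 0.5
    return (cell_fraction * minor_cn + (1.0 - cell_fraction) * 1.0) / denom


def _baseline_wave(rng: np.random.Generator, n: int, sd: float, length: int) -> np.ndarray:
    """Slowly varying LRR baseline artifact: white noise smoothed with a
    Gaussian kernel of the given autocorrelation length, rescaled to the
    requested marginal standard deviation."""
    half = 3 * length
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / length) ** 2)
    kernel /= np.sqrt(np.sum(kernel**2))
    white = rng.normal(0.0, 1.0, n + 2 * half)
    return sd * np.convolve(white, kernel, mode="valid")[:n]


def simulate_sample(config: SimulationConfig) -> tuple[pd.DataFrame, list[TruthEvent]]:
    """Generate probe-level measurements for one sample.

    Probes tile each chromosome at ``probe_spacing``; LRR is the mixture
    log-ratio against the sample baseline plus Gaussian noise, and BAF at
    heterozygous probes is the mirror-symmetrised expected BAF plus noise,
    clipped to [0, 1].  Deterministic for a fixed ``config.seed``.

    Returns the probe table (columns chrom, pos, lrr, baf, is_het) and the
    truth events verbatim.
    """
    rng = np.random.default_rng(config.seed)
    f0 = config.purity
    base = config.baseline_ploidy
    # baseline DNA mixture the array normalises against (modal state -> LRR 0)
    m_base = f0 * base + (1.0 - f0) * 2.0
    base_minor = base // 2

    frames = []
    truth = list(config.events)
    for chrom, length in config.chromosomes:
        pos = np.arange(config.probe_spacing, length + 1, config.probe_spacing)
        n = pos.size
        total = np.full(n, float(base))
        minor = np.full(n, float(base_minor))
        frac = np.full(n, f0)
        for ev in truth:
            if ev.chrom != chrom:
                continue
            sel = (pos >= ev.start) & (pos <= ev.end)
            total[sel] = ev.total_cn
            minor[sel] = ev.minor_cn
            frac[sel] = ev.cell_fraction

        mixture = np.maximum(frac * total + (1.0 - frac) * 2.0, _MIXTURE_FLOOR)
        lrr = np.log2(mixture / m_base) + rng.normal(0.0, config.lrr_sd, n)
        if config.wave_sd > 0:
            lrr += _baseline_wave(rng, n, config.wave_sd, config.wave_length)

        is_het = rng.random(n) < config.het_probe_fraction
        b = (frac * minor + (1.0 - frac)) / mixture
        mirror = rng.random(n) < 0.5
        b = np.where(mirror, 1.0 - b, b)
        hom = np.where(rng.random(n) < 0.5, 0.0, 1.0)
        baf = np.where(is_het, b, hom) + rng.normal(0.0, config.baf_sd, n)
        baf = np.clip(baf, 0.0, 1.0)

        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "lrr": lrr, "baf": baf, "is_het": is_het,
        }))
    probes = pd.concat(frames, ignore_index=True)
    return probes, truth


# ---------------------------------------------------------------------------
# cohort-level simulation

# template name -> (region, total_cn, minor_cn); cell fraction filled at draw
EVENT_TEMPLATES: dict[str, tuple[str, int, int]] = {
    "16q_loss": ("16q", 1, 0),
    "16q_cnloh": ("16q", 2, 0),
    "1q_gain": ("1q", 3, 1),
    "1q_cnloh": ("1q", 2, 0),
    "16p_gain": ("16p", 3, 1),
    "19p_gain": ("19p", 3, 1),
    "17p_loss": ("17p", 1, 0),
    "6q_loss": ("6q14-27", 1, 0),
    "8p23_loss": ("8p23", 1, 0),
    "22q13_loss": ("22q13", 1, 0),
    "11q13_gain": ("11q13", 4, 1),
    "11q13_amp": ("11q13", 6, 1),
    "rab11fip4_gain": ("17q11-RAB11FIP4", 3, 1),
    "macrod2_gain": ("20p12-MACROD2", 3, 1),
    "klf8_gain": ("Xp11-KLF8", 3, 1),
}


def make_event(template: str, cell_fraction: float) -> TruthEvent:
    """Instantiate a named event template at a given cell fraction."""
    if template not in EVENT_TEMPLATES:
        raise KeyError(f"unknown event template: {template!r}")
    region_name, cn, minor = EVENT_TEMPLATES[template]
    region = REGIONS[region_name]
    return TruthEvent(region.chrom, region.start, region.end, cn, minor,
                      cell_fraction, name=template)


@dataclass(frozen=True)
class EventSpec:
    """One event slot in a group profile: drawn with probability
    ``frequency``; mutually exclusive ``templates`` alternatives are chosen
    with ``weights``; a sub-clonal slot draws its within-tumor fraction
    uniformly from ``subclone_range`` (clonal events use 1.0)."""

    templates: tuple[str, ...]
    frequency: float
    weights: tuple[float, ...] | None = None
    subclone_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must be in [0, 1]")
        for t in self.templates:
            if t not in EVENT_TEMPLATES:
                raise KeyError(f"unknown event template: {t!r}")


@dataclass(frozen=True)
class GroupProfile:
    events: tuple[EventSpec, ...]
    triploid_prob: float = 0.0
    tetraploid_prob: float = 0.0


@dataclass
class SimulatedSample:
    sample_id: str
    group: str
    config: SimulationConfig

    @property
    def truth(self) -> list[TruthEvent]:
        return list(self.config.events)

    @property
    def purity(self) -> float:
        return self.config.purity

    def probes(self) -> pd.DataFrame:
        """Synthesise the probe table (deterministic per-sample seed)."""
        return simulate_sample(self.config)[0]


@dataclass
class Cohort:
    samples: list[SimulatedSample]

    def __len__(self) -> int:
        return len(self.samples)

    def groups(self) -> pd.Series:
        return pd.Series({s.sample_id: s.group for s in self.samples}, name="group")


def _coerce_profile(profile) -> GroupProfile:
    if isinstance(profile, GroupProfile):
        return profile
    if isinstance(profile, dict):  # shorthand: {template: frequency}
        return GroupProfile(tuple(
            EventSpec((name,), freq) for name, freq in profile.items()
        ))
    raise TypeError("group profile must be a GroupProfile or {template: freq} dict")


def simulate_cohort(
    group_profiles: dict,
    n_per_group: int | dict[str, int],
    seed: int = 0,
    purity_range: tuple[float, float] = (0.3, 0.9),
    **config_kwargs,
) -> Cohort:
    """Draw a cohort: each sample independently realises its group profile.

    ``n_per_group`` is a single count or a per-group mapping.  Probe
    synthesis is deferred (``sample.probes()``), so large cohorts can be
    drawn for truth-level statistics at no cost.  Purity is uniform on
    ``purity_range``; each sample receives its own deterministic sub-seed.
    """
    rng = np.random.default_rng(seed)
    samples = []
    for group, raw_profile in group_profiles.items():
        profile = _coerce_profile(raw_profile)
        n_group = n_per_group[group] if isinstance(n_per_group, dict) else n_per_group
        for i in range(n_group):
            purity = rng.uniform(*purity_range)
            u = rng.random()
            ploidy = 2
            if u < profile.tetraploid_prob:
                ploidy = 4
            elif u < profile.tetraploid_prob + profile.triploid_prob:
                ploidy = 3
            events = []
            for spec in profile.events:
                if rng.random() >= spec.frequency:
                    continue
                if len(spec.templates) == 1:
                    template = spec.templates[0]
                else:
                    p = np.asarray(spec.weights, dtype=float) if spec.weights else None
                    if p is not None:
                        p = p / p.sum()
                    template = rng.choice(spec.templates, p=p)
                sub = 1.0
                if spec.subclone_range is not None:
                    sub = rng.uniform(*spec.subclone_range)
                events.append(make_event(str(template), purity * sub))
            sub_seed = int(rng.integers(2**31))
            config = SimulationConfig(
                purity=purity, events=tuple(events), baseline_ploidy=ploidy,
                seed=sub_seed, **config_kwargs,
            )
            samples.append(SimulatedSample(f"{group}-{i:03d}", group, config))
    return Cohort(samples)


def study_profiles(subclone_ranges: bool = True) -> dict[str, GroupProfile]:
    """Default cohort profiles emulating the three study groups.

    Frequencies follow the reported cohort: 16q loss/cnLOH in all in-situ
    samples, 1q gain/cnLOH in ~78-89%, recurrent arm gains/losses at their
    reported counts, small focal gains private to the pure in-situ group,
    and 6q/8p23/22q13 losses plus 11q13 gain/amplification rising toward
    invasive disease.  Sub-clonal loss slots use within-tumor fractions of
    0.3-0.8, the range supported by the microdissection validation.
    """
    sub = (0.3, 0.8) if subclone_ranges else None

    def spec(templates, freq, weights=None, subclone=False):
        return EventSpec(tuple(templates), freq, weights,
                         sub if subclone else None)

    pure = GroupProfile((
        spec(["16q_loss", "16q_cnloh"], 1.0, (0.85, 0.15)),
        spec(["1q_gain", "1q_cnloh"], 0.78, (0.9, 0.1)),
        spec(["16p_gain"], 8 / 27),
        spec(["19p_gain"], 9 / 27),
        spec(["17p_loss"], 7 / 27),
        spec(["klf8_gain"], 10 / 27),
        spec(["macrod2_gain"], 6 / 27),
        spec(["rab11fip4_gain"], 5 / 27),
        spec(["8p23_loss"], 1 / 27),
        spec(["22q13_loss"], 2 / 27),
        spec(["6q_loss"], 0.15, subclone=True),
    ), triploid_prob=3 / 27)
    inv = GroupProfile((
        spec(["16q_loss", "16q_cnloh"], 1.0, (0.85, 0.15)),
        spec(["1q_gain", "1q_cnloh"], 0.89, (0.9, 0.1)),
        spec(["16p_gain"], 5 / 28),
        spec(["19p_gain"], 6 / 28),
        spec(["17p_loss"], 8 / 28),
        spec(["8p23_loss"], 2 / 28),
        spec(["22q13_loss"], 4 / 28),
        spec(["11q13_gain", "11q13_amp"], 4 / 28, (0.5, 0.5)),
        spec(["6q_loss"], 0.25, subclone=True),
    ))
    cilc = GroupProfile((
        spec(["16q_loss", "16q_cnloh"], 24 / 25, (0.85, 0.15)),
        spec(["1q_gain", "1q_cnloh"], 0.84, (0.9, 0.1)),
        spec(["16p_gain"], 9 / 25),
        spec(["19p_gain"], 2 / 25),
        spec(["17p_loss"], 12 / 25),
        spec(["8p23_loss"], 9 / 25),
        spec(["22q13_loss"], 13 / 25),
        spec(["11q13_gain", "11q13_amp"], 6 / 25, (1 / 6, 5 / 6)),
        spec(["6q_loss"], 10 / 25, subclone=True),
    ))
    return {"pure-cLCIS": pure, "inv-cLCIS": inv, "cILC": cilc}


def simulate_microdissection(
    cell_fraction: float, n_regions: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Emulate microsatellite LOH typing of microdissected regions: each
    region is dominated by cells carrying the loss with probability equal
    to the event's cell fraction.  Returns a boolean LOH call per region."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not 0.0 <= cell_fraction <= 1.0:
        raise ValueError("cell_fraction must be in [0, 1]")
    return rng.random(n_regions) < cell_fraction


def write_probe_tsv(path, probes: pd.DataFrame, config: SimulationConfig | None = None) -> None:
    """Write a probe table with the generator settings echoed as # header lines."""
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# seed={config.seed} purity={config.purity:.4f} "
                     f"baseline_ploidy={config.baseline_ploidy} "
                     f"lrr_sd={config.lrr_sd} baf_sd={config.baf_sd} "
                     f"probe_spacing={config.probe_spacing}\n")
        probes.to_csv(fh, sep="\t", index=False)
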
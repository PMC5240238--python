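# Methods

## Signal model

A SNP-array probe measures a DNA mixture.  For a locus at total copy
number `cn` carried by a cell fraction `f` (tumor purity × within-tumor
sub-clone fraction) in an otherwise diploid specimen, the mixture is
`m = f·cn + (1−f)·2`.  The log-R ratio is `LRR = log2(m / m_baseline)`,
where `m_baseline` is the mixture of the sample's modal state — array
normalisation pins the modal ploidy at LRR 0, which is why a fully
duplicated genome does not simply shift upward.  At germline-heterozygous
probes the B-allele frequency is the B-allele share of the mixture,
`BAF = (f·minor + (1−f)) / m`, mirror-symmetrised because either
haplotype may carry the B allele.  Segment-level allelic imbalance is
summarised as `AI = 2·median(|BAF − 0.5|)` over het probes: ~0 for
balanced segments, ~1 for clonal LOH.  (Folding before aggregating is
required; under mirror symmetry the median of raw BAF is 0.5 for every
segment, so a median-then-fold statistic would be degenerate.)

In this plane each absolute CN state of a sample with purity `f` has a
predictable position — CN1 at `(log2(1−f/2), f/(2−f))`, balanced CN2 at
`(0, ~0)`, copy-neutral LOH at `(0, f)`, CN3 at `(log2(1+f/2), f/(2+f))`
— which is what both the CN caller and the sub-clonality score exploit.

## Synthetic data generator

The generator emulates FFPE material hybridised to a
molecular-inversion-probe array, on a 23-chromosome hg19-scale genome
(autosomes + X) tiled at 50 kb (~62,000 probes):

| parameter | default | meaning |
|---|---|---|
| `lrr_sd` | 0.25 | per-probe LRR noise (FFPE-grade) |
| `baf_sd` | 0.03 | per-probe BAF noise |
| `wave_sd`, `wave_length` | 0.13, 20 probes | autocorrelated LRR baseline waves (GC/fixation artifact) |
| `het_probe_fraction` | 0.3 | germline-heterozygous probes |
| `probe_spacing` | 50 kb | uniform tiling |
| purity | uniform 0.3–0.9 | cohort draw; per-sample scalar |
| sub-clone fractions | 0.3–0.8 of tumor | range supported by the microdissection validation |

The baseline waves matter: real array data segments into hundreds of
fragments per genome, and the per-sample 99th-percentile threshold of
the sub-clonality procedure presupposes a diploid-proportion
distribution of that size.  With waves the segmenter produces ~150–250
segments per sample; without them (set `wave_sd=0`, used by the tests
that check the pure mixture model) a quiet genome yields one segment per
chromosome and a 99th percentile of ~25 values would be meaningless.

Cohort profiles encode the three study groups' event frequencies
(universal 16q loss or cnLOH; 1q gain in 78/89/84%; 16p/19p gains and
17p loss at their reported counts; KLF8/MACROD2/RAB11FIP4 focal gains
private to pure LCIS; 6q/8p23/22q13 losses and 11q13 gain/amplification
rising toward invasive disease; ~11% triploid backgrounds in the pure
group).  Focal templates are padded to ≥2 Mb so they stay resolvable at
50 kb spacing.  What the generator does **not** model: GC-content
dependence of individual probes, genotyping error, FFPE fragment-length
artifacts, germline CNVs, or multi-band BAF structure at CN ≥ 4 (AI is a
folded scalar).  Passing recovery tests therefore demonstrate
correctness of the analysis chain under the mixture model, not
robustness to every artifact of real arrays.

## Segmentation

Penalised recursive binary splitting on two standardised channels
(per-probe LRR; folded BAF over het probes), with a minimum of 10 probes
per segment.  Each channel is scaled by a robust noise estimate from
median absolute first differences, making the penalty noise-free-scale.
A split is accepted when the residual-sum-of-squares reduction exceeds
the penalty; when no single split qualifies, an interior-window carve-out
(windows of doubling widths) is tried so that focal events flanked by
identical levels — amplicons — are still found.  The greedy split tree
is nested, so lowering the penalty can only add breakpoints.

The penalty default, `6·ln(n)` per chromosome of `n` probes, is a free
parameter of this package (the segmentation threshold of the platform
software it stands in for is not public).  It was set to keep spurious
breakpoints on iid-noise chromosomes near zero while splitting
baseline-wave structure into platform-realistic fragment counts.

## Absolute copy-number calling

A deliberately simplified cluster-based caller; it produces what the
downstream procedure needs (CN labels, the diploid centroid, the 2-D
segment coordinates), not a full purity/ploidy likelihood inference.

1. **Clustering.** Probe-weighted kernel-density peak clustering in the
   (LRR, AI) plane (bandwidths 0.08 / 0.05; peaks under 15 probes of
   local mass ignored; peaks closer than 1.5 bandwidths merged).
   Density peaks are robust to the bridge segments that straddle event
   boundaries, which chain linkage-style clustering together.
2. **Ladder labelling.** The heaviest cluster is the modal state.  For
   each modal-ploidy hypothesis (2, 3, 4), candidate purities are solved
   from the LRR spacing between the modal cluster and every substantial
   cluster placed on nearby rungs; each (ploidy, purity) reading is
   scored by the weighted squared distance of cluster centres to their
   nearest predicted states.  Prior terms resolve the genuine
   degeneracies of the ladder: mass explained as homozygous deletion is
   heavily penalised, higher ploidies carry a small parsimony cost, and
   readings that fail to resolve the anchor rungs either side of the
   modal state are disfavoured.  (A fully even-CN tetraploid genome is
   *mathematically identical* to a diploid one at purity `2f/(1+f)`;
   detection of whole-genome duplication therefore rests on odd-rung
   clusters — post-duplication single-copy events — which is also the
   biologically typical signature.)
3. **Assignment.** Each segment takes the state of its nearest cluster
   centre, Euclidean in diploid-spread-standardised coordinates, ties
   broken toward the diploid cluster.
4. **Exclusion rule.** A sample is unusable when fewer than 20 segments
   are available, only one cluster separates, or the anchor clusters
   around the modal state (CN 1/2/3 on a diploid background) cannot be
   resolved.  In simulated cohorts this removes mostly samples below
   ~0.45 purity, mirroring the quality exclusions of the emulated study.
5. **Ploidy correction.** If the probe-weighted modal CN is ≥4 (or >50%
   of probe mass sits at CN ≥4) the genome is treated as duplicated and
   all CNs are halved, rounding halves down; a modal-CN-3 background is
   likewise rescaled by 2/3 so the modal state reports CN 2, without the
   WGD flag.  The detected ploidy remains on the model
   (`detected_modal_cn`, `aneuploid`), so triploid samples are still
   reported as such.  The correction is idempotent.

SCNA categories from corrected CN: amplification CN≥5, gain 3≤CN<5,
loss CN≤1, cnLOH at CN2 with minor 0, else neutral.

## Sub-clonality procedure

All geometry is computed in diploid-spread-standardised coordinates
(each axis divided by the diploid cluster's weighted spread), making the
proportion score invariant to rigid translation and to common rescaling
of the axes.  The CN1 segment most displaced from the diploid centroid
is the clonal reference, assumed present in 100% of tumor cells ("lowest
log2 ratio and highest allelic imbalance" are resolved as one scalar —
maximum displacement — since both grow monotonically with cell
fraction).  Every segment's displacement, as a proportion of the
reference displacement, estimates the fraction of tumor cells carrying
it.  The per-sample noise threshold is the 99th percentile — linear
interpolation between order statistics, stated explicitly because the
convention matters at these sample sizes — of the proportions of the
segments belonging to the diploid cluster itself.  CN2-labelled
stragglers from other clusters (shallow sub-clonal losses the caller
could not label CN1) are deliberately not part of that distribution;
including them would widen the threshold with exactly the signal the
procedure is meant to detect.

Candidate losses are segments called CN1 plus, under the default
`candidate_policy="intermediate"`, segments whose mean LRR lies between
the CN1 and CN2 cluster centres (both candidate readings of the source
procedure are implemented; the flag selects between them).  A candidate
at or below the threshold is diploid noise; at or above `clonal_min` it
is clonal; in between, sub-clonal.  `clonal_min` (default 0.9) is this
package's own boundary — the source procedure defines no sub-clonal/
clonal cut among supra-threshold segments — and is prominently
configurable.  The estimated cell fraction is the proportion itself,
clipped to [0, 1]; segments are weighted equally in the diploid centroid
(probe-weighting available).

A note on the threshold's arithmetic: a linearly interpolated 99th
percentile of `n` values is exceeded by up to `ceil(0.01(n−1))` of them,
so the pooled fraction of diploid segments above their sample thresholds
carries a deterministic small-sample excess bounded by one segment per
sample (~1.3% observed at ~200 diploid segments per sample, against the
nominal 1%).

## Cohort statistics

2×2 Fisher tests sum hypergeometric probabilities of tables no more
likely than the observed one (minimum-likelihood rule, with the usual
1+1e−7 relative slack); the 2×3 Freeman–Halton generalisation enumerates
completely when column margins allow (≤60) and falls back to
margin-conditional Monte Carlo on request.  A sample counts as affected
for a (region, type) query when any segment of a matching class overlaps
by ≥1 bp (gain queries match amplifications; combined gain/cnLOH and
loss/cnLOH queries serve the 1q and 16q tallies).  Germline-CNV
blacklist regions remove overlapping hits, with every removal logged
against the interval responsible.  No multiple-testing correction is
applied by default, matching the emulated analysis (raw P<0.05 then
blacklist filtering); Benjamini–Hochberg is available but off.
Arm-level SCNA-type matrices use segments of ≥100 probes with a fixed
priority (amplification > loss > gain > cnLOH) when several types touch
one arm — the order is a package convention.  Clustering is Ward linkage
on Manhattan distances over the one-hot-encoded matrix.  The unnamed
trend and paired comparisons of the emulated study are implemented as
Kendall tau-b rank trend and Wilcoxon signed-rank respectively — package
choices, documented rather than asserted to match.

All in-memory coordinates are 1-based inclusive (the SEG convention);
BED input is converted at the parser, so an interval abutting a
blacklist region (end+1 = blacklist start) is retained.

## Biomarker evaluation

IHC scores are pathologist inputs, never computed from images.
Proportion bins (0; <1/100; 1/100–1/10; 1/10–1/3; 1/3–2/3; >2/3) assign
exact boundary values to the lower bin — the published ranges are
ambiguous at the endpoints; the choice is logged.  Intensity 0 with
stained nuclei (or the converse) is rejected as inconsistent.  FISH uses
mean CCND1/CEP11 focus ratios over ≥20 cells; a ratio of exactly 2.5 is
gain, not amplification.  Predictive values are reported as
nearest-integer percentages.  Contralateral recurrences are excluded
upstream of every association — they do not represent clonal progression
of the index lesion.  The per-patient validation sheet shipped in
`lcis_scna.datasets` is a synthetic reconstruction: individual rows are
invented so that the published aggregate counts are reproduced exactly.

## Problem sizes and numerical conventions

Recovery experiments run at 50 samples (CN accuracy, purity ≥0.5), 30
samples (sub-clone sensitivity at 0.6 of tumor cells, purity 0.8), 16
samples × 13 arms (cell-fraction sweep), and 20 samples (threshold
calibration) — sizes chosen so the full suite completes in about a
minute while every metric rests on ≥200 scored units.  Exact-test
verification is exhaustive over all 2×2 tables with total ≤40 against an
independent enumeration oracle.  Degenerate inputs have defined
behaviour throughout: empty contingency margins give P=1; a zero DNA
mixture returns BAF 0.5 by convention; mixtures are floored at 0.05
before log2; chromosomes with fewer probes than the segment minimum
come back as single low-confidence segments; unusable samples are
excluded results, not exceptions.

## Known limitations

- The caller's (purity, ploidy) reading is degenerate for fully even-CN
  duplicated genomes; such samples are reported diploid at rescaled
  purity (no observable difference exists in this signal model).
- Sub-clone fractions are estimated from a single reference assumed
  fully clonal; if the true reference loss is itself sub-clonal, all
  fractions inflate proportionally.
- The folded-AI scalar discards multi-band BAF structure, limiting minor-
  allele resolution above CN 4.
- Samples below ~0.45 purity are usually excluded rather than called.
- No GC-wave correction, joint multi-sample segmentation, or
  mutation-based clonal deconvolution.
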
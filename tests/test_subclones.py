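import numpy as np
import pytest

from lcis_scna.cn_calling import Cluster, SampleModel
from lcis_scna.segmentation import Segment
from lcis_scna.subclones import (NotScorableError, call_subclones,
                                 count_subclonal_per_sample,
                                 proportion_scores, select_reference_segment,
                                 subclonality_threshold)


def _segment(lrr, ai, acn=None, minor=None, cluster_id=None, chrom="chr1",
             n_probes=100):
    return Segment(chrom, 1, 1_000_000, n_probes, lrr, ai, acn=acn,
                   minor_cn=minor, cluster_id=cluster_id)


def _model(lrr_scale=0.05, ai_scale=0.02, centroid=(0.0, 0.02)):
    return SampleModel(
        clusters=[
            Cluster(2, 1, centroid, 1000.0),
            Cluster(1, 0, (-0.7, 0.65), 100.0),
            Cluster(3, 1, (0.45, 0.28), 100.0),
        ],
        diploid_centroid=centroid, lrr_scale=lrr_scale, ai_scale=ai_scale,
        usable=True, modal_cn=2,
    )


class TestSelectReference:
    def test_single_cn1_segment_is_reference(self):
        model = _model()
        segs = [_segment(0.0, 0.02, acn=2, minor=1),
                _segment(-0.7, 0.64, acn=1, minor=0)]
        assert select_reference_segment(segs, model) is segs[1]

    def test_most_displaced_cn1_wins(self):
        """A clonal loss (full displacement) beats a shallower sub-clonal
        loss that was also labelled CN1."""
        model = _model()
        clonal = _segment(-0.72, 0.66, acn=1, minor=0, chrom="chr16")
        shallow = _segment(-0.40, 0.32, acn=1, minor=0, chrom="chr11")
        assert select_reference_segment(
            [shallow, clonal, _segment(0.0, 0.02, acn=2, minor=1)],
            model) is clonal

    def test_no_cn1_segment_not_scorable(self):
        with pytest.raises(NotScorableError):
            select_reference_segment([_segment(0.0, 0.02, acn=2, minor=1)],
                                     _model())


class TestProportionScores:
    def test_centroid_and_reference_anchors(self):
        model = _model()
        ref = _segment(-0.7, 0.65, acn=1, minor=0)
        at_centroid = _segment(0.0, 0.02, acn=2, minor=1)
        scored = dict((id(s), p) for s, p in
                      proportion_scores([at_centroid, ref], model, ref))
        assert scored[id(ref)] == 1.0
        assert scored[id(at_centroid)] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_translation_and_common_rescale_invariance(self):
        model = _model()
        ref = _segment(-0.7, 0.65)
        others = [_segment(-0.35, 0.3), _segment(0.1, 0.05)]
        base = [p for _, p in proportion_scores(others + [ref], model, ref)]

        dx, dy, scale = 0.21, 0.13, 3.7
        model2 = _model(lrr_scale=model.lrr_scale * scale,
                        ai_scale=model.ai_scale * scale,
                        centroid=(model.diploid_centroid[0] + dx,
                                  model.diploid_centroid[1] + dy))
        ref2 = _segment(ref.mean_lrr + dx, ref.ai + dy)
        others2 = [_segment(s.mean_lrr + dx, s.ai + dy) for s in others]
        moved = [p for _, p in proportion_scores(others2 + [ref2], model2, ref2)]
        assert moved == pytest.approx(base)

    def test_degenerate_reference_rejected(self):
        model = _model()
        ref = _segment(*model.diploid_centroid)
        with pytest.raises(NotScorableError, match="degenerate"):
            proportion_scores([ref], model, ref)


class TestSubclonalityThreshold:
    def test_constant_distribution(self):
        assert subclonality_threshold([0.3] * 25) == pytest.approx(0.3)

    def test_uniform_grid_percentile(self):
        props = [i / 100 for i in range(101)]
        assert subclonality_threshold(props) == pytest.approx(0.99)

    def test_too_few_diploid_segments(self):
        with pytest.raises(NotScorableError):
            subclonality_threshold([0.1] * 10)


class TestCallSubclones:
    def test_simulated_sample_classification(self, called_sample):
        """The clonal 16q/17p losses score ~1 (clonal), the half-fraction
        22q13 loss lands between threshold and clonal_min (sub-clonal),
        and diploid scatter stays below threshold."""
        segments, model = called_sample
        calls = call_subclones(segments, model)
        by_chrom = {}
        for c in calls:
            by_chrom.setdefault(c.segment.chrom, []).append(c)
        ref = [c for c in calls if c.is_reference]
        assert len(ref) == 1 and ref[0].clonality == "clonal"
        assert ref[0].proportion == 1.0
        assert any(c.clonality == "clonal" for c in by_chrom["chr17"])
        sub = [c for c in by_chrom.get("chr22", []) if c.clonality == "subclonal"]
        assert sub
        # half of tumor cells -> proportion in the derived band
        assert 0.3 <= sub[0].proportion <= 0.7
        assert sub[0].est_cell_fraction == pytest.approx(sub[0].proportion)

    def test_thresholding_rules(self):
        model = _model()
        did = model.diploid_cluster_id
        rng = np.random.default_rng(0)
        diploid = [_segment(float(x), float(a), acn=2, minor=1, cluster_id=did)
                   for x, a in zip(rng.normal(0, 0.02, 40),
                                   np.abs(rng.normal(0.02, 0.01, 40)))]
        ref = _segment(-0.7, 0.65, acn=1, minor=0, cluster_id=1)
        mid = _segment(-0.35, 0.3, acn=1, minor=0, cluster_id=1)
        calls = call_subclones(diploid + [ref, mid], model)
        ref_call = next(c for c in calls if c.is_reference)
        mid_call = next(c for c in calls if c.segment is mid)
        assert ref_call.clonality == "clonal"
        assert mid_call.clonality == "subclonal"
        assert mid_call.threshold < mid_call.proportion < 0.9

    def test_candidate_policy_cn1_only(self):
        model = _model()
        did = model.diploid_cluster_id
        rng = np.random.default_rng(1)
        diploid = [_segment(float(x), float(a), acn=2, minor=1, cluster_id=did)
                   for x, a in zip(rng.normal(0, 0.02, 30),
                                   np.abs(rng.normal(0.02, 0.01, 30)))]
        ref = _segment(-0.7, 0.65, acn=1, minor=0, cluster_id=1)
        # intermediate-LRR segment the caller labelled diploid
        between = _segment(-0.35, 0.3, acn=2, minor=1, cluster_id=did)
        strict = call_subclones(diploid + [ref, between], model,
                                candidate_policy="cn1")
        loose = call_subclones(diploid + [ref, between], model,
                               candidate_policy="intermediate")
        assert all(c.segment is not between for c in strict)
        assert any(c.segment is between for c in loose)


def test_count_subclonal_per_sample(called_sample):
    segments, model = called_sample
    calls = call_subclones(segments, model)
    n = count_subclonal_per_sample(calls)
    assert n == sum(1 for c in calls if c.clonality == "subclonal")
    assert n >= 1
    assert count_subclonal_per_sample([]) == 0
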
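import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcis_scna.cn_calling import (UnusableModelError, assign_absolute_cn,
                                  classify_scna, correct_wgd,
                                  fit_sample_model, truth_segments)
from lcis_scna.segmentation import Segment, segment_probes
from lcis_scna.synthetic import SimulationConfig, make_event, simulate_sample


class TestFitSampleModel:
    def test_cluster_centres_match_mixture_model(self, called_sample):
        segments, model = called_sample
        assert model.usable
        f = 0.8  # generator truth
        centers = model.cluster_centers
        for cn in (1, 2, 3):
            want = math.log2((f * cn + (1 - f) * 2) / 2)
            assert centers[cn][0] == pytest.approx(want, abs=0.1)
        assert model.purity_estimate == pytest.approx(f, abs=0.1)

    def test_pure_noise_sample_unusable(self):
        config = SimulationConfig(purity=0.8, seed=9)  # no events at all
        probes, _ = simulate_sample(config)
        model = fit_sample_model(segment_probes(probes))
        assert not model.usable
        assert model.reason

    def test_too_few_segments_unusable(self):
        segs = [Segment("chr1", i * 10 + 1, i * 10 + 10, 10, 0.0, 0.0)
                for i in range(5)]
        model = fit_sample_model(segs)
        assert not model.usable
        assert "too few" in model.reason


class TestAssignAbsoluteCn:
    def test_known_events_recovered(self, called_sample):
        segments, model = called_sample
        by_class = {}
        for s in segments:
            by_class.setdefault(s.scna_class, []).append(s)
        assert any(s.chrom == "chr16" for s in by_class["loss"])
        assert any(s.chrom == "chr17" for s in by_class["loss"])
        assert any(s.chrom == "chr1" for s in by_class["gain"])
        assert any(s.chrom == "chr11" for s in by_class["amplification"])

    def test_clonal_cnloh_called(self):
        config = SimulationConfig(purity=0.9, seed=21, events=(
            make_event("16q_cnloh", 0.9),
            make_event("17p_loss", 0.9),
            make_event("1q_gain", 0.9),
        ))
        probes, _ = simulate_sample(config)
        segs = segment_probes(probes)
        model = fit_sample_model(segs)
        assert model.usable, model.reason
        assign_absolute_cn(segs, model)
        cnloh = [s for s in segs if s.chrom == "chr16" and s.start > 37e6
                 and s.n_probes >= 50]
        assert cnloh
        assert all(s.acn == 2 and s.minor_cn == 0 for s in cnloh)

    def test_unusable_model_refused(self):
        from lcis_scna.cn_calling import SampleModel
        with pytest.raises(UnusableModelError):
            assign_absolute_cn([], SampleModel(usable=False, reason="x"))


class TestCorrectWgd:
    def _segs(self, acns, n_probes=100):
        return [Segment("chr1", i * 10 + 1, i * 10 + 9, n_probes, 0.0, 0.0,
                        acn=a, minor_cn=a // 2) for i, a in enumerate(acns)]

    def _usable_model(self):
        from lcis_scna.cn_calling import Cluster, SampleModel
        return SampleModel(usable=True, modal_cn=2,
                           clusters=[Cluster(2, 1, (0.0, 0.0), 1.0)],
                           diploid_centroid=(0.0, 0.0))

    def test_tetraploid_halved(self):
        segs = self._segs([4] * 30)
        segs, model = correct_wgd(segs, self._usable_model())
        assert all(s.acn == 2 for s in segs)
        assert model.wgd

    def test_diploid_unchanged(self):
        segs = self._segs([2] * 25 + [1, 3])
        segs, model = correct_wgd(segs, self._usable_model())
        assert [s.acn for s in segs] == [2] * 25 + [1, 3]
        assert not model.wgd

    def test_idempotent(self):
        segs = self._segs([4] * 20 + [2, 6])
        segs, model = correct_wgd(segs, self._usable_model())
        once = [s.acn for s in segs]
        segs, model = correct_wgd(segs, model)
        assert [s.acn for s in segs] == once


class TestClassifyScna:
    @pytest.mark.parametrize("acn,minor,want", [
        (5, 1, "amplification"),
        (3, 1, "gain"),
        (2, 1, "neutral"),
        (2, 0, "cnLOH"),
        (1, 0, "loss"),
        (0, 0, "loss"),
    ])
    def test_categories(self, acn, minor, want):
        seg = Segment("chr1", 1, 10, 10, 0.0, 0.0, acn=acn, minor_cn=minor)
        assert classify_scna(seg) == want
        assert seg.scna_class == want

    def test_unset_cn_rejected(self):
        with pytest.raises(ValueError):
            classify_scna(Segment("chr1", 1, 10, 10, 0.0, 0.0))

    @given(acn=st.integers(0, 12), minor=st.integers(0, 6))
    @settings(max_examples=60, deadline=None)
    def test_total_function_one_class(self, acn, minor):
        minor = min(minor, acn // 2)
        seg = Segment("chr1", 1, 10, 10, 0.0, 0.0, acn=acn, minor_cn=minor)
        assert classify_scna(seg) in {"neutral", "loss", "gain",
                                      "amplification", "cnLOH"}


def test_truth_segments_carry_classes():
    from lcis_scna.synthetic import SimulatedSample
    config = SimulationConfig(purity=0.8, events=(make_event("16q_loss", 0.8),))
    sample = SimulatedSample("s1", "g", config)
    segs = truth_segments(sample)
    assert len(segs) == 1
    assert segs[0].scna_class == "loss"
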
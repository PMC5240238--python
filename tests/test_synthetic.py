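import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcis_scna.synthetic import (SimulationConfig, TruthEvent, expected_baf,
                                 expected_lrr, make_event, simulate_cohort,
                                 simulate_microdissection, simulate_sample,
                                 study_profiles)


class TestExpectedLrr:
    @pytest.mark.parametrize("cn,frac,base,want", [
        (2, 1.0, 2, 0.0),
        (1, 1.0, 2, -1.0),
        (1, 0.5, 2, math.log2(0.75)),
        (4, 1.0, 2, 1.0),
    ])
    def test_closed_form(self, cn, frac, base, want):
        assert expected_lrr(cn, frac, base) == pytest.approx(want)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            expected_lrr(-1, 0.5)
        with pytest.raises(ValueError):
            expected_lrr(2, 1.5)

    @given(cn=st.integers(3, 8), frac=st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_cn_and_fraction(self, cn, frac):
        assert expected_lrr(cn + 1, frac) > expected_lrr(cn, frac)
        assert expected_lrr(cn, min(frac + 0.05, 1.0)) > expected_lrr(cn, frac)


class TestExpectedBaf:
    @pytest.mark.parametrize("cn,minor,frac,want", [
        (2, 1, 1.0, 0.5),
        (2, 0, 1.0, 0.0),
        (1, 0, 0.7, 0.3 / 1.3),
    ])
    def test_closed_form(self, cn, minor, frac, want):
        assert expected_baf(cn, minor, frac) == pytest.approx(want)

    def test_empty_mixture_convention(self):
        assert expected_baf(0, 0, 1.0) == 0.5

    @given(cn=st.integers(1, 8), frac=st.floats(0.05, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_allele_symmetry(self, cn, frac):
        """BAF of the minor allele and of its complement sum to one."""
        for minor in range(cn // 2 + 1):
            b_minor = expected_baf(cn, minor, frac)
            denom = frac * cn + (1 - frac) * 2
            b_major = (frac * (cn - minor) + (1 - frac)) / denom
            assert b_minor + b_major == pytest.approx(1.0)


class TestSimulateSample:
    def test_deterministic_under_seed(self):
        config = SimulationConfig(purity=0.8, seed=42,
                                  events=(make_event("16q_loss", 0.8),))
        probes1, truth1 = simulate_sample(config)
        probes2, truth2 = simulate_sample(config)
        pd.testing.assert_frame_equal(probes1, probes2)
        assert truth1 == truth2

    def test_no_event_sample_centred_at_zero(self):
        config = SimulationConfig(purity=1.0, seed=7, wave_sd=0.0)
        probes, _ = simulate_sample(config)
        n = len(probes)
        assert abs(probes["lrr"].mean()) < 3 * config.lrr_sd / math.sqrt(n)
        assert probes["baf"].between(0, 1).all()

    def test_clonal_loss_limit(self):
        """With vanishing noise a pure single-copy loss converges to the
        mixture-model LRR of -1."""
        config = SimulationConfig(purity=1.0, seed=7, lrr_sd=1e-4,
                                  wave_sd=0.0,
                                  events=(make_event("16q_loss", 1.0),))
        probes, (ev,) = simulate_sample(config)
        inside = probes[(probes["chrom"] == ev.chrom)
                        & probes["pos"].between(ev.start, ev.end)]
        assert inside["lrr"].mean() == pytest.approx(-1.0, abs=1e-3)

    def test_segment_mean_recovery(self):
        """At lrr_sd 0.2 the mean over >=100 event probes lands within
        +-0.06 (3 sigma / sqrt(n)) of the mixture-model expectation."""
        config = SimulationConfig(purity=0.6, seed=13, lrr_sd=0.2,
                                  wave_sd=0.0,
                                  events=(make_event("1q_gain", 0.6),))
        probes, (ev,) = simulate_sample(config)
        inside = probes[(probes["chrom"] == ev.chrom)
                        & probes["pos"].between(ev.start, ev.end)]
        assert len(inside) >= 100
        assert inside["lrr"].mean() == pytest.approx(
            math.log2((0.6 * 3 + 0.4 * 2) / 2), abs=0.06)

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            SimulationConfig(events=(
                TruthEvent("chr16", 1_000_000, 5_000_000, 1, 0, 0.5),
                TruthEvent("chr16", 4_000_000, 9_000_000, 3, 1, 0.5),
            ))


class TestSimulateCohort:
    def test_certain_event_present_in_all(self):
        cohort = simulate_cohort({"g": {"16q_loss": 1.0}}, 10, seed=0)
        assert len(cohort) == 10
        assert all(any(e.name == "16q_loss" for e in s.truth)
                   for s in cohort.samples)

    def test_empty_cohort(self):
        assert len(simulate_cohort({"g": {"16q_loss": 1.0}}, 0, seed=0)) == 0

    def test_frequency_within_binomial_ci(self):
        """Observed 1q-gain frequency at n=1000 lies inside the binomial
        99% interval around the profile frequency of 0.78."""
        cohort = simulate_cohort({"g": {"1q_gain": 0.78}}, 1000, seed=1)
        k = sum(any(e.name == "1q_gain" for e in s.truth)
                for s in cohort.samples)
        half = 2.576 * math.sqrt(0.78 * 0.22 / 1000)
        assert 0.78 - half <= k / 1000 <= 0.78 + half

    def test_unknown_template_rejected(self):
        with pytest.raises(KeyError):
            simulate_cohort({"g": {"nonsense_event": 1.0}}, 2, seed=0)

    def test_study_profiles_cover_three_groups(self):
        profiles = study_profiles()
        assert set(profiles) == {"pure-cLCIS", "inv-cLCIS", "cILC"}
        cohort = simulate_cohort(profiles, {"pure-cLCIS": 2, "inv-cLCIS": 1,
                                            "cILC": 0}, seed=0)
        assert cohort.groups().value_counts().to_dict() == {
            "pure-cLCIS": 2, "inv-cLCIS": 1}


def test_microdissection_loh_rate_tracks_cell_fraction():
    loh = simulate_microdissection(0.7, 5000, seed=3)
    assert loh.mean() == pytest.approx(0.7, abs=0.02)
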
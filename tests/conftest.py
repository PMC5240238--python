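import pytest

from lcis_scna.cn_calling import (assign_absolute_cn, classify_segments,
                                  correct_wgd, fit_sample_model)
from lcis_scna.segmentation import segment_probes
from lcis_scna.synthetic import SimulationConfig, make_event, simulate_sample


@pytest.fixture(scope="session")
def standard_config():
    """A purity-0.8 sample with the canonical aberrations: clonal 16q and
    17p losses, 1q gain, focal 11q13 amplification, and a 22q13 loss in
    half the tumor cells."""
    return SimulationConfig(
        purity=0.8, seed=101,
        events=(
            make_event("16q_loss", 0.8),
            make_event("1q_gain", 0.8),
            make_event("17p_loss", 0.8),
            make_event("11q13_amp", 0.8),
            make_event("22q13_loss", 0.4),
        ),
    )


@pytest.fixture(scope="session")
def standard_sample(standard_config):
    probes, truth = simulate_sample(standard_config)
    return probes, truth


@pytest.fixture(scope="session")
def standard_segments(standard_sample):
    probes, _ = standard_sample
    return segment_probes(probes, sample_id="s1")


@pytest.fixture(scope="session")
def called_sample(standard_segments):
    """Segments of the standard sample with a fitted model and CN calls.

    Session-scoped; tests must not mutate the returned objects."""
    segments = [s for s in standard_segments]
    model = fit_sample_model(segments)
    assert model.usable, model.reason
    assign_absolute_cn(segments, model)
    correct_wgd(segments, model)
    classify_segments(segments)
    return segments, model
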
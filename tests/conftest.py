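import numpy as np
import pytest

import fastripple as fr


@pytest.fixture(scope="session")
def noise_recording():
    """Event-free synthetic recording (8 s) at default noise levels."""
    rec, gt = fr.generate_recording(fr.SynthConfig(duration_s=8.0, seed=42))
    return rec, gt


@pytest.fixture(scope="session")
def single_event_recording():
    """One sharp-wave-associated CA1 fast ripple in 8 s of background."""
    cfg = fr.SynthConfig(
        duration_s=8.0,
        event_specs=[
            fr.FREventSpec(
                region="CA1",
                t_center=4.0,
                duration_ms=200.0,
                carrier_freq=350.0,
                amplitude_pp=60.0,
                sharp_wave=True,
                sharp_wave_duration_ms=150.0,
            )
        ],
        seed=7,
    )
    rec, gt = fr.generate_recording(cfg)
    return rec, gt


@pytest.fixture(scope="session")
def spiking_cohort():
    """Cohort with the CA3-leading spike schedule (for the MUA stage)."""
    cfg = fr.cohort_config(n_events=40, seed=11, with_spikes=True)
    rec, gt = fr.generate_recording(cfg)
    return rec, gt
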
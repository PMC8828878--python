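import logging

import pytest

import neuroipc as n

# silence the expected ridge-fallback log chatter in bulk fitting tests
logging.getLogger("neuroipc.deconvolution").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def unit_peak_hrf() -> n.HRFParams:
    """Canonical double-gamma HRF rescaled to a unit positive peak."""
    return n.peak_normalized(n.HRFParams())


@pytest.fixture(scope="session")
def isolated_subject(unit_peak_hrf):
    """A noise-free synthetic subject with non-overlapping trials.

    One run, 4 trials each for the congruent and incongruent conditions,
    spaced >= 50 s so that the full BOLD response (activity decay plus the
    32 s kernel support) of one trial dies out before the next begins.
    """
    paradigm = n.generate_paradigm(
        n_runs=1,
        trials_per_condition_per_run=4,
        conditions=("C", "IC"),
        min_isi_s=50.0,
        seed=3,
    )
    truth = n.GroundTruth(ipc=n.IPCParams(p=1.0, m=2.0), hrf=unit_peak_hrf)
    bold, _ = n.generate_subject(paradigm, truth)
    return paradigm, truth, bold
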
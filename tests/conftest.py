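import numpy as np
import pytest

from remgate import synthgen, transitions as tr, units
from remgate.params import GeneratorParams


@pytest.fixture(scope="session")
def params():
    return GeneratorParams()


@pytest.fixture(scope="session")
def session_2h(params):
    """A 2 h laser-free session with one REM-off unit."""
    hyp, truth = synthgen.simulate_hypnogram(params, 2 * 3600, seed=5)
    spikes = synthgen.simulate_unit(hyp, params, seed=6, truth=truth)
    rs = units.rate_series(spikes, hyp, zscore=True)
    eps = tr.episodes(hyp)
    return {"hyp": hyp, "truth": truth, "spikes": spikes, "rs": rs,
            "eps": eps}


@pytest.fixture(scope="session")
def session_24h(params):
    """A 24 h laser-free session with one REM-off unit (homeostasis
    analyses need many inter-REM intervals)."""
    hyp, truth = synthgen.simulate_hypnogram(params, 24 * 3600, seed=11)
    spikes = synthgen.simulate_unit(hyp, params, seed=12, truth=truth)
    rs = units.rate_series(spikes, hyp, zscore=True)
    eps = tr.episodes(hyp)
    return {"hyp": hyp, "truth": truth, "spikes": spikes, "rs": rs,
            "eps": eps}


@pytest.fixture(scope="session")
def scored_session(params):
    """A 1 h session synthesised to EEG/EMG at 500 Hz and re-scored."""
    from remgate import staging

    hyp, truth = synthgen.simulate_hypnogram(params, 3600, seed=2)
    eeg, emg = synthgen.synthesize_eeg_emg(hyp, 500.0, params, seed=3)
    scored, thr, feats = staging.score(eeg, emg, 500.0)
    return {"hyp": hyp, "eeg": eeg, "emg": emg, "fs": 500.0,
            "scored": scored, "thr": thr, "feats": feats}


def make_hypnogram(pattern, epoch_s=2.5):
    """Build a hypnogram from (state, n_epochs) pairs."""
    from remgate.hypnogram import Hypnogram

    labels = np.concatenate([[s] * n for s, n in pattern])
    return Hypnogram(np.array(labels), epoch_s)
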
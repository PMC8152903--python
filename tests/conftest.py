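import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from erpdecode import core, synth

settings.register_profile(
    "ci", deadline=None, max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def balanced_labels(n_trials: int, seed: int = 0) -> core.TrialLabels:
    """Balanced 16-cell label table without the no-repeat constraint."""
    rng = np.random.default_rng(seed)
    cells = np.array([(i, e) for i in range(1, 5) for e in range(1, 5)])
    reps = -(-n_trials // 16)
    seq = np.tile(cells, (reps, 1))[:n_trials]
    seq = seq[rng.permutation(n_trials)]
    return core.TrialLabels(identity=seq[:, 0], expression=seq[:, 1],
                            trial_index=np.arange(n_trials))


def white_noise_epochs(n_trials=160, n_channels=59, n_times=40, fs=250.0,
                       t_start_ms=0.0, seed=0) -> core.EpochSet:
    rng = np.random.default_rng(seed)
    return core.EpochSet(
        data=rng.standard_normal((n_trials, n_channels, n_times)).astype(np.float32),
        fs=fs, t_start_ms=t_start_ms,
        channel_names=synth.default_channel_names(n_channels),
        participant_id="noise",
        labels=balanced_labels(n_trials, seed=seed + 1),
    )


@pytest.fixture(scope="session")
def default_participant():
    """One simulated participant at the emulated study's native scale."""
    cfg = synth.SynthConfig()
    topo = synth.make_topographies(cfg, seed=11)
    return synth.simulate_participant(cfg, topo, seed=12), cfg


@pytest.fixture()
def tiny_epochs():
    return white_noise_epochs(n_trials=32, n_channels=6, n_times=12, seed=3)
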
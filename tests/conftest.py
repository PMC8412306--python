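import numpy as np
import pytest

from bpcurve import GeneratorConfig, TrialMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trials(values: np.ndarray, labels, fs: float = 100.0) -> TrialMatrix:
    """Wrap a plain array as a TrialMatrix with a consistent time axis."""
    values = np.asarray(values, dtype=float)
    time = np.arange(values.shape[0]) / fs
    return TrialMatrix(values=values, time=time, fs=fs, labels=np.asarray(labels))


@pytest.fixture
def random_trials(rng):
    """Small random trial matrix: 3 subgroups x 4 trials, 40 samples."""
    labels = np.repeat(["a", "b", "c"], 4)
    return make_trials(rng.standard_normal((40, 12)), labels)


def small_config(**overrides) -> GeneratorConfig:
    """Reduced-scale generator conditions for fast structural tests.

    Same statistical family as the full-scale scenarios, but a shorter
    window at a lower sampling rate so unit tests stay quick.
    """
    defaults = dict(
        n_subgroups=6,
        motif_assignment=[0, 0, 1, 1, None, None],
        n_motifs=2,
        trials_per_subgroup=(8, 8),
        fs=256.0,
        t1=0.05,
        t2=1.0,
        snr=5.0,
        seed=0,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)
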
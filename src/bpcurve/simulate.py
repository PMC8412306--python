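"""Ground-truth synthetic stimulation-response datasets.

The generator emulates the structure of a convergent single-pulse
stimulation session measured at one electrode: N stimulation-pair subgroups
of ~10-12 repeated trials each, sampled at 2048 Hz and windowed
0.050-2.000 s after the pulse.  A small library of smooth unit-norm temporal
motifs (damped oscillations and slow biexponential deflections, tapered to
zero at the window edges) is shared across spatially contiguous subgroups;
other subgroups carry pure noise.  Trial r of subgroup n is

    amp_n * (1 - drift_n * r) * motif(n) + noise,

where the optional per-repeat drift emulates response adaptation to repeated
stimulation, and the noise is white Gaussian plus a 1/f-shaped component
(spectrally shaded white noise) whose standard deviation is a fraction of
the white sigma.

Amplitudes are specified through a trial-level signal-to-noise ratio: the
ratio of the trial's signal norm (= amplitude, motifs being unit-norm) to
the expected noise norm sigma_eff * sqrt(T).  An SNR of 5 corresponds to a
clearly expressed evoked potential (per-trial explained variance ~0.96);
see docs/methods.md for why this is the natural scale for functional data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .epoching import EventTable, TrialMatrix, window_sample_bounds

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "motif_library",
    "motif_similarity",
    "generate",
    "default_scenarios",
    "scenario",
    "electrode_table",
]


def _time_axis(fs: float, t1: float, t2: float) -> np.ndarray:
    start, stop = window_sample_bounds(fs, t1, t2)
    return (start + np.arange(stop - start + 1)) / fs


def _edge_taper(n: int, frac: float = 0.08) -> np.ndarray:
    """Cosine taper to zero at both ends (Tukey-style), so motifs vanish at
    the window edges."""
    from scipy.signal.windows import tukey

    return tukey(n, alpha=2 * frac)


def motif_library(time: np.ndarray, n_motifs: int = 3) -> np.ndarray:
    """Unit-norm response motifs on the given time axis (T x n_motifs).

    The family covers both fast polyphasic shapes (the conventional N1/N2
    form) and slow deflections, since the framework makes no assumption that
    responses look N1/N2-like:

    0. fast damped oscillation (biphasic, dominant in the first ~300 ms),
    1. slow negative biexponential deflection peaking near 250 ms,
    2. slow delayed oscillation extending through the window.

    Further motifs cycle through phase-shifted damped sinusoids.
    """
    t = np.asarray(time, dtype=float)
    u = t - t[0]
    shapes = []
    catalogue = [
        lambda u: np.sin(2 * np.pi * 9.0 * u) * np.exp(-u / 0.12),
        lambda u: -(np.exp(-u / 0.55) - np.exp(-u / 0.09)),
        lambda u: np.sin(2 * np.pi * 1.7 * u + 0.6) * np.exp(-u / 0.40) * (1 - np.exp(-u / 0.05)),
    ]
    for i in range(n_motifs):
        if i < len(catalogue):
            m = catalogue[i](u)
        else:  # fallbacks: dephased mid-rate damped sinusoids
            m = np.sin(2 * np.pi * (3.0 + 1.3 * i) * u + 0.8 * i) * np.exp(-u / 0.25)
        shapes.append(m)
    M = np.column_stack(shapes) * _edge_taper(t.size)[:, None]
    M /= np.linalg.norm(M, axis=0)
    return M


def motif_similarity(motifs: np.ndarray) -> float:
    """Largest pairwise |correlation| between motifs (0 for a single motif)."""
    M = motifs - motifs.mean(axis=0)
    M = M / np.linalg.norm(M, axis=0)
    C = np.abs(M.T @ M)
    q = C.shape[0]
    if q == 1:
        return 0.0
    return float(C[np.triu_indices(q, k=1)].max())


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-power noise columns with unit standard deviation, by spectral
    shading of white noise (amplitude ~ f^-1/2, DC removed)."""
    t, k = shape
    white = rng.standard_normal((t, k))
    spec = np.fft.rfft(white, axis=0)
    f = np.fft.rfftfreq(t)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** -0.5
    pink = np.fft.irfft(spec * scale[:, None], n=t, axis=0)
    pink /= pink.std(axis=0)
    return pink


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic session.

    ``motif_assignment[i]`` is the motif index of subgroup i, or None for a
    pure-noise subgroup.  ``snr`` sets subgroup amplitudes as
    ``snr * relative_amplitude[i] * sigma_eff * sqrt(T)`` where
    ``sigma_eff = noise_sigma * sqrt(1 + pink_fraction**2)`` is the total
    per-sample noise standard deviation.  ``drift[i]`` is the fractional
    amplitude loss per repeat (adaptation).
    """

    n_subgroups: int
    motif_assignment: list  # per subgroup: motif index or None
    trials_per_subgroup: tuple[int, int] = (10, 12)  # inclusive range
    fs: float = 2048.0
    t1: float = 0.050
    t2: float = 2.000
    n_motifs: int = 3
    snr: float = 5.0
    relative_amplitude: np.ndarray | None = None  # per subgroup, default 1
    noise_sigma: float = 5.0  # microvolts, white component, per sample
    pink_fraction: float = 0.5  # 1/f component std as fraction of white sigma
    drift: np.ndarray | None = None  # per subgroup, default 0
    isi_range: tuple[float, float] = (3.0, 7.0)  # seconds between pulses
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subgroups < 2:
            raise ValueError("need at least two subgroups")
        if len(self.motif_assignment) != self.n_subgroups:
            raise ValueError("motif_assignment must have one entry per subgroup")
        for a in self.motif_assignment:
            if a is not None and not 0 <= a < self.n_motifs:
                raise ValueError(f"motif index {a!r} outside library of {self.n_motifs}")
        if self.relative_amplitude is None:
            self.relative_amplitude = np.ones(self.n_subgroups)
        self.relative_amplitude = np.asarray(self.relative_amplitude, dtype=float)
        if self.drift is None:
            self.drift = np.zeros(self.n_subgroups)
        self.drift = np.asarray(self.drift, dtype=float)
        if not (np.all(np.isfinite(self.drift))
                and np.all(np.isfinite(self.relative_amplitude))):
            raise ValueError("rates and amplitudes must be finite")

    @property
    def labels(self) -> np.ndarray:
        """Subgroup labels named after the stimulated electrode pair."""
        return np.array(
            [f"E{2 * i + 1:02d}-E{2 * i + 2:02d}" for i in range(self.n_subgroups)]
        )


@dataclass
class GroundTruth:
    """What the generator actually put into the data."""

    motifs: np.ndarray  # (T, n_motifs) unit-norm
    assignment: list  # per subgroup: motif index or None
    amplitudes: np.ndarray  # (K,) true per-trial amplitude a_k
    labels: np.ndarray  # (K,) subgroup label per trial
    subgroup_labels: np.ndarray  # (N,)


def generate(config: GeneratorConfig) -> tuple[TrialMatrix, EventTable, GroundTruth]:
    """Draw one session: trial matrix, matching event table, and ground truth."""
    rng = np.random.default_rng(config.seed)
    time = _time_axis(config.fs, config.t1, config.t2)
    T = time.size
    motifs = motif_library(time, config.n_motifs)
    sigma_eff = config.noise_sigma * np.sqrt(1 + config.pink_fraction**2)
    base_amp = config.snr * sigma_eff * np.sqrt(T)

    lo, hi = config.trials_per_subgroup
    counts = rng.integers(lo, hi + 1, size=config.n_subgroups)
    sub_labels = config.labels

    cols, trial_labels, amps = [], [], []
    for i in range(config.n_subgroups):
        k = int(counts[i])
        a_idx = config.motif_assignment[i]
        amp = base_amp * config.relative_amplitude[i]
        r = np.arange(k)
        a_k = amp * (1 - config.drift[i] * r)
        noise = rng.standard_normal((T, k)) * config.noise_sigma
        if config.pink_fraction > 0:
            noise += _pink_noise(rng, (T, k)) * (
                config.pink_fraction * config.noise_sigma
            )
        if a_idx is None:
            block = noise
            a_k = np.zeros(k)
        else:
            block = np.outer(motifs[:, a_idx], a_k) + noise
        cols.append(block)
        trial_labels.extend([sub_labels[i]] * k)
        amps.extend(a_k)

    values = np.concatenate(cols, axis=1)
    trial_labels = np.asarray(trial_labels)
    isi = rng.uniform(*config.isi_range, size=values.shape[1])
    onsets = 10.0 + np.cumsum(isi)
    trials = TrialMatrix(values=values, time=time, fs=config.fs, labels=trial_labels)
    events = EventTable(onset=onsets, label=trial_labels.copy())
    truth = GroundTruth(
        motifs=motifs,
        assignment=list(config.motif_assignment),
        amplitudes=np.asarray(amps),
        labels=trial_labels.copy(),
        subgroup_labels=sub_labels,
    )
    return trials, events, truth


def electrode_table(config: GeneratorConfig, spacing: float = 10.0) -> pd.DataFrame:
    """Synthetic electrode coordinates on a grid (BIDS-style name/x/y/z).

    Electrodes are laid out in rows of 8 (a 6x8-grid-plus-strips footprint);
    each stimulation pair occupies two adjacent contacts, so the pair
    midpoints used by the spatial maps are well defined.
    """
    n_elec = 2 * config.n_subgroups
    names, xs, ys = [], [], []
    for e in range(n_elec):
        names.append(f"E{e + 1:02d}")
        xs.append((e % 8) * spacing)
        ys.append((e // 8) * spacing)
    return pd.DataFrame({"name": names, "x": xs, "y": ys, "z": 0.0})


def default_scenarios() -> dict[str, GeneratorConfig]:
    """Named study conditions used throughout the tests and examples.

    - ``three_motifs``: 24 subgroups — three motifs over six spatially
      contiguous subgroups each, plus six pure-noise subgroups; trial SNR 5.
      Subgroup amplitudes vary deterministically by +-15% around the base.
    - ``single_motif``: one motif everywhere.
    - ``all_noise``: no evoked structure at all (null case).
    - ``adaptation``: two equal-size subgroups sharing one motif with strong
      per-repeat amplitude drift (0.06/repeat, i.e. the 11th response is 40%
      of the 1st), plus two noise subgroups.
    - ``splithalf``: three motifs, 12 trials per subgroup, no noise
      subgroups, sized for odd/even trial splitting.
    """
    rel24 = 1.0 + 0.15 * np.cos(np.arange(24) * 2.1)
    scenarios = {
        "three_motifs": GeneratorConfig(
            n_subgroups=24,
            motif_assignment=[0] * 6 + [1] * 6 + [2] * 6 + [None] * 6,
            relative_amplitude=rel24,
            snr=5.0,
        ),
        "single_motif": GeneratorConfig(
            n_subgroups=8,
            motif_assignment=[0] * 8,
            n_motifs=1,
            snr=5.0,
        ),
        "all_noise": GeneratorConfig(
            n_subgroups=8,
            motif_assignment=[None] * 8,
        ),
        "adaptation": GeneratorConfig(
            n_subgroups=4,
            motif_assignment=[0, 0, None, None],
            n_motifs=1,
            trials_per_subgroup=(11, 11),
            drift=np.array([0.06, 0.06, 0.0, 0.0]),
            snr=8.0,
        ),
        "splithalf": GeneratorConfig(
            n_subgroups=12,
            motif_assignment=[0] * 4 + [1] * 4 + [2] * 4,
            trials_per_subgroup=(12, 12),
            snr=5.0,
        ),
    }
    return scenarios


def scenario(name: str, seed: int | None = None, **overrides) -> GeneratorConfig:
    """Fetch a named scenario, optionally re-seeded or tweaked."""
    cfgs = default_scenarios()
    if name not in cfgs:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(cfgs)}")
    cfg = cfgs[name]
    if seed is not None:
        overrides["seed"] = seed
    return replace(cfg, **overrides) if overrides else cfg
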
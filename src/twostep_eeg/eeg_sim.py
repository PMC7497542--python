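"""Synthetic feedback-locked EEG epochs with configurable ground truth.

Each epoch is 1/f background noise plus Gaussian-windowed component
waveforms.  ERP components (P2-like and P3-like positivities, an FRN-like
fronto-central negativity) are phase-locked bumps; theta and delta
components are amplitude-modulated sinusoidal bursts with random phase per
trial (induced activity), so evoked and time-frequency measures can
dissociate.

Per-trial component amplitudes follow a linear model in the trial's
condition, valence, expectancy and |RPE|:

    amp = base + valence_coef * [loss]
          + expectancy_coef(condition) * [unexpected]
          + rpe_gain(condition) * |RPE|

The default configuration encodes the target dissociation: FRN and theta
couple to |RPE| and expectancy in both conditions, P3 and delta do so only
in the predictable condition.  The generator returns a ground-truth ledger
of the injected amplitudes for recovery testing.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SRATE = 512.0
TMIN = -1.0
TMAX = 1.5


@dataclass
class EpochSet:
    """Feedback-locked EEG epochs: trials x channels x samples, in uV.

    ``trial_meta`` carries one row per epoch (condition, valence,
    expectancy, abs_rpe, ...), aligned with ``data``.
    """

    data: np.ndarray
    srate: float
    tmin: float
    ch_names: tuple
    trial_meta: pd.DataFrame

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.trial_meta) != self.data.shape[0]:
            raise ValueError("metadata rows must match data rows")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel names must match data channels")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to feedback onset."""
        n = self.data.shape[2]
        return (self.tmin + np.arange(n) / self.srate) * 1000.0

    def channel(self, name: str) -> int:
        return self.ch_names.index(name)

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.srate, self.tmin,
                        tuple(self.ch_names),
                        self.trial_meta.copy())

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset epochs by boolean mask or integer indices."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            meta = self.trial_meta[mask]
        else:
            meta = self.trial_meta.iloc[mask]
        return EpochSet(self.data[mask], self.srate, self.tmin,
                        tuple(self.ch_names), meta.reset_index(drop=True))

    def to_mne(self):
        """Export to an mne.EpochsArray (volts); requires mne."""
        import mne
        info = mne.create_info(list(self.ch_names), self.srate, "eeg")
        return mne.EpochsArray(self.data * 1e-6, info, tmin=self.tmin,
                               verbose="error")


@dataclass
class ComponentSpec:
    """One generated component; amplitudes in uV, latencies/widths in ms.

    ``freq`` None -> phase-locked ERP bump; a frequency in Hz -> induced
    oscillatory burst (random phase per trial unless ``phase_locked``).
    """

    channel: str
    latency_ms: float
    width_ms: float
    base: float
    freq: float | None = None
    valence: float = 0.0                  # added on loss trials
    expectancy_predictable: float = 0.0   # added on unexpected, predictable
    expectancy_random: float = 0.0        # added on unexpected, random
    rpe_gain_predictable: float = 0.0     # x |RPE|, predictable
    rpe_gain_random: float = 0.0          # x |RPE|, random
    phase_locked: bool = True

    def amplitude(self, condition: str, valence: str, expectancy: str,
                  abs_rpe: float) -> float:
        amp = self.base
        if valence == "loss":
            amp += self.valence
        pred = condition == "predictable"
        if expectancy == "unexpected":
            amp += self.expectancy_predictable if pred \
                else self.expectancy_random
        amp += (self.rpe_gain_predictable if pred
                else self.rpe_gain_random) * abs_rpe
        return amp


def default_components() -> dict:
    """Ground-truth component model encoding the target dissociation."""
    return {
        # fixed positive deflections flanking the FRN at FCz
        "p2": ComponentSpec("FCz", 170.0, 25.0, base=5.0),
        "late_positivity": ComponentSpec("FCz", 400.0, 55.0, base=4.0),
        # FRN: negative-going; expectancy and |RPE| coupling in both
        # conditions (condition-blind)
        "frn": ComponentSpec("FCz", 270.0, 28.0, base=-2.0,
                             valence=-0.8,
                             expectancy_predictable=-1.5,
                             expectancy_random=-1.5,
                             rpe_gain_predictable=-1.5,
                             rpe_gain_random=-1.5),
        # P3: parietal positivity; expectancy and |RPE| coupling only in
        # the predictable condition
        "p3": ComponentSpec("Pz", 400.0, 60.0, base=6.0,
                            expectancy_predictable=2.5,
                            rpe_gain_predictable=2.5),
        # theta burst: condition-blind coupling
        "theta": ComponentSpec("FCz", 300.0, 60.0, base=1.5, freq=6.0,
                               valence=0.5,
                               expectancy_predictable=1.0,
                               expectancy_random=1.0,
                               rpe_gain_predictable=1.5,
                               rpe_gain_random=1.5,
                               phase_locked=False),
        # delta burst: predictable-only coupling; wins carry more power
        "delta": ComponentSpec("Pz", 400.0, 90.0, base=2.0, freq=2.5,
                               valence=-0.7,
                               expectancy_predictable=1.0,
                               rpe_gain_predictable=1.5,
                               phase_locked=False),
    }


@dataclass
class EEGGenConfig:
    srate: float = SRATE
    tmin: float = TMIN
    tmax: float = TMAX
    channels: tuple = ("FCz", "Pz")
    noise_amp: float = 8.0        # uV SD of the 1/f background
    components: dict = field(default_factory=default_components)

    def __post_init__(self):
        for name, c in self.components.items():
            if c.width_ms <= 0:
                raise ValueError(f"component {name}: width must be > 0")
        if self.noise_amp < 0:
            raise ValueError("noise amplitude must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round((self.tmax - self.tmin) * self.srate))


def perturb_config(cfg: EEGGenConfig, rng: np.random.Generator,
                   sd: float = 0.3) -> EEGGenConfig:
    """Subject-specific config: every effect coefficient (valence,
    expectancy, |RPE| gains) scaled by an independent (1 + N(0, sd))
    multiplier, emulating between-subject effect heterogeneity."""
    out = _copy.deepcopy(cfg)
    for c in out.components.values():
        for f in ("valence", "expectancy_predictable", "expectancy_random",
                  "rpe_gain_predictable", "rpe_gain_random"):
            v = getattr(c, f)
            if v != 0.0:
                setattr(c, f, v * (1.0 + sd * rng.standard_normal()))
    return out


def _one_over_f_noise(rng: np.random.Generator, n: int, n_epochs: int,
                      amp: float) -> np.ndarray:
    """1/f background: power spectral density proportional to 1/f,
    normalized to standard deviation ``amp`` per epoch."""
    if amp == 0.0:
        return np.zeros((n_epochs, n))
    n_f = n // 2 + 1
    f = np.arange(n_f, dtype=float)
    f[0] = np.inf  # no DC
    shape = 1.0 / np.sqrt(f)
    spec = (rng.standard_normal((n_epochs, n_f))
            + 1j * rng.standard_normal((n_epochs, n_f))) * shape
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return amp * x / sd


def generate_epochs(trials: pd.DataFrame, cfg: EEGGenConfig | None = None,
                    seed: int = 0, rpes=None
                    ) -> tuple[EpochSet, pd.DataFrame]:
    """Generate one epoch per trial row.

    ``trials`` needs columns condition, valence, expectancy and abs_rpe
    (the latter can instead be supplied as ``rpes``, a sequence of
    RPE records aligned with the rows).  Returns the epochs and the
    ground-truth ledger of injected per-trial component amplitudes.
    """
    cfg = cfg or EEGGenConfig()
    trials = trials.reset_index(drop=True)
    if rpes is not None:
        if len(rpes) != len(trials):
            raise ValueError("rpes and trials must be aligned")
        abs_rpe = np.array([r.abs_rpe for r in rpes])
    else:
        abs_rpe = trials["abs_rpe"].to_numpy(float)

    n_trials = len(trials)
    n = cfg.n_samples
    t_ms = (cfg.tmin + np.arange(n) / cfg.srate) * 1000.0
    rng = np.random.default_rng(seed)

    data = np.empty((n_trials, len(cfg.channels), n))
    for ch in range(len(cfg.channels)):
        data[:, ch] = _one_over_f_noise(rng, n, n_trials, cfg.noise_amp)

    ledger = {}
    for name, comp in cfg.components.items():
        ch = cfg.channels.index(comp.channel)
        env = np.exp(-0.5 * ((t_ms - comp.latency_ms) / comp.width_ms) ** 2)
        amps = np.array([
            comp.amplitude(row.condition, row.valence, row.expectancy,
                           abs_rpe[i])
            for i, row in enumerate(trials.itertuples())])
        if comp.freq is None:
            data[:, ch] += amps[:, None] * env[None, :]
        else:
            if comp.phase_locked:
                phases = np.zeros(n_trials)
            else:
                phases = rng.uniform(0.0, 2 * np.pi, size=n_trials)
            carrier = np.cos(
                2 * np.pi * comp.freq * (t_ms - comp.latency_ms) / 1000.0
                + phases[:, None])
            data[:, ch] += amps[:, None] * env[None, :] * carrier
        ledger[name] = amps

    meta = trials.copy()
    meta["abs_rpe"] = abs_rpe
    epochs = EpochSet(data=data, srate=cfg.srate, tmin=cfg.tmin,
                      ch_names=tuple(cfg.channels), trial_meta=meta)
    return epochs, pd.DataFrame(ledger)


def inject_artifacts(epochs: EpochSet, fraction: float,
                     magnitude: float = 500.0, seed: int = 0) -> EpochSet:
    """Add large-amplitude square pulses to a random subset of epochs.

    Each selected epoch gets a 100 ms pulse of +/- ``magnitude`` uV on one
    channel; affected epochs are flagged in ``trial_meta['artifact']``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    out = epochs.copy()
    rng = np.random.default_rng(seed)
    hit = rng.random(out.n_trials) < fraction
    n = out.data.shape[2]
    width = int(round(0.1 * out.srate))
    for i in np.flatnonzero(hit):
        ch = int(rng.integers(out.data.shape[1]))
        start = int(rng.integers(n - width))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out.data[i, ch, start:start + width] += sign * magnitude
    meta = out.trial_meta
    meta["artifact"] = hit
    return out
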
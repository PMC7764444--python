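"""Seeded synthetic biosignal generators.

These are parametric signal models — periodic templates plus noise — not
physiological simulators. Their purpose is to reproduce the *residual
statistics* the codec is sensitive to, so the whole pipeline is testable
without any recording:

* ``ecg-like``: narrow periodic spikes (a QRS surrogate) over a slow
  baseline; residual magnitudes have a unimodal, rapidly decaying histogram.
* ``ppg-like``: smooth periodic pulses, optionally with additive sinusoidal
  interference whose steep slopes put a second mode into the
  residual-magnitude histogram; ``dynamic_range_fraction`` near 1 mimics a
  near-saturating finger PPG.
* ``scg-like``: low-amplitude oscillatory bursts plus Bernoulli impulses —
  the impulsive noise inflates the residual support and breaks the
  adjacent-samples-correlated assumption of DPCM.
* ``gcg-like``: noise-dominated low-amplitude channel at 16-bit depth.
* ``uniform-noise``: independent uniform samples; a stationary worst case
  with wide residual support.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .residuals import ChannelSpec

__all__ = ["SignalRecipe", "generate_channel", "generate_dataset", "default_roster"]

_KINDS = {"ecg-like", "ppg-like", "scg-like", "gcg-like", "uniform-noise"}
# Mains-harmonic additive interference for ppg-like channels. A high
# harmonic has a steep slope, so its per-sample residuals separate cleanly
# from the pulse's and put a distinct second mode into the magnitude
# histogram.
_INTERFERENCE_HZ = 120.0


@dataclass(frozen=True)
class SignalRecipe:
    """Parameters of one synthetic channel. Amplitudes are ADC counts."""

    name: str
    kind: str
    sampling_rate: float = 1600.0
    duration: float = 4.0
    bit_depth: int = 14
    heart_rate: float = 1.2
    noise_sd: float = 4.0
    impulse_rate: float = 0.0
    impulse_scale: float = 0.0
    interference_amplitude: float = 0.0
    dynamic_range_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {sorted(_KINDS)}")
        if min(self.noise_sd, self.impulse_scale, self.interference_amplitude,
               self.impulse_rate) < 0:
            raise ValueError("amplitudes and rates must be >= 0")
        if not 0 < self.dynamic_range_fraction <= 1:
            raise ValueError("dynamic_range_fraction must be in (0, 1]")
        if self.duration * self.sampling_rate < 1:
            raise ValueError("duration x sampling_rate must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def channel_spec(self, samples_per_packet: int = 50) -> ChannelSpec:
        return ChannelSpec(self.name, self.bit_depth, samples_per_packet)


def _beat_phase(t: np.ndarray, heart_rate: float) -> np.ndarray:
    return np.mod(t * heart_rate, 1.0)


def generate_channel(recipe: SignalRecipe) -> np.ndarray:
    """Deterministic unsigned integer samples in ``[0, 2**M)`` for one channel."""
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_samples
    fs = recipe.sampling_rate
    t = np.arange(n) / fs
    full = float(1 << recipe.bit_depth)
    mid = full / 2.0
    amp = recipe.dynamic_range_fraction * (full / 2.0 - 1.0)
    phase = _beat_phase(t, recipe.heart_rate)

    if recipe.kind == "ecg-like":
        # narrow gaussian spike once per beat + slow baseline wander
        spike = np.exp(-0.5 * ((phase - 0.15) / 0.012) ** 2)
        baseline = 0.08 * np.sin(2 * np.pi * 0.25 * t + 0.7)
        signal = mid + amp * (0.9 * spike + baseline)
    elif recipe.kind == "ppg-like":
        pulse = (
            0.6 * np.sin(2 * np.pi * phase - np.pi / 2)
            + 0.25 * np.sin(4 * np.pi * phase + 0.8)
            + 0.1 * np.sin(6 * np.pi * phase + 1.9)
        )
        signal = mid + amp * pulse
        if recipe.interference_amplitude > 0:
            # gated interference (on half the time, as from intermittent
            # contact/motion artifact): quiet stretches keep a sharp
            # residual mode near zero while bursts add a second mode at the
            # interference slope, giving the multimodal histogram
            gate = np.sin(2 * np.pi * 0.5 * t) > 0
            signal = signal + gate * recipe.interference_amplitude * np.sin(
                2 * np.pi * _INTERFERENCE_HZ * t
            )
    elif recipe.kind == "scg-like":
        # short oscillatory burst after each beat onset
        burst_env = np.exp(-0.5 * ((phase - 0.25) / 0.04) ** 2)
        burst = burst_env * np.sin(2 * np.pi * 25.0 * t)
        signal = mid + 0.15 * amp * burst
        if recipe.impulse_rate > 0 and recipe.impulse_scale > 0:
            hits = rng.random(n) < recipe.impulse_rate
            signal = signal + hits * rng.laplace(0.0, recipe.impulse_scale, n)
    elif recipe.kind == "gcg-like":
        signal = mid + 0.05 * amp * np.sin(2 * np.pi * recipe.heart_rate * t)
    else:  # uniform-noise
        half = max(recipe.noise_sd, 1.0)
        signal = mid + rng.uniform(-half, half, n)

    if recipe.kind != "uniform-noise" and recipe.noise_sd > 0:
        signal = signal + rng.normal(0.0, recipe.noise_sd, n)

    return np.clip(np.rint(signal), 0, full - 1).astype(np.int64)


def generate_dataset(
    recipes: list[SignalRecipe], samples_per_packet: int = 50
) -> tuple[dict[str, np.ndarray], dict[str, ChannelSpec]]:
    """Aligned multichannel dataset plus the channel specs for its sidecar."""
    if not recipes:
        raise ValueError("need at least one recipe")
    n_set = {r.n_samples for r in recipes}
    if len(n_set) != 1:
        raise ValueError("all recipes must produce the same number of samples")
    names = [r.name for r in recipes]
    if len(set(names)) != len(names):
        raise ValueError("channel names must be unique")
    channels = {r.name: generate_channel(r) for r in recipes}
    specs = {r.name: r.channel_spec(samples_per_packet) for r in recipes}
    return channels, specs


def default_roster(
    duration: float = 4.0, sampling_rate: float = 1600.0, seed: int = 0
) -> list[SignalRecipe]:
    """Ten-channel roster mirroring the wearable: seven 14-bit channels
    (3 SCG axes, ECG, two chest PPGs, one finger PPG) and three 16-bit GCG
    axes. Per-channel seeds are derived from ``seed`` so channels are
    independent but the dataset as a whole is reproducible."""
    base = dict(sampling_rate=sampling_rate, duration=duration)
    scg = dict(kind="scg-like", noise_sd=6.0, impulse_rate=0.002, impulse_scale=120.0)
    roster = [
        SignalRecipe(name="scg_x", **scg, **base),
        SignalRecipe(name="scg_y", **scg, **base),
        SignalRecipe(name="scg_z", **scg, **base),
        SignalRecipe(name="ecg", kind="ecg-like", noise_sd=4.0,
                     dynamic_range_fraction=0.6, **base),
        SignalRecipe(name="ppg_c1", kind="ppg-like", noise_sd=6.0,
                     interference_amplitude=150.0, dynamic_range_fraction=0.4, **base),
        SignalRecipe(name="ppg_c2", kind="ppg-like", noise_sd=6.0,
                     interference_amplitude=150.0, dynamic_range_fraction=0.4, **base),
        SignalRecipe(name="ppg_f", kind="ppg-like", noise_sd=5.0,
                     dynamic_range_fraction=0.95, **base),
        SignalRecipe(name="gcg_x", kind="gcg-like", bit_depth=16, noise_sd=10.0, **base),
        SignalRecipe(name="gcg_y", kind="gcg-like", bit_depth=16, noise_sd=10.0, **base),
        SignalRecipe(name="gcg_z", kind="gcg-like", bit_depth=16, noise_sd=10.0, **base),
    ]
    return [replace(r, seed=seed + 7919 * i) for i, r in enumerate(roster)]
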
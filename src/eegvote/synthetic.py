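"""Synthetic labeled EEG-like trial generation.

Each trial is per-channel 1/f (pink) background noise plus a narrow-band
oscillatory component (random-phase spectral noise confined to the interior
of the effect band, a fresh draw per trial and channel, so the classes are
not trivially separable by phase).  On a chosen subset of channels the
oscillation amplitude is multiplied by ``effect_gain`` for HIGH-state
trials, so class information lives only in the band power of those channels
within ``effect_band`` — exactly the structure the rhythm / channel voting
pipeline is designed to find.  The carrier is kept strictly inside its
nominal band so that no class information sits on band edges, where
soft-edged analysis filters would smear it into neighboring rhythms.

The default geometry mirrors a standard affective-EEG recording setup:
32 channels of 8064 samples at 128 Hz (63 s trials) with 10-20 channel
names; :func:`deap_like_spec` pins that preset.  Amplitudes are on a
realistic scalp-EEG scale (background s.d. ~10 uV, oscillation s.d. ~5 uV
in the LOW state).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigError
from .recording import (
    ALPHA, DEAP_CHANNELS, HIGH, LOW, BandDefinition, TrialDataset,
)

#: Default effect channels: five 10-20 sites spread over frontal, temporal
#: and occipital cortex (indices into DEAP_CHANNELS).
DEFAULT_EFFECT_CHANNELS: tuple[int, ...] = (0, 5, 7, 13, 25)  # Fp1 FC1 T7 O1 T8


@dataclass
class SyntheticSpec:
    """Generation parameters.

    ``effect_gain`` multiplies the oscillation amplitude on the effect
    channels for HIGH trials; gain 1 makes the two classes exchangeable
    (a null dataset).  ``background_sd`` is the pink-noise standard
    deviation and ``oscillation_sd`` the LOW-state band component standard
    deviation, both in microvolts.  ``white_sd`` adds per-channel sensor
    noise.
    """

    n_trials: int = 80
    n_channels: int = 32
    n_samples: int = 8064
    fs: float = 128.0
    effect_channels: tuple[int, ...] = DEFAULT_EFFECT_CHANNELS
    effect_band: BandDefinition = field(default_factory=lambda: ALPHA)
    effect_gain: float = 4.0
    background_sd: float = 10.0
    oscillation_sd: float = 5.0
    white_sd: float = 1.0
    class_balance: float = 0.5
    seed: int = 0
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.n_trials < 1 or self.n_channels < 1 or self.n_samples < 2:
            raise ConfigError("degenerate dataset dimensions")
        if self.effect_gain < 1:
            raise ConfigError("effect_gain must be >= 1")
        if not 0 < self.class_balance < 1:
            raise ConfigError("class_balance must be in (0, 1)")
        if any(not 0 <= c < self.n_channels for c in self.effect_channels):
            raise ConfigError("effect_channels outside the valid channel range")
        self.effect_band.validate_for_fs(self.fs)

    def resolve_channel_names(self) -> list[str]:
        if self.channel_names is not None:
            if len(self.channel_names) != self.n_channels:
                raise ConfigError("channel_names length mismatch")
            return list(self.channel_names)
        if self.n_channels <= len(DEAP_CHANNELS):
            return list(DEAP_CHANNELS[: self.n_channels])
        return [f"ch{i:02d}" for i in range(self.n_channels)]


def deap_like_spec(**overrides) -> SyntheticSpec:
    """Preset pinning the 32-channel / 8064-sample / 128 Hz geometry with
    the standard 10-20 channel-name list."""
    spec = SyntheticSpec(**overrides)
    if spec.n_channels != 32 or spec.n_samples != 8064 or spec.fs != 128.0:
        raise ConfigError("deap_like_spec pins 32 channels x 8064 samples at 128 Hz")
    return spec


#: The class-carrying oscillation occupies the interior of the effect band,
#: inset by this fraction of the bandwidth on each side, so soft-edged
#: analysis filters attribute the effect uniquely to its nominal rhythm.
CARRIER_INSET_FRACTION = 0.125


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                n_samples: int, fs: float) -> np.ndarray:
    """1/f-power noise via spectral shaping, unit variance per row."""
    freqs = np.fft.rfftfreq(n_samples, d=1 / fs)
    amp = np.zeros(freqs.size, dtype=np.float32)
    nonzero = freqs > 0
    amp[nonzero] = 1.0 / np.sqrt(freqs[nonzero])  # power ~ 1/f
    spectrum = amp * (
        rng.standard_normal(shape + (freqs.size,), dtype=np.float32)
        + 1j * rng.standard_normal(shape + (freqs.size,), dtype=np.float32)
    )
    x = np.fft.irfft(spectrum, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _band_noise(rng: np.random.Generator, shape: tuple[int, ...],
                n_samples: int, fs: float, band: BandDefinition) -> np.ndarray:
    """Unit-variance narrow-band noise carrier.

    Built from random spectral components strictly inside the band interior
    (the band inset by :data:`CARRIER_INSET_FRACTION` of its width per side),
    so the carrier has exactly zero power outside its nominal rhythm — a
    random multi-component oscillation rather than a pure sine.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1 / fs)
    inset = CARRIER_INSET_FRACTION * (band.high_hz - band.low_hz)
    mask = (freqs >= band.low_hz + inset) & (freqs <= band.high_hz - inset)
    n_bins = int(mask.sum())
    if n_bins == 0:
        raise ConfigError(
            f"band {band.name!r} too narrow for a carrier at {n_samples} "
            f"samples / {fs} Hz"
        )
    spectrum = np.zeros(shape + (freqs.size,), dtype=np.complex64)
    spectrum[..., mask] = (
        rng.standard_normal(shape + (n_bins,), dtype=np.float32)
        + 1j * rng.standard_normal(shape + (n_bins,), dtype=np.float32)
    )
    x = np.fft.irfft(spectrum, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def generate_dataset(spec: SyntheticSpec) -> TrialDataset:
    """Deterministic labeled dataset per ``spec`` (same seed, same bits).

    Label counts follow ``class_balance`` exactly (HIGH count =
    round(n_trials * class_balance)), with label order shuffled by the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_high = int(round(spec.n_trials * spec.class_balance))
    labels = np.array([HIGH] * n_high + [LOW] * (spec.n_trials - n_high))
    rng.shuffle(labels)

    shape = (spec.n_trials, spec.n_channels)
    data = spec.background_sd * _pink_noise(rng, shape, spec.n_samples, spec.fs)
    carrier = spec.oscillation_sd * _band_noise(
        rng, shape, spec.n_samples, spec.fs, spec.effect_band
    )
    gains = np.ones(shape)
    if spec.effect_gain > 1:
        idx = np.asarray(spec.effect_channels, dtype=int)
        high_rows = np.where(labels == HIGH)[0]
        gains[np.ix_(high_rows, idx)] = spec.effect_gain
    data = data + gains[..., None].astype(np.float32) * carrier
    if spec.white_sd > 0:
        data = data + spec.white_sd * rng.standard_normal(
            data.shape, dtype=np.float32
        )
    return TrialDataset(
        data=data,
        fs=spec.fs,
        channel_names=spec.resolve_channel_names(),
        labels=labels,
        trial_ids=[f"trial{i:04d}" for i in range(spec.n_trials)],
    )


def generate_null_dataset(n_trials: int = 80, n_channels: int = 32,
                          seed: int = 0, **overrides) -> TrialDataset:
    """Null dataset: ``effect_gain=1`` so labels carry no signal."""
    if n_trials < 4:
        raise ConfigError("need at least 4 trials for a null dataset")
    spec = SyntheticSpec(n_trials=n_trials, n_channels=n_channels,
                         effect_gain=1.0, seed=seed, **overrides)
    return generate_dataset(spec)


def spec_to_dict(spec: SyntheticSpec) -> dict:
    d = asdict(spec)
    d["effect_band"] = {
        "name": spec.effect_band.name,
        "low_hz": spec.effect_band.low_hz,
        "high_hz": spec.effect_band.high_hz,
    }
    d["effect_channels"] = list(spec.effect_channels)
    if d.get("channel_names") is not None:
        d["channel_names"] = list(d["channel_names"])
    return d
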
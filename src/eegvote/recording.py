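"""Domain types: recordings, trial datasets, labels and rhythm bands.

An :class:`EEGRecording` is one trial — a channels x samples matrix in
microvolts with its sampling rate and 10-20 channel labels.  A
:class:`TrialDataset` stacks many same-shaped trials into a 3-D array so the
filtering and feature stages can run vectorized across the whole dataset.

Binary states are encoded as integers ``LOW = 0`` / ``HIGH = 1`` (HIGH is the
positive class throughout: high valence or high arousal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, DataError

LOW: int = 0
HIGH: int = 1

LABEL_NAMES = {LOW: "LOW", HIGH: "HIGH"}
NAME_LABELS = {"LOW": LOW, "HIGH": HIGH}

#: 32-channel 10-20 montage in the channel order used by the DEAP recordings.
DEAP_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)


def parse_label(value) -> int:
    """Map ``'LOW'``/``'HIGH'`` (case-insensitive) or 0/1 to the int encoding."""
    if isinstance(value, str):
        key = value.strip().upper()
        if key not in NAME_LABELS:
            raise DataError(f"unknown label {value!r}; expected LOW or HIGH")
        return NAME_LABELS[key]
    iv = int(value)
    if iv not in (LOW, HIGH):
        raise DataError(f"unknown label {value!r}; expected 0/1 or LOW/HIGH")
    return iv


@dataclass(frozen=True)
class BandDefinition:
    """A named EEG rhythm band ``[low_hz, high_hz)``.

    A ``low_hz`` of 0 means the band is realized as a low-pass (the delta
    rhythm retains DC).
    """

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not (0 <= self.low_hz < self.high_hz):
            raise ConfigError(
                f"band {self.name!r}: need 0 <= low < high, "
                f"got ({self.low_hz}, {self.high_hz})"
            )

    def validate_for_fs(self, fs: float) -> None:
        if self.high_hz >= fs / 2:
            raise ConfigError(
                f"band {self.name!r} upper edge {self.high_hz} Hz is at or "
                f"above Nyquist ({fs / 2} Hz)"
            )


#: Canonical rhythm bands, in the fixed analysis order.
DELTA = BandDefinition("delta", 0.0, 4.0)
THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 12.0)
BETA = BandDefinition("beta", 12.0, 30.0)
GAMMA = BandDefinition("gamma", 30.0, 45.0)


def standard_bands(include_gamma: bool = False) -> list[BandDefinition]:
    """The four rhythms used for classification, in fixed order.

    Gamma (30-45 Hz) is available for display/exploration behind the flag but
    takes no part in classification or voting.
    """
    bands = [DELTA, THETA, ALPHA, BETA]
    if include_gamma:
        bands.append(GAMMA)
    return bands


def band_by_name(name: str) -> BandDefinition:
    for band in standard_bands(include_gamma=True):
        if band.name == name.lower():
            return band
    raise ConfigError(f"unknown rhythm {name!r}")


@dataclass
class EEGRecording:
    """One EEG trial: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    channel_names: Sequence[str]
    trial_id: str = "trial"
    label: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("data must be a 2-D channels x samples matrix")
        n_channels, n_samples = self.data.shape
        if n_channels < 1 or n_samples < 2:
            raise DataError(
                f"need >= 1 channel and >= 2 samples, got {self.data.shape}"
            )
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != n_channels:
            raise DataError(
                f"{len(self.channel_names)} channel names for "
                f"{n_channels} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise DataError("data contains non-finite values")
        if self.label is not None:
            self.label = parse_label(self.label)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "EEGRecording":
        """Copy of this recording with new sample values (metadata kept)."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class TrialDataset:
    """A stack of same-shaped labeled trials.

    ``data`` has shape (n_trials, n_channels, n_samples); ``labels`` is an
    int array of LOW/HIGH, or None for unlabeled data.
    """

    data: np.ndarray
    fs: float
    channel_names: Sequence[str]
    labels: np.ndarray | None = None
    trial_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        if self.data.ndim != 3:
            raise DataError("dataset data must be 3-D (trials, channels, samples)")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[1]:
            raise DataError("channel_names length does not match data")
        if self.labels is not None:
            self.labels = np.asarray(
                [parse_label(v) for v in np.asarray(self.labels).ravel()], dtype=int
            )
            if self.labels.shape[0] != self.data.shape[0]:
                raise DataError("labels length does not match number of trials")
        if not self.trial_ids:
            self.trial_ids = [f"trial{i:04d}" for i in range(self.data.shape[0])]
        else:
            self.trial_ids = [str(t) for t in self.trial_ids]
            if len(self.trial_ids) != self.data.shape[0]:
                raise DataError("trial_ids length does not match number of trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def to_recordings(self) -> list[EEGRecording]:
        labels = self.labels if self.labels is not None else [None] * self.n_trials
        return [
            EEGRecording(
                data=self.data[i],
                fs=self.fs,
                channel_names=self.channel_names,
                trial_id=self.trial_ids[i],
                label=labels[i],
            )
            for i in range(self.n_trials)
        ]

    @classmethod
    def from_recordings(cls, recordings: Iterable[EEGRecording]) -> "TrialDataset":
        recs = list(recordings)
        if not recs:
            raise DataError("cannot build a dataset from zero recordings")
        first = recs[0]
        for r in recs[1:]:
            if r.data.shape != first.data.shape or r.fs != first.fs:
                raise DataError("all trials must share shape and sampling rate")
            if [c.lower() for c in r.channel_names] != [
                c.lower() for c in first.channel_names
            ]:
                raise DataError("all trials must share channel names")
        labels = [r.label for r in recs]
        have_labels = all(l is not None for l in labels)
        return cls(
            data=np.stack([r.data for r in recs]),
            fs=first.fs,
            channel_names=first.channel_names,
            labels=np.array(labels) if have_labels else None,
            trial_ids=[r.trial_id for r in recs],
        )
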
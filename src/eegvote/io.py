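"""File I/O: CSV and EDF trial recordings, labels, features, predictions.

CSV trials are channels x samples with an optional header row of channel
names.  EDF reading goes through MNE; writing uses a minimal single-record
EDF encoder (EDF stores int16 samples against per-channel physical ranges,
so round-trips are exact only to ~16-bit amplitude resolution).  Labels
travel separately as a two-column ``trial_id,label`` CSV with label in
{LOW, HIGH}.
"""

from __future__ import annotations

import csv
import io as _io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .features import FeatureConfig, feature_labels
from .recording import (
    LABEL_NAMES, EEGRecording, TrialDataset, parse_label,
)


# ---------------------------------------------------------------------------
# CSV trials


def _read_csv_recording(path: Path, header: bool = True) -> EEGRecording:
    try:
        raw = path.read_text()
    except OSError as exc:
        raise DataError(f"cannot read {path}: {exc}") from exc
    rows = [r for r in csv.reader(_io.StringIO(raw)) if r]
    if not rows:
        raise DataError(f"{path} is empty")
    names: list[str] | None = None
    fs = 128.0
    start = 0
    if rows[0][0].startswith("#fs="):
        fs = float(rows[0][0].split("=", 1)[1])
        start = 1
    if header:
        names = [c.strip() for c in rows[start]]
        start += 1
    data = []
    for ri, row in enumerate(rows[start:], start=start):
        vals = []
        for ci, cell in enumerate(row):
            try:
                vals.append(float(cell))
            except ValueError as exc:
                raise DataError(
                    f"{path}: non-numeric cell at row {ri + 1}, column {ci + 1}: "
                    f"{cell!r}"
                ) from exc
        data.append(vals)
    if names is None:
        names = [f"ch{i:02d}" for i in range(len(data))]
    return EEGRecording(data=np.array(data), fs=fs, channel_names=names,
                        trial_id=path.stem)


def _write_csv_recording(rec: EEGRecording, path: Path) -> None:
    lines = [f"#fs={rec.fs:g}", ",".join(rec.channel_names)]
    for row in rec.data:
        lines.append(",".join(repr(float(v)) for v in row))
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise DataError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# EDF


def _edf_samples_per_record(path: Path) -> list[int]:
    """Per-signal samples-per-record straight from the EDF header (used to
    reject mixed-rate files before handing off to MNE, which would resample)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise DataError(f"{path}: truncated EDF header")
        n_ch = int(head[252:256].decode("ascii", "replace").strip() or 0)
        per_sig = fh.read(256 * n_ch)
    offset = n_ch * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    fields = per_sig[offset: offset + 8 * n_ch]
    try:
        return [int(fields[8 * i: 8 * (i + 1)].decode("ascii").strip())
                for i in range(n_ch)]
    except ValueError as exc:
        raise DataError(f"{path}: malformed EDF signal header") from exc


def _read_edf_recording(path: Path) -> EEGRecording:
    if len(set(_edf_samples_per_record(path))) > 1:
        raise DataError(
            f"{path}: signals with mixed sampling rates are unsupported"
        )
    try:
        import mne
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except OSError as exc:
        raise DataError(f"cannot read {path}: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # MNE holds EEG in volts
    return EEGRecording(
        data=data_uv,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        trial_id=path.stem,
    )


def _edf_header_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf_recording(rec: EEGRecording, path: Path) -> None:
    """Minimal EDF writer: one data record holding the whole trial,
    int16 samples scaled to each channel's physical range (microvolts)."""
    n_ch, n_samp = rec.data.shape
    duration = n_samp / rec.fs
    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    span = phys_max - phys_min
    flat = span <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    span = phys_max - phys_min
    dig_min, dig_max = -32768, 32767
    scaled = (rec.data - phys_min[:, None]) / span[:, None]
    digital = np.round(scaled * (dig_max - dig_min) + dig_min).astype("<i2")

    header = b""
    header += _edf_header_field("0", 8)                      # version
    header += _edf_header_field("X X X X", 80)               # patient id
    header += _edf_header_field(f"Startdate X {rec.trial_id}", 80)
    header += _edf_header_field("01.01.00", 8)               # start date
    header += _edf_header_field("00.00.00", 8)               # start time
    header += _edf_header_field(str(256 * (1 + n_ch)), 8)    # header bytes
    header += _edf_header_field("", 44)                      # reserved
    header += _edf_header_field("1", 8)                      # n data records
    header += _edf_header_field(f"{duration:.6g}", 8)        # record duration
    header += _edf_header_field(str(n_ch), 4)

    def per_channel(values, width):
        return b"".join(_edf_header_field(v, width) for v in values)

    header += per_channel(rec.channel_names, 16)             # labels
    header += per_channel([""] * n_ch, 80)                   # transducer
    header += per_channel(["uV"] * n_ch, 8)                  # physical dim
    header += per_channel([f"{v:.6g}" for v in phys_min], 8)
    header += per_channel([f"{v:.6g}" for v in phys_max], 8)
    header += per_channel([str(dig_min)] * n_ch, 8)
    header += per_channel([str(dig_max)] * n_ch, 8)
    header += per_channel([""] * n_ch, 80)                   # prefiltering
    header += per_channel([str(n_samp)] * n_ch, 8)           # samples/record
    header += per_channel([""] * n_ch, 32)                   # reserved

    try:
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(digital.tobytes())                      # record: ch-major
    except OSError as exc:
        raise DataError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# public recording API


def read_recording(path, format: str | None = None, header: bool = True
                   ) -> EEGRecording:
    """Read one trial from an EDF or CSV file (format inferred from the
    suffix when not given)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return _read_csv_recording(path, header=header)
    if fmt == "edf":
        return _read_edf_recording(path)
    raise DataError(f"unsupported recording format {fmt!r}")


def write_recording(rec: EEGRecording, path, format: str | None = None) -> None:
    """Write one trial as EDF or CSV; round-trips preserve shape, channel
    names and sampling rate (EDF amplitudes to 16-bit resolution)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        _write_csv_recording(rec, path)
    elif fmt == "edf":
        _write_edf_recording(rec, path)
    else:
        raise DataError(f"unsupported recording format {fmt!r}")


# ---------------------------------------------------------------------------
# labels, datasets, features, predictions


def read_labels(path) -> dict[str, int]:
    """Two-column ``trial_id,label`` CSV -> {trial_id: LOW/HIGH int}."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected columns trial_id,label")
    return {
        str(t): parse_label(l)
        for t, l in zip(df.iloc[:, 0], df.iloc[:, 1])
    }


def write_labels(dataset: TrialDataset, path) -> None:
    if dataset.labels is None:
        raise DataError("dataset has no labels to write")
    pd.DataFrame({
        "trial_id": dataset.trial_ids,
        "label": [LABEL_NAMES[l] for l in dataset.labels],
    }).to_csv(path, index=False)


def write_dataset(dataset: TrialDataset, out_dir, format: str = "csv") -> list[Path]:
    """Write each trial as ``<trial_id>.<format>`` plus ``labels.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in dataset.to_recordings():
        p = out_dir / f"{rec.trial_id}.{format}"
        write_recording(rec, p, format)
        paths.append(p)
    if dataset.labels is not None:
        write_labels(dataset, out_dir / "labels.csv")
    return paths


def read_dataset(trial_paths, labels_path=None, format: str | None = None
                 ) -> TrialDataset:
    """Assemble a dataset from per-trial files and an optional labels CSV."""
    recs = [read_recording(p, format) for p in trial_paths]
    if labels_path is not None:
        labels = read_labels(labels_path)
        for rec in recs:
            if rec.trial_id not in labels:
                raise DataError(f"no label for trial {rec.trial_id!r}")
            rec.label = labels[rec.trial_id]
    return TrialDataset.from_recordings(recs)


def features_to_frame(features: np.ndarray, dataset: TrialDataset,
                      band_names: list[str],
                      cfg: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """Tidy long-format frame of a (trials, bands, channels, features)
    tensor: trial_id, channel, rhythm, node_level, node_index,
    feature_name, value."""
    labels = feature_labels(cfg)
    n_trials, n_bands, n_channels, n_feat = features.shape
    node_level = [int(l[1]) for l in labels]
    node_index = [int(l.split("_")[0][3:]) for l in labels]
    feat_name = [l.split("_", 1)[1] for l in labels]
    frames = []
    for bi, band in enumerate(band_names):
        for ci, ch in enumerate(dataset.channel_names):
            frames.append(pd.DataFrame({
                "trial_id": np.repeat(dataset.trial_ids, n_feat),
                "channel": ch,
                "rhythm": band,
                "node_level": node_level * n_trials,
                "node_index": node_index * n_trials,
                "feature_name": feat_name * n_trials,
                "value": features[:, bi, ci, :].ravel(),
            }))
    return pd.concat(frames, ignore_index=True)


def write_predictions(dataset: TrialDataset, predictions: np.ndarray, path
                      ) -> None:
    """``trial_id,predicted,truth`` CSV."""
    truth = (
        [LABEL_NAMES[l] for l in dataset.labels]
        if dataset.labels is not None else [""] * dataset.n_trials
    )
    pd.DataFrame({
        "trial_id": dataset.trial_ids,
        "predicted": [LABEL_NAMES[p] for p in np.asarray(predictions, dtype=int)],
        "truth": truth,
    }).to_csv(path, index=False)
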
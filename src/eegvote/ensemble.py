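"""KNN classification, channel ranking and two-step majority voting.

The decoding scheme: for each rhythm band, every channel is scored by
10-fold cross-validated KNN on its 42-element feature vector; the five
best-scoring channels' out-of-fold prediction vectors are majority-voted
into a per-rhythm prediction.  The per-rhythm predictions are then voted a
second time; with the four standard rhythms that vote would be even, so the
rhythm with the highest first-step voted accuracy is duplicated once to keep
the voter count odd.

Channel selection reuses the same out-of-fold predictions that are then
voted, which embeds selection optimism in the reported ensemble accuracy
(deliberately, mirroring how such pipelines are usually evaluated on a
single dataset).  A nested mode that re-selects channels inside each
training fold is available via ``nested_selection=True`` and gives
honest ensemble accuracy estimates at extra cost.

All tie-breaks are deterministic and documented: accuracy ties in ranking
fall back to sensitivity and then channel order; even-split votes go to the
highest-ranked voter; rhythm-duplication ties go to the earlier band in
standard order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigError, DataError
from .features import FeatureConfig, batch_channel_features
from .filtering import FilterSpec, denoise_array, extract_rhythm_array
from .recording import HIGH, LOW, BandDefinition, TrialDataset, standard_bands


@dataclass(frozen=True)
class KNNConfig:
    """k-nearest-neighbor settings (defaults: k=3, Minkowski exponent 2,
    features z-scored with training-fold statistics)."""

    k: int = 3
    minkowski_p: float = 2.0
    standardize: bool = True

    def __post_init__(self):
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.minkowski_p < 1:
            raise ConfigError("Minkowski exponent must be >= 1")


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings (default: stratified 10-fold)."""

    n_folds: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if self.n_folds < 2:
            raise ConfigError("need at least 2 folds")


@dataclass
class ChannelEvaluation:
    """Out-of-fold KNN performance of one channel under one rhythm."""

    channel: str
    rhythm: str
    channel_index: int
    oof_predictions: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass
class RhythmVote:
    """First-step result for one rhythm."""

    rhythm: str
    top_channels: list[str]
    top_channel_indices: list[int]
    channel_evaluations: list[ChannelEvaluation]
    predictions: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass
class EnsembleResult:
    """Full two-step output: per-rhythm votes, the duplicated rhythm, and the
    final cross-rhythm vote with its metrics."""

    per_rhythm: dict[str, RhythmVote]
    duplicated_rhythm: str | None
    final_predictions: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float

    def to_dict(self) -> dict:
        return {
            "per_rhythm": {
                name: {
                    "top_channels": rv.top_channels,
                    "channel_metrics": [
                        {
                            "channel": ev.channel,
                            "sensitivity": ev.sensitivity,
                            "specificity": ev.specificity,
                            "accuracy": ev.accuracy,
                        }
                        for ev in rv.channel_evaluations
                    ],
                    "vote": {
                        "sensitivity": rv.sensitivity,
                        "specificity": rv.specificity,
                        "accuracy": rv.accuracy,
                    },
                }
                for name, rv in self.per_rhythm.items()
            },
            "duplicated_rhythm": self.duplicated_rhythm,
            "final": {
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy": self.accuracy,
            },
        }


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(predictions: np.ndarray, truth: np.ndarray,
                    positive: int = HIGH) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) with HIGH as the positive class.

    If the truth contains a single class, the undefined rate is NaN while
    accuracy is still computed.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise DataError("predictions and truth must have equal length")
    accuracy = float(np.mean(predictions == truth))
    pos = truth == positive
    neg = ~pos
    sensitivity = float(np.mean(predictions[pos] == positive)) if pos.any() else float("nan")
    specificity = float(np.mean(predictions[neg] != positive)) if neg.any() else float("nan")
    return accuracy, sensitivity, specificity


# ---------------------------------------------------------------------------
# KNN


def knn_fit_predict(train_X: np.ndarray, train_y: np.ndarray,
                    test_X: np.ndarray, cfg: KNNConfig = KNNConfig()) -> np.ndarray:
    """Predict test labels by majority over the k nearest training samples.

    Distances use the configured Minkowski exponent.  With ``standardize``
    on, features are z-scored using training-set statistics only
    (zero-variance features are left unscaled).  Neighbor distance ties are
    broken toward the lower training index; a tied class vote (possible for
    even k) goes to the nearest neighbor's class.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = np.asarray(train_y, dtype=int)
    if train_X.ndim != 2 or test_X.ndim != 2 or train_X.shape[1] != test_X.shape[1]:
        raise DataError("train/test feature matrices must be 2-D with equal columns")
    n_train = train_X.shape[0]
    if cfg.k > n_train:
        raise ConfigError(f"k={cfg.k} exceeds {n_train} training samples")
    if np.unique(train_y).size < 2:
        raise ConfigError("training set must contain both classes")

    if cfg.standardize:
        mu = train_X.mean(axis=0)
        sd = train_X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        train_X = (train_X - mu) / sd
        test_X = (test_X - mu) / sd

    # query every training point: datasets here are small, and a full
    # (distance, index) sort makes tie-breaking exact
    nn = NearestNeighbors(n_neighbors=n_train, p=cfg.minkowski_p,
                          algorithm="brute")
    nn.fit(train_X)
    dist, idx = nn.kneighbors(test_X)
    preds = np.empty(test_X.shape[0], dtype=int)
    for i in range(test_X.shape[0]):
        # stable re-sort by (distance, training index) then take k
        order = np.lexsort((idx[i], dist[i]))[: cfg.k]
        neigh = idx[i][order]
        votes = train_y[neigh]
        n_high = int((votes == HIGH).sum())
        n_low = cfg.k - n_high
        if n_high > n_low:
            preds[i] = HIGH
        elif n_low > n_high:
            preds[i] = LOW
        else:
            preds[i] = votes[0]  # tie: nearest neighbor decides
    return preds


# ---------------------------------------------------------------------------
# cross-validation


def make_folds(n_trials: int, labels: np.ndarray | None,
               cfg: CVConfig = CVConfig()) -> np.ndarray:
    """Fold id per trial (0..n_folds-1), deterministic given the seed.

    Stratified by default so per-fold class proportions match the global
    proportions to within one sample; if a class has fewer members than
    folds, falls back to unstratified folding with a warning.
    """
    if n_trials < cfg.n_folds:
        raise ConfigError(f"{n_trials} trials cannot fill {cfg.n_folds} folds")
    assign = np.empty(n_trials, dtype=int)
    use_strat = cfg.stratified and labels is not None
    if use_strat:
        labels = np.asarray(labels)
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < cfg.n_folds:
            warnings.warn(
                "a class has fewer members than folds; falling back to "
                "unstratified folding", RuntimeWarning, stacklevel=2,
            )
            use_strat = False
    if use_strat:
        splitter = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                                   random_state=cfg.seed)
        split = splitter.split(np.zeros(n_trials), labels)
    else:
        splitter = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
        split = splitter.split(np.zeros(n_trials))
    for fold_id, (_, test_idx) in enumerate(split):
        assign[test_idx] = fold_id
    return assign


def oof_predict(features: np.ndarray, labels: np.ndarray, folds: np.ndarray,
                knn: KNNConfig = KNNConfig()) -> np.ndarray:
    """Out-of-fold predictions: each trial is predicted by a model trained
    on the other folds only."""
    preds = np.empty(labels.shape[0], dtype=int)
    for fold_id in np.unique(folds):
        test = folds == fold_id
        preds[test] = knn_fit_predict(features[~test], labels[~test],
                                      features[test], knn)
    return preds


def channel_oof_predictions(features: np.ndarray, labels: np.ndarray,
                            knn: KNNConfig = KNNConfig(),
                            cv: CVConfig = CVConfig(),
                            channel: str = "ch", rhythm: str = "band",
                            channel_index: int = 0,
                            folds: np.ndarray | None = None) -> ChannelEvaluation:
    """Cross-validated evaluation of one channel under one rhythm.

    ``features`` is (n_trials, n_features) for that channel.  Precomputed
    fold assignments can be passed so all channels share one split.
    """
    labels = np.asarray(labels, dtype=int)
    if features.shape[0] != labels.shape[0]:
        raise DataError("one feature vector per trial is required")
    if folds is None:
        folds = make_folds(labels.shape[0], labels, cv)
    preds = oof_predict(np.asarray(features, dtype=float), labels, folds, knn)
    acc, sens, spec = compute_metrics(preds, labels)
    return ChannelEvaluation(
        channel=channel, rhythm=rhythm, channel_index=channel_index,
        oof_predictions=preds, accuracy=acc, sensitivity=sens, specificity=spec,
    )


# ---------------------------------------------------------------------------
# ranking and voting


def rank_channels(evals: list[ChannelEvaluation], n_top: int = 5
                  ) -> list[ChannelEvaluation]:
    """Top channels by accuracy (ties: higher sensitivity, then earlier
    channel in recording order)."""
    if n_top > len(evals):
        raise ConfigError(f"cannot select top {n_top} of {len(evals)} channels")
    def key(ev: ChannelEvaluation):
        sens = ev.sensitivity if np.isfinite(ev.sensitivity) else -1.0
        return (-ev.accuracy, -sens, ev.channel_index)
    return sorted(evals, key=key)[:n_top]


def majority_vote(votes: np.ndarray) -> np.ndarray:
    """Per-trial modal label of a (n_voters, n_trials) binary vote matrix.

    On an even split the first (highest-ranked) voter's label wins.
    """
    votes = np.asarray(votes, dtype=int)
    if votes.ndim != 2 or votes.size == 0:
        raise DataError("votes must be a nonempty (n_voters, n_trials) matrix")
    n_voters = votes.shape[0]
    n_high = (votes == HIGH).sum(axis=0)
    n_low = n_voters - n_high
    out = np.where(n_high > n_low, HIGH, LOW)
    tied = n_high == n_low
    out[tied] = votes[0, tied]
    return out


def _rhythm_vote_from_features(features: np.ndarray, labels: np.ndarray,
                               channel_names: list[str], rhythm: str,
                               knn: KNNConfig, cv: CVConfig,
                               folds: np.ndarray, n_top: int = 5) -> RhythmVote:
    """First-step vote from precomputed per-channel features
    (features: n_trials x n_channels x n_features)."""
    evals = [
        channel_oof_predictions(
            features[:, ci, :], labels, knn, cv,
            channel=channel_names[ci], rhythm=rhythm, channel_index=ci,
            folds=folds,
        )
        for ci in range(features.shape[1])
    ]
    top = rank_channels(evals, n_top)
    vote_matrix = np.stack([ev.oof_predictions for ev in top])
    preds = majority_vote(vote_matrix)
    acc, sens, spec = compute_metrics(preds, labels)
    return RhythmVote(
        rhythm=rhythm,
        top_channels=[ev.channel for ev in top],
        top_channel_indices=[ev.channel_index for ev in top],
        channel_evaluations=evals,
        predictions=preds,
        accuracy=acc, sensitivity=sens, specificity=spec,
    )


# ---------------------------------------------------------------------------
# feature extraction for whole datasets


def dataset_features(dataset: TrialDataset,
                     bands: list[BandDefinition] | None = None,
                     feature_cfg: FeatureConfig = FeatureConfig(),
                     lowpass: FilterSpec | None = None,
                     denoise: bool = True,
                     method: str = "spectral",
                     chunk_size: int = 16) -> np.ndarray:
    """Feature tensor (n_trials, n_bands, n_channels, n_features).

    Trials are low-pass denoised, band-limited per rhythm (one shared
    forward FFT when the spectral projection is used), and featurized with
    the vectorized wavelet-packet path.  Work proceeds in blocks of
    ``chunk_size`` trials purely to keep temporaries cache-resident; the
    result is independent of the chunking.
    """
    if bands is None:
        bands = standard_bands()
    out: np.ndarray | None = None
    for start in range(0, dataset.n_trials, max(chunk_size, 1)):
        x = dataset.data[start:start + max(chunk_size, 1)]
        if denoise:
            x = denoise_array(x, dataset.fs, lowpass)
        x_rfft = np.fft.rfft(x, axis=-1) if method == "spectral" else None
        for bi, band in enumerate(bands):
            rhythm = extract_rhythm_array(x, dataset.fs, band, method,
                                          x_rfft=x_rfft)
            block = batch_channel_features(rhythm, feature_cfg)
            if out is None:
                out = np.empty(
                    (dataset.n_trials, len(bands)) + block.shape[1:])
            out[start:start + block.shape[0], bi] = block
    assert out is not None
    return out


def rhythm_vote(dataset: TrialDataset, band: BandDefinition,
                knn: KNNConfig = KNNConfig(), cv: CVConfig = CVConfig(),
                n_top: int = 5,
                feature_cfg: FeatureConfig = FeatureConfig()) -> RhythmVote:
    """Evaluate every channel on one rhythm, rank, and vote the top ``n_top``."""
    if dataset.labels is None:
        raise ConfigError("rhythm_vote requires labeled trials")
    features = dataset_features(dataset, [band], feature_cfg)[:, 0]
    folds = make_folds(dataset.n_trials, dataset.labels, cv)
    return _rhythm_vote_from_features(
        features, dataset.labels, list(dataset.channel_names), band.name,
        knn, cv, folds, n_top,
    )


def _rhythm_vote_nested(features: np.ndarray, labels: np.ndarray,
                        channel_names: list[str], rhythm: str,
                        knn: KNNConfig, cv: CVConfig,
                        folds: np.ndarray, n_top: int = 5) -> RhythmVote:
    """Nested-selection variant: channels are ranked inside each training
    fold (by inner out-of-fold accuracy) before predicting the held-out
    fold, removing selection optimism from the voted accuracy."""
    n_trials, n_channels = features.shape[:2]
    preds = np.empty(n_trials, dtype=int)
    top_counts = np.zeros(n_channels, dtype=int)
    evals = [
        channel_oof_predictions(
            features[:, ci, :], labels, knn, cv,
            channel=channel_names[ci], rhythm=rhythm, channel_index=ci,
            folds=folds,
        )
        for ci in range(n_channels)
    ]  # reported per-channel metrics stay the plain out-of-fold ones
    for fold_id in np.unique(folds):
        test = folds == fold_id
        inner_cv = CVConfig(n_folds=min(cv.n_folds, int((~test).sum())),
                            seed=cv.seed + 1, stratified=cv.stratified)
        inner_folds = make_folds(int((~test).sum()), labels[~test], inner_cv)
        inner_evals = [
            channel_oof_predictions(
                features[~test, ci, :], labels[~test], knn, inner_cv,
                channel=channel_names[ci], rhythm=rhythm, channel_index=ci,
                folds=inner_folds,
            )
            for ci in range(n_channels)
        ]
        top = rank_channels(inner_evals, n_top)
        for ev in top:
            top_counts[ev.channel_index] += 1
        fold_votes = np.stack([
            knn_fit_predict(features[~test, ev.channel_index, :], labels[~test],
                            features[test, ev.channel_index, :], knn)
            for ev in top
        ])
        preds[test] = majority_vote(fold_votes)
    acc, sens, spec = compute_metrics(preds, labels)
    overall_top = list(np.argsort(-top_counts, kind="stable")[:n_top])
    return RhythmVote(
        rhythm=rhythm,
        top_channels=[channel_names[i] for i in overall_top],
        top_channel_indices=[int(i) for i in overall_top],
        channel_evaluations=evals,
        predictions=preds,
        accuracy=acc, sensitivity=sens, specificity=spec,
    )


def two_step_pipeline(dataset: TrialDataset,
                      bands: list[BandDefinition] | None = None,
                      knn: KNNConfig = KNNConfig(),
                      cv: CVConfig = CVConfig(),
                      n_top: int = 5,
                      feature_cfg: FeatureConfig = FeatureConfig(),
                      lowpass: FilterSpec | None = None,
                      precomputed_features: np.ndarray | None = None,
                      nested_selection: bool = False
                      ) -> EnsembleResult:
    """The full two-step majority-voting pipeline.

    Computes a first-step vote per rhythm; if the number of rhythm vote
    vectors is even, the vote of the rhythm with the highest first-step
    voted accuracy is duplicated once (ties: earlier band in standard
    order), and the final prediction is the majority over these vectors.
    """
    if dataset.labels is None:
        raise ConfigError("the pipeline requires labeled trials")
    if bands is None:
        bands = standard_bands()
    if len(bands) < 1:
        raise ConfigError("need at least 1 rhythm band")
    labels = dataset.labels
    if precomputed_features is None:
        features = dataset_features(dataset, bands, feature_cfg, lowpass)
    else:
        features = precomputed_features
    folds = make_folds(dataset.n_trials, labels, cv)
    vote_fn = _rhythm_vote_nested if nested_selection else _rhythm_vote_from_features
    per_rhythm: dict[str, RhythmVote] = {}
    for bi, band in enumerate(bands):
        per_rhythm[band.name] = vote_fn(
            features[:, bi], labels, list(dataset.channel_names), band.name,
            knn, cv, folds, n_top,
        )
    names = [b.name for b in bands]
    vote_rows = [per_rhythm[n].predictions for n in names]
    duplicated = None
    if len(vote_rows) % 2 == 0:
        best = max(range(len(names)),
                   key=lambda i: (per_rhythm[names[i]].accuracy, -i))
        duplicated = names[best]
        # the duplicate leads so an overall tie resolves to the best rhythm
        vote_rows = [vote_rows[best]] + vote_rows
    final = majority_vote(np.stack(vote_rows))
    acc, sens, spec = compute_metrics(final, labels)
    return EnsembleResult(
        per_rhythm=per_rhythm,
        duplicated_rhythm=duplicated,
        final_predictions=final,
        accuracy=acc, sensitivity=sens, specificity=spec,
    )
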
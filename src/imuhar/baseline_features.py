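"""Hand-crafted per-channel features and a linear ECOC-SVM baseline.

Each 120-sample channel of a frame is summarized by 14 features, giving
14 x 24 = 336 features per frame.  The features are: signal mean, variance,
max amplitude, min amplitude, signal magnitude area (mean |x| over the
window), energy (sum of squares), interquartile range, skewness, kurtosis
(Pearson, i.e. the 4th standardized moment), largest frequency component,
weighted average frequency, frequency skewness, frequency kurtosis, and RMS
amplitude.

Spectral features are computed from the one-sided magnitude spectrum of the
unwindowed frame with the DC bin excluded: the largest frequency component
is the frequency (Hz) of the maximum-magnitude bin, and the remaining three
are moments of the magnitude-normalized frequency distribution.  Degenerate
channels (zero spectrum, zero variance) yield 0 for the guarded features.
"""

from __future__ import annotations

import numpy as np
from sklearn.multiclass import OutputCodeClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .signal_io import CHANNEL_NAMES, FS_DEFAULT, N_CHANNELS

FEATURE_NAMES = (
    "mean",
    "variance",
    "max",
    "min",
    "sma",
    "energy",
    "iqr",
    "skewness",
    "kurtosis",
    "largest_freq",
    "weighted_avg_freq",
    "freq_skewness",
    "freq_kurtosis",
    "rms",
)
N_FEATURES_PER_CHANNEL = 14
N_FEATURES = N_FEATURES_PER_CHANNEL * N_CHANNELS  # 336

#: exported column names, {sensor}_{modality}_{axis}_{feature}
FEATURE_COLUMNS = tuple(f"{ch}_{feat}" for ch in CHANNEL_NAMES for feat in FEATURE_NAMES)


def extract_channel_features(channel: np.ndarray, fs: float = FS_DEFAULT) -> np.ndarray:
    """14 features of one windowed channel (see module docstring)."""
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("channel must be a non-empty 1-D vector")
    n = len(x)
    mu = x.mean()
    var = x.var()
    sd = np.sqrt(var)
    if sd > 0:
        z = (x - mu) / sd
        skew = float((z**3).mean())
        kurt = float((z**4).mean())
    else:
        skew = kurt = 0.0
    q75, q25 = np.percentile(x, [75, 25])

    mags = np.abs(np.fft.rfft(x))[1:]  # one-sided, DC excluded
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)[1:]
    total = mags.sum()
    if total > 0:
        largest = float(freqs[int(np.argmax(mags))])
        p = mags / total
        f_mean = float((p * freqs).sum())
        f_sd = float(np.sqrt((p * (freqs - f_mean) ** 2).sum()))
        if f_sd > 0:
            zf = (freqs - f_mean) / f_sd
            f_skew = float((p * zf**3).sum())
            f_kurt = float((p * zf**4).sum())
        else:
            f_skew = f_kurt = 0.0
    else:
        largest = f_mean = f_skew = f_kurt = 0.0

    return np.array(
        [
            mu,
            var,
            x.max(),
            x.min(),
            np.abs(x).mean(),
            (x**2).sum(),
            q75 - q25,
            skew,
            kurt,
            largest,
            f_mean,
            f_skew,
            f_kurt,
            np.sqrt((x**2).mean()),
        ]
    )


def extract_frame_features(frame: np.ndarray, fs: float = FS_DEFAULT) -> np.ndarray:
    """336-dimensional feature vector of a (24, 120) frame: per-channel
    feature blocks concatenated in canonical channel order."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[0] != N_CHANNELS:
        raise ValueError(f"frame must be ({N_CHANNELS}, frame_len)")
    return np.concatenate([extract_channel_features(ch, fs) for ch in frame])


def extract_features(frames: np.ndarray, fs: float = FS_DEFAULT) -> np.ndarray:
    """Feature matrix (n_frames, 336) of a frame tensor."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("expected (n_frames, 24, frame_len)")
    return np.stack([extract_frame_features(f, fs) for f in frames])


def fit_baseline_classifier(
    features: np.ndarray, labels: np.ndarray, random_state: int | None = 0
) -> Pipeline:
    """Fit the linear multiclass baseline: global standardization followed
    by an error-correcting output codes ensemble of linear SVMs.

    Returns a fitted sklearn pipeline exposing ``predict``.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes to fit the baseline classifier")
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "ecoc",
                OutputCodeClassifier(
                    estimator=LinearSVC(max_iter=5000),
                    # enough random code bits to keep class-pair margins;
                    # short codebooks visibly hurt the rare classes
                    code_size=4.0,
                    random_state=random_state,
                ),
            ),
        ]
    )
    model.fit(np.asarray(features, dtype=float), labels)
    return model
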
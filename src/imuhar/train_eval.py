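"""Training protocol, evaluation metrics, statistical comparisons,
robustness simulations and the experiment drivers.

Systems are trained end-to-end from random initialization with Adam
(lr 1e-3, beta1 0.9, beta2 0.999) on minibatches of 100 consecutive frames
from single recordings.  20% of each recording's minibatch blocks are held
out to monitor validation loss, which drives early stopping (patience in
epochs, best-epoch weights restored).  The headline metric is the
unweighted average F1 score (UWAF): per-class F1 = tp / (tp + 0.5(fp+fn)),
averaged over classes without frequency weighting, which keeps rare
movement categories visible under the heavily skewed class distribution.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .augmentation import AugmentationConfig, augment_minibatch
from .encoders import EncoderSpec, build_encoder, count_parameters, estimate_flops
from .nn import Adam, Dropout, Module, Tensor, softmax, softmax_cross_entropy
from .signal_io import N_CLASSES, CLASS_NAMES
from .synthetic_data import Recording
from .temporal_models import TemporalSpec, build_temporal


@dataclass
class TrainConfig:
    """Optimization and cross-validation settings."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    batch_frames: int = 100
    max_epochs: int = 250
    patience: int = 30
    val_fraction: float = 0.2
    n_repeats: int = 3
    k_folds: int = 7
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        for name in ("batch_frames", "max_epochs", "patience", "n_repeats", "k_folds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class EvalReport:
    """Evaluation results of one system on one dataset."""

    uwaf: float
    per_class_f1: dict[str, float]
    confusion: np.ndarray
    recording_scores: dict[str, float]
    ci: tuple[float, float] | None = None
    details: dict = field(default_factory=dict)


# ----------------------------------------------------------------------
# metric
def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int = N_CLASSES):
    """Counts matrix, rows = true class, columns = predicted class."""
    conf = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(conf, (np.asarray(y_true, dtype=int), np.asarray(y_pred, dtype=int)), 1)
    return conf


def per_class_f1(conf: np.ndarray) -> np.ndarray:
    """F1_c = tp / (tp + 0.5 (fp + fn)) per class; NaN where the class is
    absent from both truth and predictions."""
    conf = np.asarray(conf, dtype=float)
    tp = np.diag(conf)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    denom = tp + 0.5 * (fp + fn)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, tp / denom, np.nan)


def uwaf(conf: np.ndarray) -> float:
    """Unweighted average F1 over classes.  Classes with tp+fp+fn = 0
    (absent from both truth and predictions) are excluded from the average
    rather than counted as zero."""
    conf = np.asarray(conf)
    if conf.size == 0 or conf.sum() == 0:
        raise ValueError("empty confusion matrix")
    f1 = per_class_f1(conf)
    if np.all(np.isnan(f1)):
        raise ValueError("no class has any support")
    return float(np.nanmean(f1))


# ----------------------------------------------------------------------
# model container
class MovementNet(Module):
    """Encoder -> (bottleneck dropout) -> temporal model."""

    def __init__(
        self,
        encoder_spec: EncoderSpec,
        temporal_spec: TemporalSpec,
        seed: int = 0,
        bottleneck_dropout_p: float = 0.0,
    ):
        super().__init__()
        ss = np.random.SeedSequence(seed)
        enc_ss, tmp_ss, drop_ss = ss.spawn(3)
        self.encoder_spec = encoder_spec
        self.temporal_spec = temporal_spec
        self.encoder = build_encoder(encoder_spec, np.random.default_rng(enc_ss))
        self.temporal = build_temporal(temporal_spec, np.random.default_rng(tmp_ss))
        self.bottleneck_dropout = Dropout(
            bottleneck_dropout_p, np.random.default_rng(drop_ss)
        )

    def forward(self, x: Tensor) -> Tensor:
        feats = self.encoder(x)
        feats = self.bottleneck_dropout(feats)
        return self.temporal(feats)

    def predict_proba(self, frames: np.ndarray, block_len: int = 100) -> np.ndarray:
        """(n_frames, 24, 120) -> (n_frames, n_classes), processed in blocks
        of consecutive frames with zero initial state."""
        frames = np.asarray(frames, dtype=float)
        self.eval()
        out = []
        for i in range(0, len(frames), block_len):
            logits = self(Tensor(frames[i : i + block_len]))
            out.append(softmax(logits.data, axis=-1))
        self.train()
        if not out:
            return np.empty((0, self.temporal_spec.n_classes))
        return np.concatenate(out, axis=0)

    def predict(self, frames: np.ndarray, block_len: int = 100) -> np.ndarray:
        return self.predict_proba(frames, block_len).argmax(axis=1)


def _as_soft(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim == 2:
        return labels.astype(float)
    return np.eye(n_classes)[labels.astype(int)]


def _blocks(n_frames: int, batch_frames: int) -> list[tuple[int, int]]:
    """Consecutive-frame minibatch blocks of one recording; a trailing
    partial block is kept when it holds at least 2 frames."""
    spans = []
    for start in range(0, n_frames, batch_frames):
        stop = min(start + batch_frames, n_frames)
        if stop - start >= 2 or start == 0:
            spans.append((start, stop))
    return spans


def _split_blocks(dataset, cfg: TrainConfig, rng: np.random.Generator):
    """Per recording: seeded random val_fraction of blocks for validation,
    the rest for training.

    Short recordings can round their per-recording share down to zero; the
    selection is then topped up across recordings (preferring those with
    the most blocks) until the global validation fraction is honored, so
    validation-loss monitoring stays meaningful on small datasets.
    """
    per_rec = []
    for ri, rec in enumerate(dataset):
        spans = _blocks(len(rec.frames), cfg.batch_frames)
        n_val = int(round(cfg.val_fraction * len(spans)))
        order = rng.permutation(len(spans))
        val_ids = set(order[:n_val].tolist())
        per_rec.append([ri, spans, order, val_ids])
    total_blocks = sum(len(spans) for _, spans, _, _ in per_rec)
    target = max(1, int(round(cfg.val_fraction * total_blocks)))
    while sum(len(v) for *_, v in per_rec) < target:
        candidates = [t for t in per_rec if len(t[3]) < len(t[1]) - 1]
        if not candidates:
            break
        richest = max(candidates, key=lambda t: len(t[1]) - len(t[3]))
        for bi in richest[2]:
            if bi not in richest[3]:
                richest[3].add(int(bi))
                break
    train, val = [], []
    for ri, spans, _, val_ids in per_rec:
        for bi, span in enumerate(spans):
            (val if bi in val_ids else train).append((ri, span))
    return train, val


def _loss_over(model: MovementNet, dataset, block_list) -> float:
    model.eval()
    total, n = 0.0, 0
    for ri, (a, b) in block_list:
        rec = dataset[ri]
        logits = model(Tensor(rec.frames[a:b]))
        t = _as_soft(rec.labels[a:b], model.temporal_spec.n_classes)
        total += float(softmax_cross_entropy(logits, t).data) * (b - a)
        n += b - a
    model.train()
    return total / max(n, 1)


def train_system(
    encoder_spec: EncoderSpec,
    temporal_spec: TemporalSpec,
    dataset: list[Recording],
    aug: AugmentationConfig | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[MovementNet, dict]:
    """End-to-end training with Adam, early stopping on validation loss and
    best-epoch weight restoration.  Fully reproducible from cfg.seed."""
    aug = aug or AugmentationConfig.none()
    cfg = cfg or TrainConfig()
    dataset = [r for r in dataset if len(r.frames)]
    if not dataset:
        raise ValueError("empty dataset")
    ss = np.random.SeedSequence(cfg.seed)
    model_ss, split_ss, loop_ss = ss.spawn(3)
    model = MovementNet(
        encoder_spec,
        temporal_spec,
        seed=model_ss.generate_state(1)[0] % (2**31),
        bottleneck_dropout_p=aug.bottleneck_dropout_p if aug.dr2 else 0.0,
    )
    train_blocks, val_blocks = _split_blocks(dataset, cfg, np.random.default_rng(split_ss))
    if not train_blocks:
        raise ValueError("no training minibatches left after validation split")
    rng = np.random.default_rng(loop_ss)
    opt = Adam(model.parameters(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)

    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = model.state()
    best_epoch = -1
    since_best = 0
    model.train()
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_blocks))
        epoch_loss, n_frames_seen = 0.0, 0
        for bi in order:
            ri, (a, b) = train_blocks[bi]
            rec = dataset[ri]
            x = augment_minibatch(rec.frames[a:b], aug, rng)
            logits = model(Tensor(x))
            t = _as_soft(rec.labels[a:b], temporal_spec.n_classes)
            loss = softmax_cross_entropy(logits, t)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, block {bi}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * (b - a)
            n_frames_seen += b - a
        history["train_loss"].append(epoch_loss / n_frames_seen)
        val_loss = _loss_over(model, dataset, val_blocks) if val_blocks else history[
            "train_loss"
        ][-1]
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    model.load_state(best_state)
    model.eval()
    history["best_epoch"] = best_epoch
    history["epochs_run"] = len(history["train_loss"])
    return model, history


# ----------------------------------------------------------------------
# evaluation
def evaluate_system(
    model: MovementNet, dataset: list[Recording], block_len: int = 100
) -> EvalReport:
    """Pooled confusion matrix + UWAF over recordings, with per-recording
    UWAF scores (evaluation is deterministic)."""
    conf = np.zeros((model.temporal_spec.n_classes,) * 2, dtype=int)
    rec_scores = {}
    for rec in dataset:
        pred = model.predict(rec.frames, block_len)
        c = confusion_matrix(rec.labels, pred, model.temporal_spec.n_classes)
        conf += c
        rec_scores[rec.recording_id] = uwaf(c)
    f1 = per_class_f1(conf)
    return EvalReport(
        uwaf=uwaf(conf),
        per_class_f1={CLASS_NAMES[i]: float(f1[i]) for i in range(len(f1))},
        confusion=conf,
        recording_scores=rec_scores,
    )


def bootstrap_ci(
    per_recording_scores,
    n_iter: int = 10000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile confidence interval of the mean score under resampling
    recordings with replacement."""
    scores = np.asarray(list(per_recording_scores), dtype=float)
    if len(scores) == 0:
        raise ValueError("no recording scores")
    if len(scores) == 1:
        warnings.warn("single recording: degenerate zero-width interval")
        return float(scores[0]), float(scores[0])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, len(scores), size=(n_iter, len(scores)))
    means = scores[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def compare_modules(scores_a, scores_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two score samples
    (exact enumeration for small tie-free samples, mid-rank normal
    approximation otherwise)."""
    a = np.asarray(list(scores_a), dtype=float)
    b = np.asarray(list(scores_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both score samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) < 25 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


# ----------------------------------------------------------------------
# robustness simulations
def simulate_packet_loss(
    data: np.ndarray,
    rate: float,
    burst: int = 4,
    rng: int | np.random.Generator = 0,
) -> np.ndarray:
    """Zero packet-aligned ``burst``-sample runs per sensor until the
    dropped fraction matches ``rate``; independent across sensors.

    ``data`` is either a (24, n_samples) recording matrix or an
    (n_frames, 24, frame_len) frame tensor (each frame's time axis is
    packet-aligned).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    data = np.asarray(data, dtype=float).copy()
    if rate == 0.0:
        return data
    if data.ndim == 2:
        n = data.shape[1]
        n_packets = -(-n // burst)
        k = int(round(rate * n_packets))
        for s in range(4):
            drop = rng.choice(n_packets, size=k, replace=False)
            for p in drop:
                data[6 * s : 6 * s + 6, p * burst : (p + 1) * burst] = 0.0
        return data
    if data.ndim == 3:
        n_frames, _, t = data.shape
        if t % burst != 0:
            raise ValueError("frame length must be a multiple of the burst size")
        per_frame = t // burst
        total = n_frames * per_frame
        k = int(round(rate * total))
        view = data.reshape(n_frames, data.shape[1], per_frame, burst)
        for s in range(4):
            drop = rng.choice(total, size=k, replace=False)
            fi, pi = np.unravel_index(drop, (n_frames, per_frame))
            view[fi, 6 * s : 6 * s + 6, pi, :] = 0.0
        return data
    raise ValueError("expected a (24, n) recording or (n_frames, 24, T) frames")


def drop_sensors(frames: np.ndarray, sensors) -> np.ndarray:
    """Zero the 6 channels of each listed sensor index."""
    out = np.asarray(frames, dtype=float).copy()
    for s in sensors:
        out[..., 6 * int(s) : 6 * int(s) + 6, :] = 0.0
    return out


def sensor_dropout_eval(
    model: MovementNet, dataset: list[Recording], n_dropped: int
) -> tuple[float, dict]:
    """Mean UWAF over every combination of ``n_dropped`` zeroed sensors
    (C(4, n) evaluations; n_dropped = 0 reduces to the clean evaluation)."""
    if n_dropped >= 4:
        raise ValueError("cannot drop all four sensors")
    combos = list(itertools.combinations(range(4), n_dropped))
    per_combo = {}
    for combo in combos:
        conf = np.zeros((model.temporal_spec.n_classes,) * 2, dtype=int)
        for rec in dataset:
            pred = model.predict(drop_sensors(rec.frames, combo))
            conf += confusion_matrix(rec.labels, pred, model.temporal_spec.n_classes)
        per_combo[combo] = uwaf(conf)
    return float(np.mean(list(per_combo.values()))), per_combo


def packet_loss_eval(
    model: MovementNet,
    dataset: list[Recording],
    rate: float,
    n_repetitions: int = 5,
    seed: int = 0,
) -> float:
    """Mean UWAF over seeded repetitions of the packet-loss simulation."""
    scores = []
    for rep in range(n_repetitions):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
        conf = np.zeros((model.temporal_spec.n_classes,) * 2, dtype=int)
        for rec in dataset:
            corrupted = simulate_packet_loss(rec.frames, rate, rng=rng)
            pred = model.predict(corrupted)
            conf += confusion_matrix(rec.labels, pred, model.temporal_spec.n_classes)
        scores.append(uwaf(conf))
    return float(np.mean(scores))


# ----------------------------------------------------------------------
# cross-validation
def make_folds(n_recordings: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded random partition of recording indices into k near-equal
    subject-disjoint folds (one subject per recording)."""
    if n_recordings < k:
        raise ValueError(f"need at least {k} recordings for {k}-fold cross-validation")
    order = rng.permutation(n_recordings)
    return [np.sort(fold) for fold in np.array_split(order, k)]


def crossvalidate(
    dataset: list[Recording],
    encoder_spec: EncoderSpec,
    temporal_spec: TemporalSpec,
    aug: AugmentationConfig | None = None,
    cfg: TrainConfig | None = None,
) -> EvalReport:
    """k-fold subject-disjoint cross-validation, repeated n_repeats times
    with fresh initializations; repeats are averaged.

    Every recording is scored exactly once per repeat by a model that never
    saw it during training.
    """
    cfg = cfg or TrainConfig()
    ss = np.random.SeedSequence(cfg.seed)
    folds = make_folds(len(dataset), cfg.k_folds, np.random.default_rng(ss.spawn(1)[0]))
    repeat_uwafs = []
    rec_scores_acc: dict[str, list[float]] = {r.recording_id: [] for r in dataset}
    confusion_total = np.zeros((temporal_spec.n_classes,) * 2, dtype=int)
    for rep in range(cfg.n_repeats):
        conf = np.zeros((temporal_spec.n_classes,) * 2, dtype=int)
        for fi, fold in enumerate(folds):
            test_ids = set(fold.tolist())
            train_set = [r for i, r in enumerate(dataset) if i not in test_ids]
            fold_cfg = TrainConfig(**{**asdict(cfg), "seed": cfg.seed + 1000 * rep + fi})
            model, _ = train_system(encoder_spec, temporal_spec, train_set, aug, fold_cfg)
            for i in fold:
                rec = dataset[i]
                pred = model.predict(rec.frames)
                c = confusion_matrix(rec.labels, pred, temporal_spec.n_classes)
                conf += c
                rec_scores_acc[rec.recording_id].append(uwaf(c))
        repeat_uwafs.append(uwaf(conf))
        confusion_total += conf
    rec_scores = {k: float(np.mean(v)) for k, v in rec_scores_acc.items()}
    ci = bootstrap_ci(list(rec_scores.values()), seed=cfg.seed) if len(dataset) > 1 else None
    f1 = per_class_f1(confusion_total)
    return EvalReport(
        uwaf=float(np.mean(repeat_uwafs)),
        per_class_f1={CLASS_NAMES[i]: float(f1[i]) for i in range(len(f1))},
        confusion=confusion_total,
        recording_scores=rec_scores,
        ci=ci,
        details={"repeat_uwafs": repeat_uwafs},
    )


# ----------------------------------------------------------------------
# experiment drivers
ENCODER_GRID = ("dense", "conv1d", "conv2d_i", "conv2d_is", "conv2d_si")
TEMPORAL_GRID = ("dense", "lstm", "gru", "bgru", "wavenet")


def _config_hash(payload: dict) -> str:
    return hashlib.sha1(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[
        :12
    ]


def run_experiment_grid(
    experiment: str,
    dataset: list[Recording] | None = None,
    cfg: TrainConfig | None = None,
    aug_settings: dict[str, AugmentationConfig] | None = None,
    train: bool = True,
    bottleneck_sweep: tuple[int, ...] = (40, 20, 10),
    packet_rates: tuple[float, ...] = (0.25, 0.5),
    packet_repetitions: int = 5,
    holdout_fraction: float = 0.25,
) -> pd.DataFrame:
    """The three experiment drivers.

    ``architectures``
        All 25 encoder x temporal combinations; with ``train=True`` each is
        cross-validated per ``cfg`` (UWAF + bootstrap CI), otherwise
        freshly initialized systems are evaluated as-is (a smoke grid).
    ``size_complexity``
        Parameter counts and per-frame encoder MFLOPs for all 25 systems,
        plus the sensor-independent encoder's bottleneck sweep (features
        per sensor in ``bottleneck_sweep``) with raw-input compression
        ratios.
    ``robustness``
        Chosen systems x augmentation settings, each trained on a seeded
        holdout split and evaluated clean, with 1 or 2 sensors dropped
        (all combinations averaged), and under packet loss at
        ``packet_rates`` (repetitions averaged).

    Every row carries the seed and a config hash for exact re-running.
    """
    cfg = cfg or TrainConfig()
    rows: list[dict] = []

    if experiment == "architectures":
        if dataset is None:
            raise ValueError("architectures experiment requires a dataset")
        for enc_kind in ENCODER_GRID:
            for tmp_kind in TEMPORAL_GRID:
                e_spec = EncoderSpec(kind=enc_kind)
                t_spec = TemporalSpec(kind=tmp_kind)
                chash = _config_hash(
                    {"enc": enc_kind, "tmp": tmp_kind, "cfg": asdict(cfg), "train": train}
                )
                if train:
                    report = crossvalidate(dataset, e_spec, t_spec, None, cfg)
                    lo, hi = report.ci if report.ci else (np.nan, np.nan)
                    rows.append(
                        dict(
                            encoder=enc_kind,
                            temporal=tmp_kind,
                            uwaf=report.uwaf,
                            ci_lo=lo,
                            ci_hi=hi,
                            n_repeats=cfg.n_repeats,
                            seed=cfg.seed,
                            config_hash=chash,
                        )
                    )
                else:
                    model = MovementNet(e_spec, t_spec, seed=cfg.seed)
                    report = evaluate_system(model, dataset)
                    rows.append(
                        dict(
                            encoder=enc_kind,
                            temporal=tmp_kind,
                            uwaf=report.uwaf,
                            ci_lo=np.nan,
                            ci_hi=np.nan,
                            n_repeats=0,
                            seed=cfg.seed,
                            config_hash=chash,
                        )
                    )
        return pd.DataFrame(rows)

    if experiment == "size_complexity":
        for enc_kind in ENCODER_GRID:
            for tmp_kind in TEMPORAL_GRID:
                model = MovementNet(EncoderSpec(kind=enc_kind), TemporalSpec(kind=tmp_kind), cfg.seed)
                rows.append(
                    dict(
                        encoder=enc_kind,
                        temporal=tmp_kind,
                        per_sensor_dim=np.nan,
                        n_parameters=model.n_parameters(),
                        encoder_mflops=estimate_flops(model.encoder),
                        compression_ratio=np.nan,
                        seed=cfg.seed,
                        config_hash=_config_hash({"enc": enc_kind, "tmp": tmp_kind}),
                    )
                )
        for psd in bottleneck_sweep:
            e_spec = EncoderSpec(kind="conv2d_si", per_sensor_dim=psd)
            t_spec = TemporalSpec(kind="wavenet", input_dim=e_spec.bottleneck_dim)
            model = MovementNet(e_spec, t_spec, cfg.seed)
            rows.append(
                dict(
                    encoder="conv2d_si",
                    temporal="wavenet",
                    per_sensor_dim=psd,
                    n_parameters=model.n_parameters(),
                    encoder_mflops=estimate_flops(model.encoder),
                    compression_ratio=(24 * 120) / (4 * psd),
                    seed=cfg.seed,
                    config_hash=_config_hash({"enc": "conv2d_si", "psd": psd}),
                )
            )
        return pd.DataFrame(rows)

    if experiment == "robustness":
        if dataset is None:
            raise ValueError("robustness experiment requires a dataset")
        systems = [
            ("conv2d_si", "wavenet"),
            ("conv1d", "dense"),
            ("conv1d", "gru"),
        ]
        if aug_settings is None:
            aug_settings = {
                "none": AugmentationConfig.none(),
                "dr1": AugmentationConfig.from_keys(["dr1"]),
                "dr2": AugmentationConfig.from_keys(["dr2"]),
                "rot": AugmentationConfig.from_keys(["rot"]),
                "tw": AugmentationConfig.from_keys(["tw"]),
                "drs": AugmentationConfig.from_keys(["drs"]),
                "dr1+drs": AugmentationConfig.from_keys(["dr1", "drs"]),
            }
        rng = np.random.default_rng(cfg.seed)
        n_test = max(1, int(round(holdout_fraction * len(dataset))))
        order = rng.permutation(len(dataset))
        test_ids = set(order[:n_test].tolist())
        train_set = [r for i, r in enumerate(dataset) if i not in test_ids]
        test_set = [r for i, r in enumerate(dataset) if i in test_ids]
        for enc_kind, tmp_kind in systems:
            for aug_name, aug in aug_settings.items():
                model, _ = train_system(
                    EncoderSpec(kind=enc_kind), TemporalSpec(kind=tmp_kind), train_set, aug, cfg
                )
                chash = _config_hash(
                    {"enc": enc_kind, "tmp": tmp_kind, "aug": aug_name, "cfg": asdict(cfg)}
                )
                base = dict(
                    encoder=enc_kind,
                    temporal=tmp_kind,
                    augmentation=aug_name,
                    seed=cfg.seed,
                    config_hash=chash,
                )
                rows.append(
                    dict(base, condition="clean", uwaf=evaluate_system(model, test_set).uwaf)
                )
                for n_drop in (1, 2):
                    score, _ = sensor_dropout_eval(model, test_set, n_drop)
                    rows.append(dict(base, condition=f"sensor_drop{n_drop}", uwaf=score))
                for rate in packet_rates:
                    score = packet_loss_eval(
                        model, test_set, rate, packet_repetitions, seed=cfg.seed
                    )
                    rows.append(
                        dict(base, condition=f"packet_loss{int(rate * 100)}", uwaf=score)
                    )
        return pd.DataFrame(rows)

    raise ValueError(
        f"unknown experiment {experiment!r}; choose architectures, size_complexity or robustness"
    )
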
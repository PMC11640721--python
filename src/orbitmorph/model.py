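"""2D attention U-Net with slice positional encoding.

A plain 2D segmentation network sees each axial slice in isolation and
cannot tell, e.g., a small superior eyeball cross-section from a nerve
cross-section of similar size and intensity.  To retain volumetric
context at 2D cost, the slice's position in the stack is injected as
extra input channels: a sinusoidal positional encoding of the slice
index, each component broadcast to a constant spatial plane and
concatenated with the image channel.  Concatenation (rather than
addition) is used because image intensities and encodings live on
different scales.

The network is an encoder-decoder with skip connections gated by
additive attention: at each decoder level the upsampled decoder feature
acts as the gating signal, and a learned coefficient map in [0, 1]
multiplies the skip features before concatenation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_prep import LabeledVolume, SliceSample, extract_axial_slices
from .nn import autodiff as ad
from .nn.autodiff import Adam, Tensor

DEFAULT_FREQ_BASE = 100.0


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``pe_dim`` sinusoidal channels are appended to the input when
    ``pe_mode`` is "on"; "off" reduces the model to a plain single-channel
    attention U-Net (the measurement code path is unaffected either way).
    """

    depth: int = 3
    base_channels: int = 8
    pe_dim: int = 8
    pe_mode: str = "on"
    n_classes: int = 3
    input_size: int = 64
    freq_base: float = DEFAULT_FREQ_BASE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.pe_mode not in ("on", "off"):
            raise ValueError("pe_mode must be 'on' or 'off'")
        if self.pe_mode == "on" and (self.pe_dim % 2 or self.pe_dim < 2):
            raise ValueError("pe_dim must be even and >= 2 when pe_mode is on")
        if self.n_classes != 3:
            raise ValueError("the pipeline is defined for 3 classes")

    @property
    def in_channels(self) -> int:
        return 1 + (self.pe_dim if self.pe_mode == "on" else 0)


@dataclass(frozen=True)
class TrainConfig:
    folds: int = 5
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 2e-3
    ce_weight: float = 1.0
    dice_weight: float = 1.0
    intensity_scale: float = 100.0  # image channel is divided by this
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def positional_encoding(slice_index: int, n_slices: int, pe_dim: int,
                        freq_base: float = DEFAULT_FREQ_BASE) -> np.ndarray:
    """Sinusoidal encoding of a slice position, values in [-1, 1].

    Component pairs are ``(sin(k * w_j), cos(k * w_j))`` for the slice
    index ``k`` with ``pe_dim / 2`` geometrically spaced frequencies
    ``w_j = freq_base ** (-2j / pe_dim)``.
    """
    if not 0 <= slice_index < n_slices:
        raise ValueError(f"slice_index {slice_index} outside [0, {n_slices})")
    if pe_dim % 2 or pe_dim < 2:
        raise ValueError("pe_dim must be even and >= 2")
    j = np.arange(pe_dim // 2)
    w = freq_base ** (-2.0 * j / pe_dim)
    out = np.empty(pe_dim, dtype=np.float32)
    out[0::2] = np.sin(slice_index * w)
    out[1::2] = np.cos(slice_index * w)
    return out


def attach_encoding(sample: SliceSample, config: ModelConfig) -> np.ndarray:
    """Build the model input stack ``(channels, H, W)`` for one slice.

    Channel 0 is the image (unmodified here; the training harness applies
    intensity scaling); with ``pe_mode`` on, channels 1..pe_dim are the
    positional-encoding components, each a spatially constant plane.
    """
    img = np.asarray(sample.image, dtype=np.float32)
    if config.pe_mode == "off":
        return img[None]
    pe = positional_encoding(sample.slice_index, sample.n_slices,
                             config.pe_dim, config.freq_base)
    planes = np.broadcast_to(pe[:, None, None], (config.pe_dim, *img.shape))
    return np.concatenate([img[None], planes], axis=0).astype(np.float32)


# ---------------------------------------------------------------------------
# network


class _ConvBlock:
    def __init__(self, rng, c_in: int, c_out: int):
        k = 3
        self.w1 = ad.he_init(rng, (c_out, c_in, k, k), fan_in=c_in * k * k)
        self.b1 = Tensor(np.zeros(c_out, np.float32), requires_grad=True)
        self.w2 = ad.he_init(rng, (c_out, c_out, k, k), fan_in=c_out * k * k)
        self.b2 = Tensor(np.zeros(c_out, np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        x = ad.relu(ad.conv2d(x, self.w1, self.b1, pad=1))
        return ad.relu(ad.conv2d(x, self.w2, self.b2, pad=1))

    @property
    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]


class _AttentionGate:
    """Additive attention gate on a skip connection.

    ``alpha = sigmoid(psi(relu(Wg g + Wx s)))`` with 1x1 convolutions;
    the gate output is ``s * alpha`` with ``alpha`` broadcast over skip
    channels.
    """

    def __init__(self, rng, c_skip: int, c_gate: int, c_inter: int):
        self.wg = ad.he_init(rng, (c_inter, c_gate, 1, 1), fan_in=c_gate)
        self.wx = ad.he_init(rng, (c_inter, c_skip, 1, 1), fan_in=c_skip)
        self.bg = Tensor(np.zeros(c_inter, np.float32), requires_grad=True)
        self.psi = ad.he_init(rng, (1, c_inter, 1, 1), fan_in=c_inter)
        self.bpsi = Tensor(np.zeros(1, np.float32), requires_grad=True)
        self.last_alpha: Optional[np.ndarray] = None

    def __call__(self, skip: Tensor, gate: Tensor) -> Tensor:
        q = ad.relu(ad.add(ad.conv2d(gate, self.wg, self.bg, pad=0),
                           ad.conv2d(skip, self.wx, None, pad=0)))
        alpha = ad.sigmoid(ad.conv2d(q, self.psi, self.bpsi, pad=0))
        self.last_alpha = alpha.data
        return ad.mul(skip, alpha)

    @property
    def params(self):
        return [self.wg, self.wx, self.bg, self.psi, self.bpsi]


class AttentionUNet:
    """Attention U-Net over (N, C, H, W) inputs, 3-class output scores."""

    def __init__(self, config: ModelConfig):
        size = config.input_size
        if size % (2 ** (config.depth - 1)):
            raise ValueError(
                f"input size {size} not divisible by 2^{config.depth - 1}")
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        chans = [c * 2 ** i for i in range(config.depth)]
        self.enc = [_ConvBlock(rng, config.in_channels if i == 0 else chans[i - 1],
                               chans[i]) for i in range(config.depth)]
        self.up_reduce: list = []
        self.gates: list[_AttentionGate] = []
        self.dec: list[_ConvBlock] = []
        for i in range(config.depth - 2, -1, -1):
            c_coarse = chans[i + 1]
            c_skip = chans[i]
            self.up_reduce.append(
                (ad.he_init(rng, (c_skip, c_coarse, 1, 1), fan_in=c_coarse),
                 Tensor(np.zeros(c_skip, np.float32), requires_grad=True)))
            self.gates.append(_AttentionGate(rng, c_skip, c_skip, max(c_skip // 2, 1)))
            self.dec.append(_ConvBlock(rng, 2 * c_skip, c_skip))
        self.w_out = ad.he_init(rng, (config.n_classes, chans[0], 1, 1), fan_in=chans[0])
        self.b_out = Tensor(np.zeros(config.n_classes, np.float32), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for blk in self.enc + self.dec:
            ps += blk.params
        for w, b in self.up_reduce:
            ps += [w, b]
        for g in self.gates:
            ps += g.params
        ps += [self.w_out, self.b_out]
        return ps

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        h = x
        for i, blk in enumerate(self.enc):
            h = blk(h)
            if i < len(self.enc) - 1:
                skips.append(h)
                h = ad.maxpool2(h)
        for j, (blk, gate, (wu, bu)) in enumerate(
                zip(self.dec, self.gates, self.up_reduce)):
            u = ad.conv2d(ad.upsample2(h), wu, bu, pad=0)
            s = skips[len(skips) - 1 - j]
            h = blk(ad.concat([u, gate(s, u)], axis=1))
        return ad.conv2d(h, self.w_out, self.b_out, pad=0)

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for a (N, C, H, W) batch."""
        logits = self.forward(Tensor(batch))
        return ad.softmax(logits, axis=1).data

    def attention_maps(self) -> list[np.ndarray]:
        """Attention coefficient maps from the most recent forward pass."""
        return [g.last_alpha for g in self.gates if g.last_alpha is not None]


def build_model(config: ModelConfig) -> AttentionUNet:
    """Construct a seeded attention U-Net from its config."""
    return AttentionUNet(config)


# ---------------------------------------------------------------------------
# training harness


@dataclass
class FoldReport:
    """Per-fold, per-class held-out metrics plus loss curves."""

    fold_metrics: list[dict]          # fold -> {class_name: ClassMetrics}
    loss_curves: list[list[float]]    # fold -> per-epoch mean loss
    fold_subjects: list[list[str]]    # fold -> held-out subject ids

    def mean_sd(self, class_name: str, metric: str) -> tuple[float, float]:
        vals = [getattr(fm[class_name], metric) for fm in self.fold_metrics]
        vals = [v for v in vals if v == v]  # drop NaN
        return float(np.mean(vals)), float(np.std(vals))

    def summary_table(self) -> "pandas.DataFrame":  # noqa: F821
        import pandas as pd

        rows = []
        for cname in self.fold_metrics[0]:
            for metric in ("dice", "iou", "sensitivity", "specificity"):
                m, s = self.mean_sd(cname, metric)
                rows.append({"class": cname, "metric": metric,
                             "mean": m, "sd": s})
        return pd.DataFrame(rows)


def _prepare_batch(samples: Sequence[SliceSample], config: ModelConfig,
                   scale: float) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for s in samples:
        stack = attach_encoding(s, config).copy()
        stack[0] /= scale
        xs.append(stack)
        ys.append(np.asarray(s.mask, dtype=np.int64))
    return np.stack(xs), np.stack(ys)


def assign_folds(subject_ids: Sequence[str], n_folds: int,
                 seed: int) -> dict[str, int]:
    """Deterministic subject-level fold assignment.

    Grouping by subject keeps both orbits (and every slice) of a subject
    in the same fold, preventing left/right leakage across folds.
    """
    uniq = sorted(set(subject_ids))
    if len(uniq) < n_folds:
        raise ValueError(f"{len(uniq)} subjects < {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(uniq))
    return {sid: i % n_folds for i, sid in enumerate(order)}


def fit(model: AttentionUNet, slices: Sequence[SliceSample],
        cfg: TrainConfig, verbose: bool = False) -> list[float]:
    """Train in place on a set of slices; returns per-epoch mean loss."""
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params, lr=cfg.learning_rate)
    losses: list[float] = []
    idx = np.arange(len(slices))
    for epoch in range(cfg.epochs):
        rng.shuffle(idx)
        total, nb = 0.0, 0
        for start in range(0, len(idx), cfg.batch_size):
            batch = [slices[i] for i in idx[start:start + cfg.batch_size]]
            x, y = _prepare_batch(batch, model.config, cfg.intensity_scale)
            logits = model.forward(Tensor(x))
            loss = ad.add(
                ad.mul(ad.softmax_cross_entropy(logits, y), cfg.ce_weight),
                ad.mul(ad.soft_dice_loss(logits, y), cfg.dice_weight))
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data)
            nb += 1
        losses.append(total / nb)
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs} loss {losses[-1]:.4f}")
    return losses


def predict_volume(model: AttentionUNet, volume: LabeledVolume,
                   intensity_scale: float = 100.0) -> np.ndarray:
    """Segment a whole volume slice-by-slice: argmax class map per slice."""
    h, w = volume.shape[1:]
    if h != model.config.input_size or w != model.config.input_size:
        raise ValueError(
            f"slice size {(h, w)} does not match model input "
            f"{model.config.input_size}")
    samples = extract_axial_slices(volume)
    x, _ = _prepare_batch_images(samples, model.config, intensity_scale)
    proba = model.predict_proba(x)
    return proba.argmax(axis=1).astype(np.uint8)


def _prepare_batch_images(samples, config, scale):
    xs = []
    for s in samples:
        stack = attach_encoding(s, config).copy()
        stack[0] /= scale
        xs.append(stack)
    return np.stack(xs), None


def train(cohort: Sequence, model_cfg: ModelConfig, train_cfg: TrainConfig,
          folds_to_run: Optional[Iterable[int]] = None,
          verbose: bool = False) -> tuple[list[AttentionUNet], FoldReport]:
    """Grouped k-fold cross-validation over a phantom cohort.

    ``cohort`` is a sequence of objects with ``volume`` (LabeledVolume)
    and ``subject_id`` attributes (e.g. phantom CohortMembers), or raw
    LabeledVolumes.  Each fold trains a fresh seeded model on the other
    folds' slices and evaluates per-volume class metrics on its held-out
    volumes.  ``folds_to_run`` restricts execution to a subset of folds
    (e.g. a single holdout) while keeping the full assignment.
    """
    from .evaluate import class_metrics
    from .io_prep import CLASS_NAMES

    volumes = [m.volume if hasattr(m, "volume") else m for m in cohort]
    sids = [v.subject_id for v in volumes]
    fold_of = assign_folds(sids, train_cfg.folds, train_cfg.seed)
    run = set(range(train_cfg.folds)) if folds_to_run is None else set(folds_to_run)

    models: list[AttentionUNet] = []
    fold_metrics, loss_curves, fold_subjects = [], [], []
    for f in sorted(run):
        train_vols = [v for v in volumes if fold_of[v.subject_id] != f]
        test_vols = [v for v in volumes if fold_of[v.subject_id] == f]
        train_slices = [s for v in train_vols for s in extract_axial_slices(v)]
        model = build_model(replace(model_cfg, seed=model_cfg.seed + f))
        curve = fit(model, train_slices,
                    replace(train_cfg, seed=train_cfg.seed + f), verbose=verbose)
        per_class: dict[str, list] = {n: [] for n in CLASS_NAMES.values()}
        for v in test_vols:
            pred = predict_volume(model, v, train_cfg.intensity_scale)
            for cid, cname in CLASS_NAMES.items():
                per_class[cname].append(class_metrics(pred, v.labels, cid))
        agg = {cname: _average_metrics(ms) for cname, ms in per_class.items()}
        models.append(model)
        fold_metrics.append(agg)
        loss_curves.append(curve)
        fold_subjects.append(sorted({v.subject_id for v in test_vols}))
    return models, FoldReport(fold_metrics, loss_curves, fold_subjects)


def _average_metrics(metrics_list):
    from .evaluate import ClassMetrics

    def nanmean(vals):
        vals = [v for v in vals if v == v]
        return float(np.mean(vals)) if vals else float("nan")

    return ClassMetrics(
        dice=nanmean([m.dice for m in metrics_list]),
        iou=nanmean([m.iou for m in metrics_list]),
        sensitivity=nanmean([m.sensitivity for m in metrics_list]),
        specificity=nanmean([m.specificity for m in metrics_list]),
    )
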
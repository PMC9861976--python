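"""Desk-scale segmentation-model demonstrator.

Patient-grouped data splitting, a seeded U-Net training loop with early
stopping (binary cross-entropy, RMSprop), and one round of automatic
hard-example retraining: after the first round a sample of training items is
profiled for pixel F-scores, the 30th percentile becomes a threshold, and
every training item scoring below it is duplicated before a second round of
training continues from the round-one weights.

Because the phantom's ground truth is produced by the confluence rule, a
sufficiently trained model here must recover that rule's output from the
intensity data alone — the pipeline's analogue of parameter recovery on
simulated data.  Two flavors share the architecture: the en face flavor
(input = mean-projection en face intensity, target = en face GA map) and the
B-scan flavor (input = intensity B-scan, target = BM-band mask).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize as _sk_resize

from ._nn import RMSprop, UNet
from .enface import binarize as _binarize_values
from .phantom import DeviceGeometry, generate_phantom

__all__ = [
    "TrainConfig",
    "PAPER_CONFIG",
    "DESK_CONFIG",
    "DESK_GEOMETRY",
    "TrainingHistory",
    "SplitAssignment",
    "TrainItem",
    "patient_split",
    "build_model",
    "make_enface_dataset",
    "make_bscan_dataset",
    "train",
    "mine_hard_examples",
    "retrain",
    "predict",
    "binarize",
    "pixel_f_score",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.

    ``PAPER_CONFIG`` carries the full-scale settings (256-px inputs, 5-px
    kernels, batch 40, 200 samples per epoch, learning rate 1e-4, early
    stopping after 7 epochs without validation improvement, ~2e7
    parameters).  ``DESK_CONFIG`` is the default: same loop and loss on a
    small net sized so a full train + retrain cycle takes minutes on one
    CPU; its higher learning rate compensates for the far smaller number of
    optimizer steps.
    """

    input_size: int = 64
    kernel_width: int = 5
    depth: int = 3
    base_filters: int = 4
    batch_size: int = 40
    samples_per_epoch: int = 200
    learning_rate: float = 1e-2
    early_stop_patience: int = 6
    max_epochs: int = 25
    loss: str = "bce"
    optimizer: str = "rmsprop"
    head_bias_init: float = -4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.input_size, self.batch_size, self.samples_per_epoch, self.max_epochs) < 1:
            raise ValueError("sizes must be positive")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")


DESK_CONFIG = TrainConfig()
PAPER_CONFIG = TrainConfig(
    input_size=256,
    kernel_width=5,
    depth=4,
    base_filters=32,
    batch_size=40,
    samples_per_epoch=200,
    learning_rate=1e-4,
    early_stop_patience=7,
    max_epochs=100,
)

#: small cube used for desk-scale experiments: 128 x 128 en face grid over
#: 6 mm x 6 mm so the mean projection is already model-sized, shallow depth
DESK_GEOMETRY = DeviceGeometry(n_bscans=128, n_ascans=128, n_depth=64)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0  # 1-based index of the last epoch run
    best_epoch: int = 0


@dataclass
class TrainItem:
    """One training example: image and binary target at native resolution."""

    image: np.ndarray
    target: np.ndarray
    item_id: str


# ---------------------------------------------------------------------------
# patient-grouped splitting
# ---------------------------------------------------------------------------


@dataclass
class SplitAssignment:
    assignment: dict  # patient_id -> "train" | "val" | "test"
    fractions: tuple[float, float, float]
    seed: int

    def patients(self, split: str) -> list:
        return [p for p, s in self.assignment.items() if s == split]


def patient_split(
    patients,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Assign whole patients to train/val/test.

    ``patients`` is a list of patient ids or of (patient_id, timepoints)
    pairs; every timepoint of a patient inherits its split, so no patient
    contributes to both training and testing.  Counts use largest-remainder
    rounding, so each realized split is within one patient of its target.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = [p[0] if isinstance(p, (tuple, list)) else p for p in patients]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    n = len(ids)
    n_splits = sum(f > 0 for f in fractions)
    if n < n_splits:
        raise ValueError(f"need at least {n_splits} patients for {n_splits} nonempty splits")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    for i in sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)[:rem]:
        counts[i] += 1
    names = ("train", "val", "test")
    assignment = {}
    pos = 0
    for name, c in zip(names, counts):
        for j in order[pos : pos + c]:
            assignment[ids[j]] = name
        pos += c
    return SplitAssignment(assignment, tuple(fractions), seed)


# ---------------------------------------------------------------------------
# model construction and phantom datasets
# ---------------------------------------------------------------------------


def build_model(config: TrainConfig = DESK_CONFIG) -> UNet:
    """Instantiate the seeded U-Net for a configuration.

    The output head's bias starts at ``head_bias_init`` so the network's
    initial confidence matches a low lesion prevalence instead of 0.5; with
    sparse targets this removes the long early phase in which training only
    pushes the background toward zero.
    """
    model = UNet(
        input_size=config.input_size,
        depth=config.depth,
        base=config.base_filters,
        k=config.kernel_width,
        seed=config.seed,
    )
    model.head.b[:] = config.head_bias_init
    return model


def make_enface_dataset(
    n_volumes: int,
    geometry: DeviceGeometry = DESK_GEOMETRY,
    seed: int = 0,
    *,
    n_lesions_range: tuple[int, int] = (1, 4),
    hyper_gain: float = 2.0,
    noise_sd: float = 0.05,
) -> list[TrainItem]:
    """En face flavor data: mean-projection intensity vs analytic GA map.

    One phantom cube per item; the lesion count is uniform over
    ``n_lesions_range`` (inclusive).
    """
    rng = np.random.default_rng(seed)
    items = []
    for i in range(n_volumes):
        n_les = int(rng.integers(n_lesions_range[0], n_lesions_range[1] + 1))
        vol = generate_phantom(
            geometry,
            n_les,
            seed=int(rng.integers(2**31)),
            hyper_gain=hyper_gain,
            noise_sd=noise_sd,
        )
        image = vol.intensity.mean(axis=1)  # (n_bscans, n_ascans)
        items.append(TrainItem(image.astype(np.float32), vol.truth_enface, f"vol{i:04d}"))
    return items


def make_bscan_dataset(
    n_volumes: int,
    geometry: DeviceGeometry = DESK_GEOMETRY,
    seed: int = 0,
    *,
    hyper_gain: float = 2.0,
    noise_sd: float = 0.05,
    thickness_px: int = 10,
) -> list[TrainItem]:
    """B-scan flavor data: intensity B-scans vs BM-band GA masks."""
    from .ga_mask import mask_volume

    rng = np.random.default_rng(seed)
    items = []
    for i in range(n_volumes):
        n_les = int(rng.integers(1, 4))
        vol = generate_phantom(
            geometry, n_les, seed=int(rng.integers(2**31)), hyper_gain=hyper_gain, noise_sd=noise_sd
        )
        masks = mask_volume(vol.layer_sets, geometry, thickness_px=thickness_px)
        for b in range(geometry.n_bscans):
            items.append(
                TrainItem(vol.intensity[b], masks[b].mask, f"vol{i:04d}_b{b:03d}")
            )
    return items


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _resize_image(img: np.ndarray, size: int) -> np.ndarray:
    """Resize to the model input and standardize to zero mean, unit std."""
    img = img.astype(float)
    if img.shape != (size, size):
        img = _sk_resize(img, (size, size), order=1, anti_aliasing=True)
    return ((img - img.mean()) / (img.std() + 1e-8)).astype(np.float32)


def _resize_target(t: np.ndarray, size: int) -> np.ndarray:
    if t.shape == (size, size):
        return t.astype(np.float32)
    return _sk_resize(t.astype(float), (size, size), order=0, anti_aliasing=False).astype(
        np.float32
    )


def _prepare(items, size) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([_resize_image(it.image, size) for it in items])[..., None]
    y = np.stack([_resize_target(it.target, size) for it in items])[..., None]
    return x, y


def _val_loss(model: UNet, xv: np.ndarray, yv: np.ndarray, batch: int) -> float:
    from ._nn import bce_with_logits

    losses, weights = [], []
    for i in range(0, len(xv), batch):
        logits = model.forward_logits(xv[i : i + batch])
        losses.append(bce_with_logits(logits, yv[i : i + batch])[0])
        weights.append(len(xv[i : i + batch]))
    return float(np.average(losses, weights=weights))


def should_stop(val_losses: list[float], patience: int) -> bool:
    """Early-stopping rule: no strict improvement for ``patience`` epochs."""
    if len(val_losses) <= patience:
        return False
    best = int(np.argmin(val_losses))
    return (len(val_losses) - 1 - best) >= patience


def train(
    model: UNet,
    train_items: list[TrainItem],
    val_items: list[TrainItem],
    config: TrainConfig = DESK_CONFIG,
    seed: int | None = None,
    optimizer: RMSprop | None = None,
) -> tuple[UNet, TrainingHistory]:
    """Seeded training loop with early stopping and best-weight restoration.

    Each epoch draws ``samples_per_epoch`` items from the training set with
    replacement (duplicated items are therefore sampled proportionally more
    often), runs mini-batches of ``batch_size``, and evaluates the full
    validation loss; training stops when the validation loss has not
    improved for ``early_stop_patience`` consecutive epochs or at
    ``max_epochs``, and the best-validation weights are restored.
    """
    if not train_items:
        raise ValueError("empty training set")
    if not val_items:
        raise ValueError("empty validation set (required for early stopping)")
    for it in train_items + val_items:
        u = np.unique(it.target)
        if not np.all(np.isin(u, (0, 1))):
            raise ValueError(f"non-binary target in item {it.item_id}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    opt = optimizer or RMSprop(lr=config.learning_rate)
    xt, yt = _prepare(train_items, config.input_size)
    xv, yv = _prepare(val_items, config.input_size)

    hist = TrainingHistory()
    best_weights = model.get_weights()
    best_val = np.inf
    for epoch in range(1, config.max_epochs + 1):
        idx = rng.integers(0, len(train_items), size=config.samples_per_epoch)
        ep_losses = []
        for i in range(0, len(idx), config.batch_size):
            sel = idx[i : i + config.batch_size]
            ep_losses.append(model.train_step(xt[sel], yt[sel], opt))
        hist.train_loss.append(float(np.mean(ep_losses)))
        vl = _val_loss(model, xv, yv, config.batch_size)
        hist.val_loss.append(vl)
        hist.stopped_epoch = epoch
        if vl < best_val:
            best_val = vl
            best_weights = model.get_weights()
            hist.best_epoch = epoch
        if should_stop(hist.val_loss, config.early_stop_patience):
            break
    model.set_weights(best_weights)
    return model, hist


# ---------------------------------------------------------------------------
# hard-example mining and retraining
# ---------------------------------------------------------------------------


def pixel_f_score(pred: np.ndarray, truth: np.ndarray) -> float:
    """Pixel-wise F; 1.0 when prediction and truth are both empty."""
    from .metrics import dice

    return dice(pred, truth)


def _item_f(model: UNet, item: TrainItem, input_size: int, threshold: float) -> float:
    conf = predict(model, item.image, input_size=input_size)
    return pixel_f_score(binarize(conf, threshold), item.target.astype(bool))


def augment_by_f_scores(
    train_items: list,
    f_all: np.ndarray,
    sample_idx: np.ndarray,
    percentile: float = 30.0,
) -> tuple[list, float]:
    """Duplication rule given per-item F-scores.

    The threshold is the ``percentile``-th percentile (linear interpolation)
    of the sampled scores; every item with F strictly below it is appended
    once after the originals.  All-tied samples leave the set unchanged.
    """
    thr = float(np.percentile(np.asarray(f_all, dtype=float)[sample_idx], percentile,
                              method="linear"))
    dups = [it for it, f in zip(train_items, f_all) if f < thr]
    return list(train_items) + dups, thr


def mine_hard_examples(
    model: UNet,
    train_items: list[TrainItem],
    sample_n: int = 100,
    percentile: float = 30.0,
    seed: int = 0,
    *,
    input_size: int | None = None,
    threshold: float = 0.5,
) -> tuple[list[TrainItem], float]:
    """Duplicate the training items the model performs worst on.

    A seeded sample of ``sample_n`` items is profiled for pixel F-scores and
    the ``percentile``-th percentile (linear interpolation) of those scores
    becomes the threshold; every training item with F strictly below it is
    appended once to the training list (originals retained, order stable).
    Returns (augmented items, threshold).  When all sampled F-scores tie,
    nothing falls strictly below the threshold and no item is duplicated.
    """
    size = input_size or model.input_size
    rng = np.random.default_rng(seed)
    n = len(train_items)
    if sample_n >= n:
        sample_idx = np.arange(n)
    else:
        sample_idx = rng.choice(n, size=sample_n, replace=False)
    f_all = np.array([_item_f(model, it, size, threshold) for it in train_items])
    return augment_by_f_scores(train_items, f_all, sample_idx, percentile)


def retrain(
    model: UNet,
    augmented_items: list[TrainItem],
    val_items: list[TrainItem],
    config: TrainConfig = DESK_CONFIG,
    seed: int | None = None,
) -> tuple[UNet, TrainingHistory]:
    """Second training round: same procedure and parameters, continuing from
    the round-one weights, on the duplicated-example training set."""
    return train(model, augmented_items, val_items, config, seed=seed)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def predict(model: UNet, image: np.ndarray, input_size: int | None = None) -> np.ndarray:
    """Per-pixel confidence map in [0, 1] at the image's native resolution.

    The image is resized to the model input on entry and the confidence map
    resized back on exit.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    size = input_size or model.input_size
    x = _resize_image(image, size)[None, ..., None]
    conf = model.predict_proba(x)[0, ..., 0].astype(float)
    if conf.shape != image.shape:
        conf = _sk_resize(conf, image.shape, order=1, anti_aliasing=False)
    return np.clip(conf, 0.0, 1.0)


def binarize(conf: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a confidence map; higher thresholds give subsets of positives."""
    return _binarize_values(conf, threshold)


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------


def save_model(model: UNet, config: TrainConfig, path) -> None:
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    meta = np.array(
        [config.input_size, config.depth, config.base_filters, config.kernel_width, config.seed]
    )
    np.savez(path, _meta=meta, **arrays)


def load_model(path) -> tuple[UNet, TrainConfig]:
    data = np.load(path)
    size, depth, base, k, seed = (int(v) for v in data["_meta"])
    config = replace(DESK_CONFIG, input_size=size, depth=depth, base_filters=base,
                     kernel_width=k, seed=seed)
    model = build_model(config)
    model.set_weights([data[f"w{i}"] for i in range(len(data.files) - 1)])
    return model, config
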
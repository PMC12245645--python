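"""SSS landmark localisation: U-Net heatmap regression (SSSLocNet).

The network takes the 21-channel rectified/normalised photoacoustic stack
and regresses a single-channel heatmap whose maximum marks the superior
sagittal sinus.  Exposed as the sklearn-style :class:`SSSLocalizer`
estimator (``fit`` on images + annotated points, ``predict`` points), with
the individual operations available as thin module functions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .core import SpectralImage, WavelengthGrid, default_grid
from .preprocess import (
    GeometricAugmentParams,
    TEST_RECTIFY_K,
    TRAIN_RECTIFY_K_RANGE,
    WavelengthBins,
    geometric_augment,
    make_heatmap_target,
    mask_channels,
    minmax_normalize,
    rectify_dynamic_range,
    sample_channel_subset,
)


@dataclass
class UNetConfig:
    in_channels: int = 21
    out_channels: int = 1
    levels: int = 4
    base_features: int = 8
    dropout_p: float = 0.5

    @property
    def deepest_features(self) -> int:
        return self.base_features * 2 ** (self.levels - 1)


@dataclass
class TrainConfig:
    batch_size: int = 4
    learning_rate: float = 1e-4
    epochs: int = 2000
    seed: int = 0
    augment_geometric: bool = True
    channel_subset_prob: float = 0.5
    rectify_k_range: tuple[float, float] = TRAIN_RECTIFY_K_RANGE


def build_localizer(cfg: UNetConfig, rng: np.random.Generator | None = None) -> nn.UNet:
    """Instantiate the heatmap-regression U-Net from its configuration."""
    return nn.UNet(
        in_channels=cfg.in_channels,
        out_channels=cfg.out_channels,
        levels=cfg.levels,
        base_features=cfg.base_features,
        dropout_p=cfg.dropout_p,
        rng=rng,
    )


def heatmap_to_point(heatmap: np.ndarray) -> tuple[int, int]:
    """(x, y) of the heatmap maximum; ties break to the smallest row-major index."""
    hm = np.asarray(heatmap)
    if hm.size == 0 or np.all(np.isnan(hm)):
        raise ValueError("heatmap is empty or all-NaN")
    flat = np.nanargmax(hm)
    y, x = np.unravel_index(flat, hm.shape)
    return int(x), int(y)


def _as_image(img) -> SpectralImage:
    return img if isinstance(img, SpectralImage) else SpectralImage(np.asarray(img))


def preprocess_for_inference(img, k: float = TEST_RECTIFY_K) -> np.ndarray:
    """Test-time conditioning: rectify at k, then joint min-max normalise."""
    out = minmax_normalize(rectify_dynamic_range(_as_image(img), k), mode="joint")
    return out.pixels


class SSSLocalizer(BaseEstimator):
    """Heatmap-regression landmark localiser for the superior sagittal sinus.

    Parameters mirror the published training recipe: batch size 4, Adam at
    1e-4, MSE loss against Gaussian heatmap targets (sigma 3 px, peak 1),
    dropout 0.5 after every pooling/upsampling stage, with rectification-k,
    geometric, and binned channel-subset augmentation.  ``epochs`` is
    config-scalable so the same estimator runs at desk scale.

    After ``fit``: ``model_`` (the network), ``loss_history_`` (per-epoch
    mean training loss), ``input_shape_``.
    """

    def __init__(self, in_channels: int = 21, levels: int = 4, base_features: int = 8,
                 dropout_p: float = 0.5, batch_size: int = 4, learning_rate: float = 1e-4,
                 epochs: int = 2000, heatmap_sigma: float = 3.0,
                 rectify_k: float = TEST_RECTIFY_K,
                 rectify_k_range: tuple[float, float] = TRAIN_RECTIFY_K_RANGE,
                 augment_geometric: bool = True,
                 augment_params: GeometricAugmentParams | None = None,
                 channel_subset_prob: float = 0.5,
                 random_state: int = 0):
        self.in_channels = in_channels
        self.levels = levels
        self.base_features = base_features
        self.dropout_p = dropout_p
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.heatmap_sigma = heatmap_sigma
        self.rectify_k = rectify_k
        self.rectify_k_range = rectify_k_range
        self.augment_geometric = augment_geometric
        self.augment_params = augment_params
        self.channel_subset_prob = channel_subset_prob
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _unet_config(self) -> UNetConfig:
        return UNetConfig(in_channels=self.in_channels, levels=self.levels,
                          base_features=self.base_features, dropout_p=self.dropout_p)

    def _ensure_model(self, shape_yx: tuple[int, int]) -> None:
        seq = np.random.SeedSequence(self.random_state)
        init_seq, data_seq, drop_seq = seq.spawn(3)
        if not hasattr(self, "model_"):
            self.model_ = build_localizer(self._unet_config(),
                                          rng=np.random.default_rng(init_seq))
            self.input_shape_ = tuple(shape_yx)
            self.loss_history_ = []
        self._data_rng = np.random.default_rng(data_seq)
        self._drop_rng = np.random.default_rng(drop_seq)

    def fit(self, X, y, grid: WavelengthGrid | None = None):
        """Train on raw image stacks ``X`` (n, 21, H, W) and points ``y`` (n, 2).

        ``X`` may also be a list of :class:`SpectralImage`.  Targets are
        (x, y) pixel annotations of the SSS centre.
        """
        images = [_as_image(x) for x in X]
        points = np.asarray(y, dtype=int)
        if len(images) == 0:
            raise ValueError("need at least one training sample")
        if points.shape != (len(images), 2):
            raise ValueError("y must be (n_samples, 2) (x, y) points")
        grid = grid or default_grid()
        bins = WavelengthBins()
        shape_yx = images[0].shape_yx
        self._ensure_model(shape_yx)
        model = self.model_
        opt = nn.Adam(list(model.layers()), lr=self.learning_rate)
        aug_params = self.augment_params or GeometricAugmentParams()
        rng = self._data_rng
        n = len(images)
        # per-image statistics for the rectify/normalise pair are reused
        # across epochs; only the draw of k changes per presentation
        stats = [(float(img.pixels.mean()), float(img.pixels.std()),
                  float(img.pixels.min()), float(img.pixels.max())) for img in images]
        targets = [make_heatmap_target(tuple(p), shape_yx, self.heatmap_sigma)
                   for p in points]

        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = np.empty((len(idx), *shape_yx, self.in_channels), dtype=np.float32)
                tb = np.empty((len(idx), *shape_yx, 1), dtype=np.float32)
                for bi, i in enumerate(idx):
                    k = rng.uniform(*self.rectify_k_range)
                    mean_i, std_i, min_i, max_i = stats[i]
                    t = mean_i + k * std_i
                    clipped = np.minimum(images[i].pixels, np.float32(t))
                    span = min(t, max_i) - min_i
                    norm = (clipped - np.float32(min_i)) / np.float32(span) \
                        if span > 0 else np.zeros_like(clipped)
                    img = SpectralImage(norm, images[i].pixel_spacing_mm)
                    hm = targets[i]
                    if self.augment_geometric:
                        img, hm = geometric_augment(img, hm, rng, aug_params)
                    if rng.random() < self.channel_subset_prob:
                        keep = sample_channel_subset(grid, bins, rng)
                        img = mask_channels(img, keep, grid)
                    xb[bi] = img.pixels.transpose(1, 2, 0)
                    tb[bi, ..., 0] = hm
                pred = model.forward(xb, dropout_rng=self._drop_rng)
                loss, grad = nn.mse_loss(pred, tb)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at epoch {epoch}"
                    )
                model.backward(grad)
                opt.step()
                losses.append(loss)
            self.loss_history_.append(float(np.mean(losses)))
        return self

    # ------------------------------------------------------------------
    def _forward(self, X, dropout_rng=None) -> np.ndarray:
        images = [_as_image(x) for x in X]
        xb = np.stack([
            preprocess_for_inference(img, self.rectify_k).transpose(1, 2, 0)
            for img in images
        ])
        out = self.model_.forward(xb, dropout_rng=dropout_rng)
        return out[..., 0]

    def predict_heatmap(self, X, stochastic: bool = False,
                        rng: np.random.Generator | None = None) -> np.ndarray:
        """Heatmaps for a batch; ``stochastic=True`` keeps dropout active (MCD)."""
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        drop = (rng or np.random.default_rng(0)) if stochastic else None
        return self._forward(X, dropout_rng=drop)

    def predict(self, X) -> np.ndarray:
        """Predicted (x, y) SSS locations, one row per image."""
        hms = self.predict_heatmap(X, stochastic=False)
        return np.array([heatmap_to_point(hm) for hm in hms])

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        state = {f"param.{k}": v for k, v in self.model_.state_dict().items()}
        meta = dict(config=asdict(self._unet_config()), seed=self.random_state,
                    input_shape=list(self.input_shape_))
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **state)

    @classmethod
    def load(cls, path, expected_config: UNetConfig | None = None) -> "SSSLocalizer":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg = UNetConfig(**meta["config"])
            if expected_config is not None and cfg != expected_config:
                raise ValueError(
                    f"checkpoint config {cfg} does not match expected {expected_config}"
                )
            est = cls(in_channels=cfg.in_channels, levels=cfg.levels,
                      base_features=cfg.base_features, dropout_p=cfg.dropout_p,
                      random_state=meta["seed"])
            est._ensure_model(tuple(meta["input_shape"]))
            est.model_.load_state_dict(
                {k[len("param."):]: data[k] for k in data.files if k.startswith("param.")}
            )
        return est


# ---------------------------------------------------------------------------
# spec-level functional wrappers

def train_localizer(model: nn.UNet, samples, cfg: TrainConfig,
                    heatmap_sigma: float = 3.0) -> tuple[nn.UNet, list[float]]:
    """Train an existing U-Net on :class:`SampleRecord` items; returns loss history."""
    if not samples:
        raise ValueError("need at least one training sample")
    est = SSSLocalizer(
        in_channels=model.in_channels, levels=model.levels,
        base_features=model.base_features, dropout_p=model.dropout_p,
        batch_size=cfg.batch_size, learning_rate=cfg.learning_rate, epochs=cfg.epochs,
        heatmap_sigma=heatmap_sigma, augment_geometric=cfg.augment_geometric,
        channel_subset_prob=cfg.channel_subset_prob,
        rectify_k_range=cfg.rectify_k_range, random_state=cfg.seed,
    )
    est.model_ = model
    est.input_shape_ = samples[0].image.shape_yx
    est.loss_history_ = []
    est.fit([s.image for s in samples], [s.sss_xy for s in samples])
    return est.model_, est.loss_history_


def predict_heatmap(model: nn.UNet, img, stochastic: bool = False,
                    rng: np.random.Generator | None = None,
                    rectify_k: float = TEST_RECTIFY_K) -> np.ndarray:
    """Single-image heatmap through the test-time preprocessing contract."""
    x = preprocess_for_inference(img, rectify_k).transpose(1, 2, 0)[None]
    drop = (rng or np.random.default_rng(0)) if stochastic else None
    return model.forward(x, dropout_rng=drop)[0, ..., 0]
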
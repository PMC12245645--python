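"""Leave-one-subject-out evaluation harness, metrics, and baseline workflows.

The central comparison is between the two-step workflow (landmark detection
followed by ROI spectral unmixing) and four end-to-end CNN baselines that
regress O2Satss directly from different input encodings:

* M1 — 21-channel min-max-normalised raw spectrum stack (no rectification);
* M2 — 1-channel O2Sat map, unmixed only in the 50x80 window around the SSS,
  zeros elsewhere;
* M3 — the 22-channel concatenation of M1 and M2;
* M4 — a 20x20 patch of the M3 stack cropped around the SSS, fed to a
  smaller CNN.

All metrics are pooled over leave-one-subject-out folds so every prediction
comes from a network that never saw the test subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from . import nn
from .core import SampleRecord, SpectralImage, StudyDataset
from .localization import SSSLocalizer
from .oximetry import (
    DEFAULT_ROI,
    HYPOXIA_THRESHOLD,
    ROIParams,
    UnmixConfig,
    measure_sample,
    unmix_region,
)
from .preprocess import GeometricAugmentParams, geometric_augment, minmax_normalize


@dataclass(frozen=True)
class FoldSpec:
    held_out_subject: str
    train_subjects: tuple[str, ...]


def loso_folds(ds: StudyDataset) -> list[FoldSpec]:
    """One fold per subject; the test sets partition the dataset."""
    if len(ds.subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least two subjects")
    return [
        FoldSpec(held_out_subject=s,
                 train_subjects=tuple(t for t in ds.subjects if t != s))
        for s in ds.subjects
    ]


def regression_metrics(pred, gt) -> dict[str, float]:
    """OLS of predictions on ground truth; slope, intercept and R^2 of the fit."""
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if pred.shape != gt.shape or pred.size < 3:
        raise ValueError("need equal-length prediction/truth vectors, n >= 3")
    if np.ptp(gt) == 0:
        return {"r_squared": float("nan"), "slope": float("nan"),
                "intercept": float("nan")}
    if np.ptp(pred) == 0:
        return {"r_squared": 0.0, "slope": 0.0, "intercept": float(pred[0])}
    fit = stats.linregress(gt, pred)
    return {"r_squared": float(fit.rvalue**2), "slope": float(fit.slope),
            "intercept": float(fit.intercept)}


def classify_and_score(preds, gts, threshold: float = HYPOXIA_THRESHOLD) -> dict:
    """Hypoxia (value < threshold) is the positive class; strict-< boundary."""
    preds = np.asarray(preds, dtype=float)
    gts = np.asarray(gts, dtype=float)
    pred_pos = preds < threshold
    gt_pos = gts < threshold
    tp = int(np.sum(pred_pos & gt_pos))
    fn = int(np.sum(~pred_pos & gt_pos))
    tn = int(np.sum(~pred_pos & ~gt_pos))
    fp = int(np.sum(pred_pos & ~gt_pos))
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return {"sensitivity": sens, "specificity": spec,
            "tp": tp, "fn": fn, "tn": tn, "fp": fp}


def curation_check(subject_samples: list[SampleRecord],
                   threshold: float = HYPOXIA_THRESHOLD) -> tuple[bool, str]:
    """Series-plausibility check: the first acquisition must read healthy.

    Oxygen is lowered gradually during a session, so a subject whose first
    blood-gas reading is already hypoxic points to a measurement error
    (catheter displacement, contaminated analyser) and is flagged.
    """
    if not subject_samples:
        return False, "no samples"
    first = subject_samples[0].o2satss_gt
    if first < threshold:
        return False, (f"first sample O2Satss {first:.1f}% is below "
                       f"{threshold:.0f}% (expected a healthy start)")
    return True, "ok"


@dataclass
class EvalMetrics:
    r_squared: float
    slope: float
    intercept: float
    sensitivity: float
    specificity: float
    n_failed: int
    predictions: pd.DataFrame = field(repr=False)


# ---------------------------------------------------------------------------
# baseline input assembly


@dataclass(frozen=True)
class BaselineVariant:
    name: str

    _CHANNELS = {"M1": 21, "M2": 1, "M3": 22, "M4": 22}

    def __post_init__(self):
        if self.name not in self._CHANNELS:
            raise ValueError("variant must be one of M1..M4")

    @property
    def n_channels(self) -> int:
        return self._CHANNELS[self.name]

    @property
    def patch(self) -> bool:
        return self.name == "M4"


def _o2sat_channel(sample: SampleRecord, sss_xy, cfg: UnmixConfig) -> np.ndarray:
    omap = unmix_region(sample.image, sss_xy, cfg)
    chan = np.where(omap.mask, omap.values, 0.0) / 100.0
    return chan.astype(np.float32)


def assemble_baseline_input(sample: SampleRecord, variant: BaselineVariant,
                            sss_xy=None, cfg: UnmixConfig | None = None,
                            patch_size: int = 20) -> np.ndarray:
    """Build the (C, H, W) network input for a baseline variant.

    M2-M4 need an SSS location (defaults to the expert annotation) and an
    unmixing configuration.  M4 patches falling outside the frame are
    zero-padded.
    """
    if variant.name != "M1":
        sss_xy = tuple(sss_xy if sss_xy is not None else sample.sss_xy)
        if cfg is None:
            raise ValueError(f"{variant.name} requires an unmixing configuration")
    norm = minmax_normalize(sample.image, "joint").pixels  # raw, not rectified

    if variant.name == "M1":
        return norm
    o2chan = _o2sat_channel(sample, sss_xy, cfg)[None]
    if variant.name == "M2":
        return o2chan
    stack = np.concatenate([norm, o2chan], axis=0)
    if variant.name == "M3":
        return stack
    # M4: patch crop with zero padding at the frame border
    half = patch_size // 2
    x, y = sss_xy
    out = np.zeros((stack.shape[0], patch_size, patch_size), dtype=np.float32)
    h, w = stack.shape[1:]
    y0, y1 = y - half, y - half + patch_size
    x0, x1 = x - half, x - half + patch_size
    sy, sx = slice(max(0, y0), min(h, y1)), slice(max(0, x0), min(w, x1))
    out[:, sy.start - y0:sy.stop - y0, sx.start - x0:sx.stop - x0] = stack[:, sy, sx]
    return out


class BaselineRegressor(BaseEstimator, RegressorMixin):
    """LeNet-style CNN regressing O2Satss from an image stack.

    Published recipe: batch size 8, Adam at 1e-6, MSE loss, 10,000 epochs,
    with hypoxia/normoxia groups sampled into each batch with equal
    probability to counter the ~70% hypoxic class imbalance.  ``epochs`` and
    ``learning_rate`` scale down for desk-size runs.  Targets are internally
    scaled to [0, 1].
    """

    def __init__(self, in_channels: int, input_hw: tuple[int, int],
                 conv_features: tuple[int, ...] = (8, 16), dense_width: int = 32,
                 batch_size: int = 8, learning_rate: float = 1e-6,
                 epochs: int = 10000, augment_geometric: bool = False,
                 threshold: float = HYPOXIA_THRESHOLD, random_state: int = 0):
        self.in_channels = in_channels
        self.input_hw = input_hw
        self.conv_features = conv_features
        self.dense_width = dense_width
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.augment_geometric = augment_geometric
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y):
        """X: (n, C, H, W) stacks; y: O2Satss percent."""
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=float)
        seq = np.random.SeedSequence(self.random_state)
        init_seq, samp_seq = seq.spawn(2)
        if not hasattr(self, "model_"):
            self.model_ = nn.LeNetRegressor(
                self.in_channels, self.input_hw, self.conv_features,
                self.dense_width, rng=np.random.default_rng(init_seq))
            self.loss_history_ = []
        rng = np.random.default_rng(samp_seq)
        hyp = np.nonzero(y < self.threshold)[0]
        nrm = np.nonzero(y >= self.threshold)[0]
        if len(hyp) == 0 or len(nrm) == 0:
            raise ValueError("balanced batches need both hypoxic and normoxic samples")
        opt = nn.Adam(list(self.model_.layers()), lr=self.learning_rate)
        steps = max(1, len(y) // self.batch_size)
        aug = GeometricAugmentParams()
        for _ in range(self.epochs):
            losses = []
            for _ in range(steps):
                groups = rng.random(self.batch_size) < 0.5
                idx = np.where(groups, rng.choice(hyp, self.batch_size),
                               rng.choice(nrm, self.batch_size))
                xb = X[idx]
                if self.augment_geometric:
                    xb = np.stack([self._augment(xi, rng, aug) for xi in xb])
                xb = xb.transpose(0, 2, 3, 1)
                pred = self.model_.forward(xb)
                loss, grad = nn.mse_loss(pred, y[idx] / 100.0)
                if not np.isfinite(loss):
                    raise RuntimeError("training diverged: non-finite loss")
                self.model_.backward(grad)
                opt.step()
                losses.append(loss)
            self.loss_history_.append(float(np.mean(losses)))
        return self

    @staticmethod
    def _augment(x, rng, params):
        img = SpectralImage(x)
        dummy = np.zeros(x.shape[1:], dtype=np.float32)
        dummy[x.shape[1] // 2, x.shape[2] // 2] = 1.0
        out, _ = geometric_augment(img, dummy, rng, params)
        return out.pixels

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32).transpose(0, 2, 3, 1)
        return self.model_.forward(X) * 100.0


def sample_balanced_batch(y, batch_size: int, rng: np.random.Generator,
                          threshold: float = HYPOXIA_THRESHOLD) -> np.ndarray:
    """Indices drawn from the hypoxic/normoxic groups with equal probability."""
    y = np.asarray(y, dtype=float)
    hyp = np.nonzero(y < threshold)[0]
    nrm = np.nonzero(y >= threshold)[0]
    if len(hyp) == 0 or len(nrm) == 0:
        raise ValueError("both classes must be present")
    groups = rng.random(batch_size) < 0.5
    return np.where(groups, rng.choice(hyp, batch_size), rng.choice(nrm, batch_size))


def train_baseline(variant: BaselineVariant, train_samples: list[SampleRecord],
                   cfg: UnmixConfig, epochs: int = 10000, learning_rate: float = 1e-6,
                   batch_size: int = 8, seed: int = 0,
                   use_predicted_sss=None) -> BaselineRegressor:
    """Assemble variant inputs from the samples and fit the baseline CNN."""
    inputs = np.stack([
        assemble_baseline_input(s, variant, sss_xy=None, cfg=cfg)
        for s in train_samples
    ])
    y = np.array([s.o2satss_gt for s in train_samples])
    hw = inputs.shape[2:]
    features = (8,) if variant.patch else (8, 16)
    reg = BaselineRegressor(
        in_channels=inputs.shape[1], input_hw=hw, conv_features=features,
        dense_width=16 if variant.patch else 32, batch_size=batch_size,
        learning_rate=learning_rate, epochs=epochs, random_state=seed)
    if epochs > 0:
        reg.fit(inputs, y)
    else:
        reg.model_ = nn.LeNetRegressor(inputs.shape[1], hw, features,
                                       16 if variant.patch else 32,
                                       rng=np.random.default_rng(seed))
        reg.loss_history_ = []
    return reg


# ---------------------------------------------------------------------------
# end-to-end pipeline


def run_full_pipeline(ds: StudyDataset, mode: str, cfg: UnmixConfig,
                      roi: ROIParams = DEFAULT_ROI, localizer_kwargs: dict | None = None,
                      baseline_kwargs: dict | None = None, seed: int = 0,
                      threshold: float = HYPOXIA_THRESHOLD) -> EvalMetrics:
    """Evaluate one workflow over leave-one-subject-out folds.

    ``mode``: ``"two-step"`` (train a localiser per fold, then ROI unmixing at
    the predicted point), ``"gt"`` (ROI unmixing at the expert annotation; no
    training), or a baseline name ``"M1"``..``"M4"`` (M4 reads the patch at
    the expert annotation, matching its evaluation convention).
    """
    folds = loso_folds(ds)
    rows = []
    for fold_i, fold in enumerate(folds):
        train = [s for s in ds.samples if s.subject_id != fold.held_out_subject]
        test = [s for s in ds.samples if s.subject_id == fold.held_out_subject]
        assert all(s.subject_id != fold.held_out_subject for s in train)

        if mode == "gt":
            preds = [measure_sample(s.image, s.sss_xy, cfg, roi) for s in test]
        elif mode == "two-step":
            kw = dict(localizer_kwargs or {})
            kw.setdefault("random_state", seed + fold_i)
            loc = SSSLocalizer(**kw)
            loc.fit([s.image for s in train], [s.sss_xy for s in train])
            points = loc.predict([s.image for s in test])
            preds = [measure_sample(s.image, tuple(p), cfg, roi)
                     for s, p in zip(test, points)]
        elif mode in ("M1", "M2", "M3", "M4"):
            variant = BaselineVariant(mode)
            kw = dict(baseline_kwargs or {})
            kw.setdefault("seed", seed + fold_i)
            reg = train_baseline(variant, train, cfg, **kw)
            inputs = np.stack([
                assemble_baseline_input(s, variant, sss_xy=None, cfg=cfg)
                for s in test
            ])
            preds = reg.predict(inputs)
        else:
            raise ValueError(f"unknown pipeline mode {mode!r}")

        for s, p in zip(test, preds):
            rows.append(dict(subject=s.subject_id, fold=fold.held_out_subject,
                             gt=s.o2satss_gt, pred=float(p), fio2=s.fio2))

    frame = pd.DataFrame(rows)
    ok = frame[np.isfinite(frame["pred"])]
    n_failed = len(frame) - len(ok)
    reg = regression_metrics(ok["pred"].to_numpy(), ok["gt"].to_numpy())
    cls = classify_and_score(ok["pred"].to_numpy(), ok["gt"].to_numpy(), threshold)
    frame["class_gt"] = np.where(frame["gt"] < threshold, "hypoxia", "normoxia")
    frame["class_pred"] = np.where(frame["pred"] < threshold, "hypoxia", "normoxia")
    return EvalMetrics(
        r_squared=reg["r_squared"], slope=reg["slope"], intercept=reg["intercept"],
        sensitivity=cls["sensitivity"], specificity=cls["specificity"],
        n_failed=n_failed, predictions=frame,
    )
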
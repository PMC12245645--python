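"""Monte Carlo dropout uncertainty for the two-step oxygenation readout.

Three sampling modes:

* ``model`` — dropout layers stay active at test time; each of ``n_model``
  stochastic forward passes on the full 21-channel input yields a landmark
  and hence an O2Satss reading (epistemic / model uncertainty);
* ``data`` — dropout off, each of ``n_data`` passes sees a fresh
  one-wavelength-per-bin 5-channel subset with the rest masked to zero
  (input-spectrum uncertainty);
* ``combined`` — the factorial n_model x n_data grid of (dropout mask,
  channel subset) configurations, 20 x 20 = 400 by default.

Per sample, the uncertainty epsilon is the standard deviation (population
formula) of the O2Satss readings in percentage points, and the confidence
score is beta = 1 - 2 * epsilon (epsilon as a fraction).  The dataset-level
summary mSTD is the mean of per-sample epsilons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SpectralImage, default_grid
from .localization import SSSLocalizer, heatmap_to_point
from .oximetry import ROIParams, UnmixConfig, extract_o2satss, smooth_o2sat_map, unmix_region
from .preprocess import WavelengthBins, mask_channels, sample_channel_subset


@dataclass
class MCDConfig:
    mode: str = "combined"          # model | data | combined
    n_model: int = 20
    n_data: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("model", "data", "combined"):
            raise ValueError(f"unknown MCD mode {self.mode!r}")
        if self.mode == "model" and self.n_model < 1:
            raise ValueError("model mode needs n_model >= 1")
        if self.mode == "data" and self.n_data < 1:
            raise ValueError("data mode needs n_data >= 1")

    @property
    def n_runs(self) -> int:
        if self.mode == "model":
            return self.n_model
        if self.mode == "data":
            return self.n_data
        return self.n_model * self.n_data


@dataclass
class UncertaintyResult:
    points: np.ndarray              # (n_runs, 2) predicted (x, y)
    o2sat_samples: np.ndarray       # (n_runs,) percent
    epsilon: float                  # std of o2sat samples, percentage points
    beta: float                     # 1 - 2 * epsilon/100
    xy_std: tuple[float, float]     # per-axis std, px
    low_confidence: bool = field(default=False)


def confidence_from_epsilon(epsilon: float) -> float:
    """beta = 1 - 2*epsilon for epsilon expressed as a fraction (0.20 -> 0.60)."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    return 1.0 - 2.0 * float(epsilon)


def mcd_sample(localizer: SSSLocalizer, img: SpectralImage, roi: ROIParams,
               cfg: UnmixConfig, mcd: MCDConfig) -> UncertaintyResult:
    """Run MCD inference on one sample and summarise the prediction spread.

    Every run goes through the standard step-2 path: predicted point ->
    regional unmix (computed once, around the deterministic prediction) ->
    sigma-smoothed map -> ROI average at the run's point.
    """
    grid = default_grid()
    bins = WavelengthBins()
    seq = np.random.SeedSequence(mcd.seed)
    model_seqs = seq.spawn(max(mcd.n_model, 1))
    data_rng = np.random.default_rng(seq.spawn(1)[0])

    # the O2Sat map depends only on the image; anchor it at the
    # deterministic prediction so all runs read from one map
    det_point = tuple(localizer.predict([img])[0])
    omap = smooth_o2sat_map(unmix_region(img, det_point, cfg), roi.sigma)

    if mcd.mode == "model":
        configs = [(i, None) for i in range(mcd.n_model)]
    elif mcd.mode == "data":
        subsets = [sample_channel_subset(grid, bins, data_rng) for _ in range(mcd.n_data)]
        configs = [(None, s) for s in subsets]
    else:
        subsets = [sample_channel_subset(grid, bins, data_rng) for _ in range(mcd.n_data)]
        configs = [(i, s) for i in range(mcd.n_model) for s in subsets]

    points = np.empty((len(configs), 2), dtype=int)
    o2 = np.empty(len(configs))
    for r, (mi, subset) in enumerate(configs):
        run_img = img if subset is None else mask_channels(img, subset, grid)
        if mi is None:
            hm = localizer.predict_heatmap([run_img], stochastic=False)[0]
        else:
            # one generator per model variation: the dropout mask is shared
            # across data variations of the same model index (factorial design)
            hm = localizer.predict_heatmap(
                [run_img], stochastic=True,
                rng=np.random.default_rng(model_seqs[mi]),
            )[0]
        pt = heatmap_to_point(hm)
        points[r] = pt
        o2[r] = extract_o2satss(omap, pt, roi)

    valid = np.isfinite(o2)
    if valid.any():
        vals = o2[valid]
        # identical readings are exactly zero-spread (no float residue)
        eps = 0.0 if np.ptp(vals) == 0 else float(np.std(vals))
    else:
        eps = float("nan")
    beta = confidence_from_epsilon(eps / 100.0) if np.isfinite(eps) else float("nan")
    return UncertaintyResult(
        points=points,
        o2sat_samples=o2,
        epsilon=eps,
        beta=beta,
        xy_std=(float(np.std(points[:, 0])), float(np.std(points[:, 1]))),
        low_confidence=bool(np.isfinite(beta) and beta < 0.0),
    )


def aggregate_mstd(results: list[UncertaintyResult]) -> dict[str, float]:
    """Dataset-level mean of per-sample stds (mSTD) and the matching mean beta."""
    if not results:
        raise ValueError("need at least one result")
    eps = np.array([r.epsilon for r in results])
    xs = np.array([r.xy_std[0] for r in results])
    ys = np.array([r.xy_std[1] for r in results])
    mstd = float(np.mean(eps))
    return {
        "mstd_o2sat": mstd,
        "mean_beta": confidence_from_epsilon(mstd / 100.0),
        "mstd_x_px": float(np.mean(xs)),
        "mstd_y_px": float(np.mean(ys)),
    }
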
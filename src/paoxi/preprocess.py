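"""Input conditioning and training-time augmentation.

Deterministic conditioning: dynamic-range rectification (clip at
mean + k*std of the full spectrum stack), min-max normalisation, and
Gaussian heatmap targets for landmark regression.  Stochastic training
augmentation: rectification-coefficient jitter, shared geometric warps of
the (image, heatmap) pair, and binned wavelength-channel dropout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import SpectralImage, WavelengthGrid

#: default saturation coefficient applied at test time
TEST_RECTIFY_K = 0.5

#: training-time range the coefficient is drawn from
TRAIN_RECTIFY_K_RANGE = (0.0, 1.0)

#: standard deviation (px) of the heatmap target Gaussian
HEATMAP_SIGMA = 3.0


def rectify_dynamic_range(img: SpectralImage, k: float = TEST_RECTIFY_K) -> SpectralImage:
    """Saturate intensities at T = mean + k * std over all channels jointly.

    The statistics are population statistics of the full 21-channel stack, so
    macro-vessels and micro-vessels end up on comparable footing and the
    brain-curvature structure dominates the rectified image.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    px = img.pixels
    t = float(px.mean()) + k * float(px.std())
    return SpectralImage(np.minimum(px, t), img.pixel_spacing_mm)


def minmax_normalize(img: SpectralImage, mode: str = "joint") -> SpectralImage:
    """Map intensities to [0, 1]; a degenerate (constant) scope maps to zeros."""
    px = img.pixels.astype(np.float32)
    if mode == "joint":
        lo, hi = float(px.min()), float(px.max())
        out = (px - lo) / (hi - lo) if hi > lo else np.zeros_like(px)
    elif mode == "per_channel":
        lo = px.min(axis=(1, 2), keepdims=True)
        hi = px.max(axis=(1, 2), keepdims=True)
        rng = hi - lo
        safe = np.where(rng > 0, rng, 1.0)
        out = np.where(rng > 0, (px - lo) / safe, 0.0)
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    return SpectralImage(out, img.pixel_spacing_mm)


def make_heatmap_target(
    sss_xy: tuple[int, int], shape: tuple[int, int], sigma: float = HEATMAP_SIGMA
) -> np.ndarray:
    """Gaussian-blurred point annotation, min-max normalised to peak exactly 1."""
    h, w = shape
    x, y = sss_xy
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError(f"point {sss_xy} outside shape {shape}")
    delta = np.zeros((h, w), dtype=np.float64)
    delta[y, x] = 1.0
    hm = ndimage.gaussian_filter(delta, sigma=sigma, mode="constant")
    hm -= hm.min()
    hm /= hm.max()
    return hm.astype(np.float32)


@dataclass(frozen=True)
class WavelengthBins:
    """Five inclusive nm ranges partitioning the 21-wavelength grid (4,4,5,4,4)."""

    ranges: tuple[tuple[float, float], ...] = (
        (700.0, 730.0),
        (740.0, 770.0),
        (780.0, 820.0),
        (830.0, 860.0),
        (870.0, 900.0),
    )

    def members(self, grid: WavelengthGrid) -> list[np.ndarray]:
        out = []
        for lo, hi in self.ranges:
            sel = grid.values[(grid.values >= lo) & (grid.values <= hi)]
            out.append(sel)
        return out

    def check_partition(self, grid: WavelengthGrid) -> None:
        members = self.members(grid)
        total = np.concatenate(members)
        if len(total) != len(grid.values) or not np.allclose(np.sort(total), grid.values):
            raise ValueError("bins do not partition the wavelength grid")


def sample_channel_subset(
    grid: WavelengthGrid, bins: WavelengthBins, rng: np.random.Generator
) -> np.ndarray:
    """Draw one wavelength per bin (5 total, spectrum-spanning by construction)."""
    return np.array([rng.choice(m) for m in bins.members(grid)])


def mask_channels(img: SpectralImage, keep, grid: WavelengthGrid) -> SpectralImage:
    """Zero out all channels except the listed wavelengths."""
    keep = np.atleast_1d(np.asarray(keep, dtype=float))
    out = np.zeros_like(img.pixels)
    for w in keep:
        i = grid.index_of(w)  # raises KeyError for wavelengths off the grid
        out[i] = img.pixels[i]
    return SpectralImage(out, img.pixel_spacing_mm)


@dataclass
class GeometricAugmentParams:
    """Magnitudes of the shared spatial transforms (flip/shift/rotate/scale/distort)."""

    p_apply: float = 0.5               # per-sample probability of any geometric warp
    p_flip: float = 0.5
    max_shift_frac: float = 0.10       # of each frame dimension
    max_rotate_deg: float = 10.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    p_distort: float = 0.3
    distort_cells: int = 4             # control grid resolution of the distortion field
    distort_mag_px: float = 2.0
    max_tries: int = 10

    @classmethod
    def identity(cls) -> "GeometricAugmentParams":
        return cls(p_apply=1.0, p_flip=0.0, max_shift_frac=0.0, max_rotate_deg=0.0,
                   scale_range=(1.0, 1.0), p_distort=0.0)


def _affine_pair(img: np.ndarray, hm: np.ndarray, matrix, offset) -> tuple[np.ndarray, np.ndarray]:
    # channel axis rides along untouched via a block-diagonal 3x3 matrix
    block = np.eye(3)
    block[1:, 1:] = matrix
    warped = ndimage.affine_transform(img, block, offset=[0.0, *offset], order=1,
                                      mode="constant", cval=0.0)
    hm_w = ndimage.affine_transform(hm, matrix, offset=offset, order=1,
                                    mode="constant", cval=0.0)
    return warped, hm_w


def geometric_augment(
    img: SpectralImage,
    heatmap: np.ndarray,
    rng: np.random.Generator,
    params: GeometricAugmentParams | None = None,
) -> tuple[SpectralImage, np.ndarray]:
    """Apply one shared random spatial transform to the (image, target) pair.

    The same warp acts on every image channel and on the heatmap; the warped
    heatmap is re-normalised to peak 1.  Draws whose peak leaves the frame are
    rejected and redrawn, so the returned target always has an in-frame peak.
    """
    params = params or GeometricAugmentParams()
    px = img.pixels
    h, w = heatmap.shape
    if px.shape[1:] != heatmap.shape:
        raise ValueError("image and heatmap spatial shapes differ")
    if rng.random() >= params.p_apply:
        return SpectralImage(px.copy(), img.pixel_spacing_mm), heatmap.copy()

    for _ in range(params.max_tries):
        flip = rng.random() < params.p_flip
        dy = rng.uniform(-params.max_shift_frac, params.max_shift_frac) * h
        dx = rng.uniform(-params.max_shift_frac, params.max_shift_frac) * w
        theta = np.deg2rad(rng.uniform(-params.max_rotate_deg, params.max_rotate_deg))
        scale = rng.uniform(*params.scale_range)
        distort = rng.random() < params.p_distort
        dfield = None
        if distort:
            cells = params.distort_cells
            coarse = rng.uniform(-params.distort_mag_px, params.distort_mag_px,
                                 size=(2, cells, cells))
            dfield = np.stack([
                ndimage.zoom(coarse[i], (h / cells, w / cells), order=3) for i in range(2)
            ])

        src = px[:, :, ::-1].copy() if flip else px
        src_hm = heatmap[:, ::-1].copy() if flip else heatmap

        # output (y, x) -> input coords: rotation+scale about the frame centre, then shift
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]]) / scale
        centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        offset = centre - rot @ centre - rot @ np.array([dy, dx])
        out_img, out_hm = _affine_pair(src, src_hm, rot, offset)

        if dfield is not None:
            yy, xx = np.mgrid[0:h, 0:w].astype(float)
            coords = np.array([yy + dfield[0], xx + dfield[1]])
            out_hm = ndimage.map_coordinates(out_hm, coords, order=1, mode="constant")
            # one call for all channels: integer channel coordinates keep
            # the interpolation strictly within each channel
            nch = out_img.shape[0]
            ch = np.broadcast_to(np.arange(nch, dtype=float)[:, None, None], (nch, h, w))
            coords3 = np.stack([ch,
                                np.broadcast_to(coords[0], (nch, h, w)),
                                np.broadcast_to(coords[1], (nch, h, w))])
            out_img = ndimage.map_coordinates(out_img, coords3, order=1, mode="constant")

        peak = float(out_hm.max())
        if peak > 0.2:  # peak still inside the frame
            out_hm = np.clip(out_hm / peak, 0.0, 1.0)
            return SpectralImage(out_img, img.pixel_spacing_mm), out_hm.astype(np.float32)

    # all draws pushed the peak out of the frame; fall back to the identity
    return SpectralImage(px.copy(), img.pixel_spacing_mm), heatmap.copy()
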
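"""Synthetic multispectral head-phantom generator.

Emulates the coronal photoacoustic appearance the pipeline is built around:
a skin/skull surface band near the top of the frame, cortical veins tracing
an "M"-shaped brain curvature that converges onto a midline dent, and the
superior sagittal sinus (SSS) as a disc at that dent at ~20 mm depth.  Each
subject gets its own anatomy (curvature amplitude, SSS depth/diameter jitter,
vessel layout, global intensity scale) and a declining venous-oxygenation
trajectory driven by a falling FiO2 schedule, so that roughly 70% of samples
end up hypoxic (O2Satss < 30%) under the default study conditions.

The forward model per pixel is

    I(lambda, y, x) = scale * bloodfrac(y, x) * S_GT(lambda, O2Sat(y, x))
                      * exp(-mu(lambda) * depth_mm(y)) + noise,  clipped at 0

i.e. reference hemoglobin spectra under single-exponential wavelength-
dependent fluence decay with additive Gaussian noise.  With ``noise_sd=0``
the model is exact and spectral unmixing with the matched attenuation model
inverts it to the assigned saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (
    AttenuationModel,
    ReferenceSpectra,
    SampleRecord,
    SpectralImage,
    StudyDataset,
    WavelengthGrid,
    build_reference_spectra,
    default_grid,
)

#: per-subject sample counts of the default study (10 subjects, 84 samples)
DEFAULT_SUBJECT_COUNTS = (10, 5, 6, 9, 11, 9, 8, 11, 6, 9)


@dataclass
class PhantomConfig:
    image_h: int = 96
    image_w: int = 128
    pixel_spacing_mm: float = 0.3
    sss_depth_mm: float = 20.0
    sss_depth_jitter_mm: float = 2.0
    sss_lateral_jitter_px: int = 3
    sss_diameter_mm: float = 3.6
    sss_diameter_jitter_mm: float = 0.8
    curvature_rise_mm: float = 4.0        # how much shallower the humps sit vs the dent
    curvature_rise_jitter_mm: float = 1.5
    dent_halfwidth_mm: float = 3.0        # lateral half-width of the midline dent
    n_cortical_vessels: int = 8
    vessel_blood_frac: float = 0.7
    curve_blood_frac: float = 0.35
    skin_band_depth_px: int = 6
    skin_band_thickness_px: int = 3
    skin_blood_frac: float = 0.5
    skin_o2sat: float = 95.0
    noise_rel_sd: float = 0.01            # additive noise sd, relative to the SSS peak
    intensity_scale_range: tuple[float, float] = (1.75e3, 2.3e6)
    mu_700_per_mm: float = 0.06           # fluence attenuation at 700 nm, 1/mm
    mu_900_per_mm: float = 0.10           # ... rising linearly to 900 nm
    o2sat_start_range: tuple[float, float] = (45.0, 60.0)
    o2sat_floor: float = 5.0
    o2sat_decay_rate: float = 2.1         # e-folding of the venous trajectory over a series
    o2sat_noise_sd: float = 2.0
    fio2_start: float = 1.0
    fio2_end: float = 0.08

    def validate(self) -> None:
        if self.image_h <= 0 or self.image_w <= 0:
            raise ValueError("image dimensions must be positive")
        sss_y = self.sss_depth_mm / self.pixel_spacing_mm
        margin = (self.sss_depth_jitter_mm + self.sss_diameter_mm / 2) / self.pixel_spacing_mm + 1
        if not (0 < sss_y - margin and sss_y + margin < self.image_h):
            raise ValueError("SSS geometry does not fit inside the image depth range")
        if self.sss_diameter_mm - self.sss_diameter_jitter_mm <= 0:
            raise ValueError("diameter jitter must keep the SSS diameter positive")
        if min(self.intensity_scale_range) <= 0:
            raise ValueError("intensity scales must be positive")


# tissue labels
BG, SKIN, VESSEL, SSS = 0, 1, 2, 3


@dataclass
class AnatomyMap:
    """Per-subject tissue geometry with per-pixel blood fraction and O2Sat."""

    labels: np.ndarray              # (H, W) int, one of BG/SKIN/VESSEL/SSS
    blood_frac: np.ndarray          # (H, W) in [0, 1]
    o2sat: np.ndarray               # (H, W) percent; venous pixels filled later
    sss_xy: tuple[int, int]
    pixel_spacing_mm: float

    def with_venous_o2sat(self, o2satss: float) -> "AnatomyMap":
        """Assign the subject-timepoint venous saturation to SSS and cortical veins."""
        o2 = self.o2sat.copy()
        o2[(self.labels == SSS) | (self.labels == VESSEL)] = float(o2satss)
        return replace(self, o2sat=o2)


def attenuation_model(cfg: PhantomConfig, grid: WavelengthGrid | None = None) -> AttenuationModel:
    """The lambda-dependent fluence decay used by the renderer (matched profile)."""
    grid = grid or default_grid()
    t = (grid.values - 700.0) / 200.0
    return AttenuationModel(cfg.mu_700_per_mm + t * (cfg.mu_900_per_mm - cfg.mu_700_per_mm))


def generate_anatomy(cfg: PhantomConfig, subject_rng: np.random.Generator) -> AnatomyMap:
    cfg.validate()
    h, w, sp = cfg.image_h, cfg.image_w, cfg.pixel_spacing_mm
    labels = np.zeros((h, w), dtype=np.int8)
    blood = np.zeros((h, w), dtype=float)
    o2 = np.full((h, w), np.nan)

    # skin/skull surface band near y = 0
    if cfg.skin_band_thickness_px > 0:
        y0 = cfg.skin_band_depth_px + int(subject_rng.integers(-2, 3))
        y0 = max(0, y0)
        band = slice(y0, min(h, y0 + cfg.skin_band_thickness_px))
        labels[band, :] = SKIN
        blood[band, :] = cfg.skin_blood_frac
        o2[band, :] = cfg.skin_o2sat

    # SSS disc at the midline dent
    depth_mm = cfg.sss_depth_mm + subject_rng.uniform(
        -cfg.sss_depth_jitter_mm, cfg.sss_depth_jitter_mm
    )
    cx = w // 2 + int(subject_rng.integers(-cfg.sss_lateral_jitter_px, cfg.sss_lateral_jitter_px + 1))
    cy = int(round(depth_mm / sp))
    diam_mm = cfg.sss_diameter_mm + subject_rng.uniform(
        -cfg.sss_diameter_jitter_mm, cfg.sss_diameter_jitter_mm
    )
    radius_px = max(1.0, diam_mm / sp / 2.0)
    yy, xx = np.mgrid[0:h, 0:w]
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError("SSS centre fell outside the image")

    # "M"-shaped cortical-vein curve: humps shallower than the dent, with the
    # dent bottom at the SSS centre depth
    rise_px = max(
        1.0,
        (cfg.curvature_rise_mm + subject_rng.uniform(-cfg.curvature_rise_jitter_mm,
                                                     cfg.curvature_rise_jitter_mm)) / sp,
    )
    dent_hw_px = cfg.dent_halfwidth_mm / sp
    half_span = 0.45 * w
    xs = np.arange(w)
    t = (xs - cx) / half_span
    dent = np.exp(-0.5 * (xs - cx) ** 2 / dent_hw_px**2)
    curve_y = cy - rise_px * (1.0 - dent) + 2.0 * rise_px * np.clip(np.abs(t) - 0.85, 0, None)
    curve_y = np.clip(np.round(curve_y).astype(int), 0, h - 1)
    on_curve = np.abs(t) <= 1.0

    if cfg.curve_blood_frac > 0:
        for x in xs[on_curve]:
            y = curve_y[x]
            labels[y, x] = np.where(labels[y, x] == BG, VESSEL, labels[y, x])
            blood[y, x] = max(blood[y, x], cfg.curve_blood_frac)

    # brighter minor cortical vessels: short strokes sitting on the curve
    if cfg.n_cortical_vessels > 0:
        cand = xs[on_curve & (np.abs(xs - cx) > 2.5 * radius_px)]
        if cand.size:
            picks = subject_rng.choice(cand, size=min(cfg.n_cortical_vessels, cand.size),
                                       replace=False)
            for x in picks:
                seg = slice(max(0, x - 2), min(w, x + 3))
                for xi in range(seg.start, seg.stop):
                    y = curve_y[xi]
                    for dy in (-1, 0, 1):
                        yi = min(h - 1, max(0, y + dy))
                        if labels[yi, xi] in (BG, VESSEL):
                            labels[yi, xi] = VESSEL
                            blood[yi, xi] = max(blood[yi, xi], cfg.vessel_blood_frac)

    labels[disc] = SSS
    blood[disc] = 1.0
    return AnatomyMap(labels, blood, o2, (cx, cy), sp)


def render_spectral_image(
    anatomy: AnatomyMap,
    ref: ReferenceSpectra,
    cfg: PhantomConfig,
    rng: np.random.Generator,
    intensity_scale: float | None = None,
    noise_rel_sd: float | None = None,
) -> SpectralImage:
    """Forward-render the multiwavelength stack from an anatomy map."""
    if np.any(np.isnan(anatomy.o2sat[anatomy.blood_frac > 0])):
        raise ValueError("anatomy has unassigned O2Sat in perfused pixels; "
                         "call with_venous_o2sat first")
    h, w = anatomy.labels.shape
    n_wl = ref.n_wavelengths
    scale = float(intensity_scale) if intensity_scale is not None else float(
        np.exp(rng.uniform(*np.log(cfg.intensity_scale_range)))
    )
    nrel = cfg.noise_rel_sd if noise_rel_sd is None else noise_rel_sd

    grid = WavelengthGrid(ref.wavelengths_nm[0], ref.wavelengths_nm[-1],
                          ref.wavelengths_nm[1] - ref.wavelengths_nm[0] if n_wl > 1 else 1.0,
                          ref.wavelengths_nm)
    atten = attenuation_model(cfg, grid)
    depth_mm = np.arange(h) * anatomy.pixel_spacing_mm
    decay = np.exp(-atten.mu_per_mm[:, None] * depth_mm[None, :])  # (n_wl, H)

    img = np.zeros((n_wl, h, w), dtype=np.float64)
    ys, xs = np.nonzero(anatomy.blood_frac > 0)
    if ys.size:
        s = anatomy.o2sat[ys, xs] / 100.0  # continuous blend, not snapped to the grid
        spectra = s[:, None] * ref.table[-1][None, :] + (1 - s[:, None]) * ref.table[0][None, :]
        # normalise so "blood at zero depth with unit fraction" peaks at `scale` AU
        spectra = spectra / ref.table.max() * scale
        vals = spectra.T * anatomy.blood_frac[ys, xs][None, :] * decay[:, ys]
        img[:, ys, xs] = vals

    if nrel > 0:
        sss_peak = img[:, anatomy.sss_xy[1], anatomy.sss_xy[0]].max()
        noise_sd = nrel * (sss_peak if sss_peak > 0 else scale)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
        np.clip(img, 0.0, None, out=img)

    return SpectralImage(img.astype(np.float32), anatomy.pixel_spacing_mm)


def _fio2_schedule(n: int, cfg: PhantomConfig) -> np.ndarray:
    if n == 1:
        return np.array([cfg.fio2_start])
    return np.geomspace(cfg.fio2_start, cfg.fio2_end, n)


def _o2sat_trajectory(n: int, cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Declining venous saturation: healthy start, exponential fall to a floor."""
    s0 = rng.uniform(*cfg.o2sat_start_range)
    u = np.arange(n) / max(n - 1, 1)
    base = cfg.o2sat_floor + (s0 - cfg.o2sat_floor) * np.exp(-cfg.o2sat_decay_rate * u)
    traj = base + rng.normal(0.0, cfg.o2sat_noise_sd, size=n)
    traj = np.clip(traj, 2.0, 100.0)
    traj[0] = np.clip(traj[0], 35.0, 100.0)  # the series always starts healthy
    return traj


def generate_study(
    n_subjects: int = 10,
    per_subject_counts: tuple[int, ...] | None = None,
    fio2_schedule=None,
    cfg: PhantomConfig | None = None,
    seed: int = 0,
    ref: ReferenceSpectra | None = None,
) -> StudyDataset:
    """Generate a full multi-subject study; fully determined by ``seed``."""
    cfg = cfg or PhantomConfig()
    cfg.validate()
    if per_subject_counts is None:
        per_subject_counts = tuple(DEFAULT_SUBJECT_COUNTS[i % len(DEFAULT_SUBJECT_COUNTS)]
                                   for i in range(n_subjects))
    if len(per_subject_counts) != n_subjects:
        raise ValueError("per_subject_counts length must equal n_subjects")
    if any(c <= 0 for c in per_subject_counts):
        raise ValueError("per-subject counts must be positive")
    ref = ref or build_reference_spectra(default_grid())

    master = np.random.SeedSequence(seed)
    subject_seqs = master.spawn(n_subjects)
    samples: list[SampleRecord] = []
    subjects: list[str] = []
    for i, (count, seq) in enumerate(zip(per_subject_counts, subject_seqs)):
        sid = f"S{i + 1:02d}"
        subjects.append(sid)
        rng = np.random.default_rng(seq)
        anatomy = generate_anatomy(cfg, rng)
        scale = float(np.exp(rng.uniform(*np.log(cfg.intensity_scale_range))))
        fio2 = np.asarray(fio2_schedule) if fio2_schedule is not None else _fio2_schedule(count, cfg)
        if len(fio2) != count:
            raise ValueError("fio2 schedule length must match the subject count")
        if np.any(np.diff(fio2) > 1e-12):
            raise ValueError("fio2 schedule must be non-increasing")
        traj = _o2sat_trajectory(count, cfg, rng)
        for k in range(count):
            filled = anatomy.with_venous_o2sat(traj[k])
            img = render_spectral_image(filled, ref, cfg, rng, intensity_scale=scale)
            samples.append(
                SampleRecord(
                    image=img,
                    subject_id=sid,
                    fio2=float(fio2[k]),
                    o2satss_gt=float(traj[k]),
                    sss_xy=anatomy.sss_xy,
                )
            )
    return StudyDataset(samples=samples, subjects=subjects)
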
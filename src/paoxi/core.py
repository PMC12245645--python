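"""Domain types: wavelength grid, spectral images, study records, reference spectra.

Conventions used throughout the package:

* images are indexed ``(channel, y, x)`` with ``y`` increasing with depth;
* pixel coordinates are 0-based ``(x, y)`` pairs;
* pixel spacing is isotropic, 0.3 mm by default;
* photoacoustic intensities are non-negative arbitrary units (AU).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._extinction import extinction_at

DEFAULT_PIXEL_SPACING_MM = 0.3


class InvalidGridError(ValueError):
    """Raised when a wavelength grid specification is inconsistent."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Inclusive arithmetic grid of acquisition wavelengths in nm."""

    start_nm: float
    stop_nm: float
    step_nm: float
    values: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.values)

    def index_of(self, wavelength_nm: float) -> int:
        idx = np.nonzero(np.isclose(self.values, wavelength_nm))[0]
        if idx.size == 0:
            raise KeyError(f"wavelength {wavelength_nm} nm not on the grid")
        return int(idx[0])


def wavelength_grid(start_nm: float, stop_nm: float, step_nm: float) -> WavelengthGrid:
    """Build the inclusive wavelength grid, e.g. (700, 900, 10) -> 21 values."""
    if stop_nm < start_nm:
        raise InvalidGridError("stop_nm must be >= start_nm")
    if step_nm <= 0:
        raise InvalidGridError("step_nm must be positive")
    n_steps = (stop_nm - start_nm) / step_nm
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise InvalidGridError(
            f"step {step_nm} does not divide the span [{start_nm}, {stop_nm}]"
        )
    count = int(round(n_steps)) + 1
    values = start_nm + step_nm * np.arange(count, dtype=float)
    return WavelengthGrid(start_nm, stop_nm, step_nm, values)


def default_grid() -> WavelengthGrid:
    """The 700-900 nm / 10 nm acquisition grid (21 wavelengths)."""
    return wavelength_grid(700.0, 900.0, 10.0)


def px_to_mm(pixels: float, pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM) -> float:
    """Convert a pixel distance to millimetres."""
    return float(pixels) * float(pixel_spacing_mm)


def mm_to_px(mm: float, pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM) -> float:
    return float(mm) / float(pixel_spacing_mm)


@dataclass
class SpectralImage:
    """Multiwavelength photoacoustic image stack, indexed (channel, y, x)."""

    pixels: np.ndarray
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a (channel, y, x) array")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    def spectrum_at(self, x: int, y: int) -> np.ndarray:
        return self.pixels[:, y, x]

    def depth_mm(self, y: float) -> float:
        return px_to_mm(y, self.pixel_spacing_mm)


@dataclass
class SampleRecord:
    """One acquisition: image + subject id, FiO2 level, blood-gas truth, SSS point."""

    image: SpectralImage
    subject_id: str
    fio2: float
    o2satss_gt: float
    sss_xy: tuple[int, int]


@dataclass
class StudyDataset:
    samples: list[SampleRecord]
    subjects: list[str]

    def __len__(self) -> int:
        return len(self.samples)

    def samples_of(self, subject_id: str) -> list[SampleRecord]:
        return [s for s in self.samples if s.subject_id == subject_id]


@dataclass
class ReferenceSpectra:
    """Reference photoacoustic amplitude table S_GT(lambda, O2Sat).

    Each row is a convex blend of the two hemoglobin endpoint spectra:
    ``S_GT(lambda, s) = (s/100) * eps_HbO2(lambda) + (1 - s/100) * eps_Hb(lambda)``.
    """

    wavelengths_nm: np.ndarray
    o2sat_grid: np.ndarray          # percent levels, e.g. 0..100 step 1
    table: np.ndarray               # shape (n_levels, n_wavelengths), AU

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.o2sat_grid = np.asarray(self.o2sat_grid, dtype=float)
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (len(self.o2sat_grid), len(self.wavelengths_nm)):
            raise ValueError("table shape must be (n_levels, n_wavelengths)")

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths_nm)

    def spectrum_at(self, o2sat_percent: float) -> np.ndarray:
        """Continuous blend at an arbitrary saturation (not snapped to the grid)."""
        s = float(o2sat_percent) / 100.0
        if self.o2sat_grid[0] == 0.0 and self.o2sat_grid[-1] == 100.0:
            return s * self.table[-1] + (1.0 - s) * self.table[0]
        hbo2, hb = extinction_at(self.wavelengths_nm)
        return s * hbo2 + (1.0 - s) * hb

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.table.T,
            index=pd.Index(self.wavelengths_nm, name="wavelength_nm"),
            columns=[f"s{int(v)}" for v in self.o2sat_grid],
        )


def build_reference_spectra(
    grid: WavelengthGrid, o2sat_step: float = 1.0
) -> ReferenceSpectra:
    """Tabulate S_GT over saturations 0..100 at ``o2sat_step`` percent spacing."""
    if o2sat_step <= 0 or abs(100.0 / o2sat_step - round(100.0 / o2sat_step)) > 1e-9:
        raise ValueError("o2sat_step must divide 100")
    hbo2, hb = extinction_at(grid.values)  # raises out-of-range error
    levels = np.arange(0.0, 100.0 + o2sat_step / 2, o2sat_step)
    frac = levels[:, None] / 100.0
    table = frac * hbo2[None, :] + (1.0 - frac) * hb[None, :]
    return ReferenceSpectra(grid.values.copy(), levels, table)


@dataclass
class CompensationProfile:
    """Per-wavelength multiplicative gain undoing fluence attenuation at one depth."""

    gains: np.ndarray
    reference_depth_mm: float

    def __post_init__(self) -> None:
        self.gains = np.asarray(self.gains, dtype=float)
        if np.any(self.gains <= 0):
            raise ValueError("gains must be positive")

    def apply(self, spectrum: np.ndarray) -> np.ndarray:
        return compensate_spectrum(spectrum, self)


@dataclass
class AttenuationModel:
    """Single-exponential fluence decay exp(-mu(lambda) * depth_mm)."""

    mu_per_mm: np.ndarray  # length n_wavelengths

    def __post_init__(self) -> None:
        self.mu_per_mm = np.asarray(self.mu_per_mm, dtype=float)

    def decay(self, depth_mm: float) -> np.ndarray:
        return np.exp(-self.mu_per_mm * float(depth_mm))

    def profile_at(self, depth_mm: float) -> CompensationProfile:
        return CompensationProfile(np.exp(self.mu_per_mm * float(depth_mm)), depth_mm)


def compensate_spectrum(spectrum: np.ndarray, compensation: CompensationProfile) -> np.ndarray:
    """Elementwise per-wavelength gain correction of a measured spectrum."""
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape[0] != len(compensation.gains):
        raise ValueError(
            f"spectrum has {spectrum.shape[0]} channels, profile has {len(compensation.gains)}"
        )
    return spectrum * compensation.gains
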
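"""Molar extinction coefficients of oxy- and deoxyhemoglobin in the NIR band.

Values are approximate published-compilation molar extinction coefficients
(cm^-1 / (mol/L)) for human HbO2 and Hb, tabulated at 10 nm steps over
700-900 nm.  The absolute scale is irrelevant downstream (photoacoustic
amplitudes are in arbitrary units and the unmixing fit is scale-invariant);
what matters is the spectral *shape*: HbO2 rising monotonically across the
band, Hb with its characteristic 756 nm peak, and the isosbestic crossing
near 800 nm where the two species absorb equally.
"""

from __future__ import annotations

import numpy as np

# wavelength (nm) -> (epsilon_HbO2, epsilon_Hb), cm^-1/M
EXTINCTION_TABLE: dict[int, tuple[float, float]] = {
    700: (290.0, 1794.3),
    710: (314.0, 1608.0),
    720: (342.0, 1327.0),
    730: (390.0, 1102.2),
    740: (446.0, 1200.0),
    750: (518.0, 1405.2),
    760: (586.0, 1548.5),
    770: (650.0, 1311.9),
    780: (710.0, 1056.0),
    790: (766.0, 880.0),
    800: (816.0, 761.8),
    810: (864.0, 717.1),
    820: (908.0, 694.3),
    830: (950.0, 684.5),
    840: (1006.0, 682.0),
    850: (1058.0, 691.3),
    860: (1092.0, 702.0),
    870: (1128.0, 714.0),
    880: (1154.0, 726.1),
    890: (1178.0, 741.0),
    900: (1198.0, 754.0),
}

WAVELENGTH_MIN_NM = min(EXTINCTION_TABLE)
WAVELENGTH_MAX_NM = max(EXTINCTION_TABLE)


def extinction_at(wavelengths_nm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (eps_HbO2, eps_Hb) linearly interpolated at the given wavelengths.

    Raises ``ValueError`` if any wavelength is outside the tabulated range.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    if np.any(wl < WAVELENGTH_MIN_NM) or np.any(wl > WAVELENGTH_MAX_NM):
        raise ValueError(
            f"wavelengths must lie within [{WAVELENGTH_MIN_NM}, {WAVELENGTH_MAX_NM}] nm"
        )
    knots = np.array(sorted(EXTINCTION_TABLE), dtype=float)
    hbo2 = np.array([EXTINCTION_TABLE[int(k)][0] for k in knots])
    hb = np.array([EXTINCTION_TABLE[int(k)][1] for k in knots])
    return np.interp(wl, knots, hbo2), np.interp(wl, knots, hb)
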
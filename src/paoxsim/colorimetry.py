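"""Colorimetry of diffuse reflectance spectra.

Converts skin reflectance spectra to CIELAB coordinates under illuminant D65
and the CIE 1964 10-degree standard observer, derives the individual
typology angle (ITA) — the standard colorimetric measure of skin tone —
renders sRGB hex swatches, and assigns Fitzpatrick skin types from ITA
bands.

ITA = arctan((L* - 50) / b*) * 180 / pi, in degrees: high ITA (bright,
weakly yellow) means light skin; ITA decreases monotonically with epidermal
melanin.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .adding_doubling import ReflectanceSpectrum

__all__ = [
    "ColorResult",
    "spectrum_to_lab",
    "ita",
    "lab_to_hex",
    "assign_fitzpatrick",
    "color_result",
    "FITZPATRICK_ITA_CUTS",
]

#: ITA cut points (degrees) between Fitzpatrick types I|II, II|III, III|IV,
#: IV|V, V|VI. Band edges follow the ITA-based skin-color classification
#: literature, with the I-IV cuts placed so the six-model series maps one
#: model per type.
FITZPATRICK_ITA_CUTS = (60.0, 48.0, 30.0, 10.0, -30.0)

_ROMAN = ("I", "II", "III", "IV", "V", "VI")

#: sRGB D65 white point (2-degree colorimetric standard); the observer
#: white computed from the bundled tables is mapped onto this before the
#: sRGB matrix, so a perfect reflector renders as #FFFFFF.
_SRGB_WHITE = np.array([0.95047, 1.0, 1.08883])

_XYZ_TO_RGB = np.array([
    [3.2406, -1.5372, -0.4986],
    [-0.9689, 1.8758, 0.0415],
    [0.0557, -0.2040, 1.0570],
])


@functools.lru_cache(maxsize=1)
def _observer_tables():
    import pandas as pd

    with (resources.files("paoxsim.data") / "cie1964_10deg.csv").open("r") as fh:
        cmf = pd.read_csv(fh, comment="#")
    with (resources.files("paoxsim.data") / "illuminant_d65.csv").open("r") as fh:
        d65 = pd.read_csv(fh, comment="#")
    lam = cmf["wavelength_nm"].to_numpy(float)
    xyz = cmf[["xbar", "ybar", "zbar"]].to_numpy(float)
    spd = np.interp(lam, d65["wavelength_nm"].to_numpy(float),
                    d65["power"].to_numpy(float))
    white = (spd[:, None] * xyz).sum(axis=0)
    white = 100.0 * white / white[1]
    return lam, xyz, spd, white


def d65_white_point() -> np.ndarray:
    """XYZ of the D65/10-degree white (Y = 100) from the bundled tables."""
    return _observer_tables()[3].copy()


def _f_lab(t):
    delta = 6.0 / 29.0
    return np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)


def _f_lab_inv(t):
    delta = 6.0 / 29.0
    return np.where(t > delta, t**3, 3 * delta**2 * (t - 4.0 / 29.0))


def spectrum_to_lab(spectrum) -> tuple[float, float, float]:
    """CIELAB (L*, a*, b*) of a reflectance spectrum under D65 / 10 degrees.

    Accepts a ReflectanceSpectrum or a (wavelengths, reflectance) pair. The
    spectrum must cover at least 450-700 nm; outside its support it is
    extended with its end values (the standard constant-extrapolation
    convention for reflectance factors).
    """
    if isinstance(spectrum, ReflectanceSpectrum):
        lam_r, refl = spectrum.grid.values, spectrum.R
    else:
        lam_r, refl = np.asarray(spectrum[0], float), np.asarray(spectrum[1], float)
    if lam_r[0] > 450.0 or lam_r[-1] < 700.0:
        raise ValueError("reflectance spectrum must cover at least 450-700 nm")
    lam, xyz, spd, white = _observer_tables()
    r = np.interp(lam, lam_r, refl)     # constant extrapolation at the ends
    raw = (spd[:, None] * r[:, None] * xyz).sum(axis=0)
    norm = (spd * xyz[:, 1]).sum()
    X, Y, Z = 100.0 * raw / norm
    fx, fy, fz = _f_lab(np.array([X, Y, Z]) / white)
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return float(L), float(a), float(b)


def ita(L_star: float, b_star: float) -> float:
    """Individual typology angle in degrees, restricted to (-90, 90].

    Uses the two-argument arctangent so b* = 0 is well defined (L* > 50,
    b* = 0 gives +90 deg).
    """
    angle = np.degrees(np.arctan2(L_star - 50.0, b_star))
    if angle > 90.0:
        angle -= 180.0
    elif angle <= -90.0:
        angle += 180.0
    return float(angle)


def lab_to_hex(L_star: float, a_star: float, b_star: float) -> str:
    """Render CIELAB to a gamma-encoded sRGB hex string (gamut-clipped)."""
    _, _, _, white = _observer_tables()
    fy = (L_star + 16.0) / 116.0
    fx = fy + a_star / 500.0
    fz = fy - b_star / 200.0
    xyz_rel = _f_lab_inv(np.array([fx, fy, fz]))   # XYZ relative to white
    rgb_lin = _XYZ_TO_RGB @ (xyz_rel * _SRGB_WHITE)
    rgb_lin = np.clip(rgb_lin, 0.0, 1.0)
    rgb = np.where(
        rgb_lin <= 0.0031308,
        12.92 * rgb_lin,
        1.055 * rgb_lin ** (1.0 / 2.4) - 0.055,
    )
    chans = np.round(np.clip(rgb, 0, 1) * 255).astype(int)
    return "#{:02X}{:02X}{:02X}".format(*chans)


def assign_fitzpatrick(ita_deg: float) -> str:
    """Fitzpatrick skin type I-VI from the ITA band cut points."""
    for i, cut in enumerate(FITZPATRICK_ITA_CUTS):
        if ita_deg > cut:
            return _ROMAN[i]
    return _ROMAN[5]


@dataclass(frozen=True)
class ColorResult:
    L_star: float
    a_star: float
    b_star: float
    ita_deg: float
    hex: str
    fitzpatrick: str

    def __post_init__(self):
        if not 0.0 <= self.L_star <= 100.0 + 1e-6:
            raise ValueError("L* outside [0, 100]")
        if not -90.0 < self.ita_deg <= 90.0:
            raise ValueError("ITA outside (-90, 90]")


def color_result(spectrum: ReflectanceSpectrum) -> ColorResult:
    """Full colorimetric summary of a reflectance spectrum."""
    L, a, b = spectrum_to_lab(spectrum)
    angle = ita(L, b)
    return ColorResult(
        L_star=L, a_star=a, b_star=b, ita_deg=angle,
        hex=lab_to_hex(L, a, b), fitzpatrick=assign_fitzpatrick(angle),
    )
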
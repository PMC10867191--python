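"""Standard curves for honeybee colorimetry.

Everything here is computed from closed forms so the package carries no
tabulated data:

* Receptor spectral sensitivities use the Govardovskii et al. (2000) A1
  visual-pigment nomogram with peak wavelengths 344 nm (UV), 436 nm (blue)
  and 544 nm (green) — the classic *Apis mellifera* values.
* The daylight-like illuminant is a 6500 K blackbody expressed as photon
  flux (quantum units), which is what photoreceptor catches integrate over.
* The adaptation background is a parametric green-leaf reflectance curve:
  low UV/blue reflectance, a chlorophyll "green bump" near 550 nm and the
  beginning of the red edge towards 700 nm.

Absolute scales are irrelevant throughout: quantum catches are normalised to
the background (von Kries adaptation), so only curve *shapes* matter.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .spectra import GRID, Spectrum, StandardCurves

#: Honeybee receptor peak sensitivities, nm.
BEE_LAMBDA_MAX = {"uv": 344.0, "blue": 436.0, "green": 544.0}

_RECEPTOR_ORDER = ("uv", "blue", "green")


def govardovskii_a1(lambda_max: float, grid: np.ndarray = GRID) -> np.ndarray:
    """A1 visual-pigment absorbance template (alpha + beta band), max 1.

    The alpha band follows the four-exponential Govardovskii template; the
    beta band is the standard Gaussian satellite peaking near 350 nm for
    mid-wavelength pigments.
    """
    grid = np.asarray(grid, dtype=float)
    x = lambda_max / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lam_beta = 189.0 + 0.315 * lambda_max
    b = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((grid - lam_beta) / b) ** 2))
    s = alpha + beta
    return s / s.max()


def bee_sensitivities(grid: np.ndarray = GRID) -> tuple[Spectrum, Spectrum, Spectrum]:
    """UV, blue and green honeybee receptor sensitivity curves (max 1)."""
    return tuple(
        Spectrum(grid, govardovskii_a1(BEE_LAMBDA_MAX[k], grid), label=f"S_{k}")
        for k in _RECEPTOR_ORDER
    )  # type: ignore[return-value]


def daylight_illuminant(grid: np.ndarray = GRID, temperature_k: float = 6500.0) -> Spectrum:
    """Daylight-like illuminant as relative photon flux.

    Planck's law for spectral radiance divided by the photon energy hc/λ,
    normalised to 1 at 500 nm.  A smooth stand-in for standard daylight with
    realistic relative UV content for open-sky conditions.
    """
    grid = np.asarray(grid, dtype=float)
    lam_m = grid * 1e-9
    h, c, kb = 6.62607015e-34, 2.99792458e8, 1.380649e-23
    radiance = lam_m**-5 / (np.exp(h * c / (lam_m * kb * temperature_k)) - 1.0)
    photons = radiance * lam_m  # divide by photon energy hc/λ
    ref = np.interp(500.0, grid, photons)
    return Spectrum(grid, photons / ref, label="daylight_6500K")


def green_leaf_background(grid: np.ndarray = GRID) -> Spectrum:
    """Canonical green-foliage reflectance: the hexagon adaptation background.

    ~5 % across UV/blue, a chlorophyll bump reaching ~15 % at 550 nm, and a
    rising red edge appearing just below 700 nm.
    """
    grid = np.asarray(grid, dtype=float)
    base = 0.05
    bump = 0.10 * np.exp(-(((grid - 550.0) / 40.0) ** 2))
    red_edge = 0.25 * expit((grid - 705.0) / 8.0)
    return Spectrum(grid, base + bump + red_edge, label="green_leaf")


def default_curves(grid: np.ndarray = GRID) -> StandardCurves:
    """The package's default viewing conditions: daylight over green foliage."""
    curves = StandardCurves(
        illuminant=daylight_illuminant(grid),
        background=green_leaf_background(grid),
        sensitivities=bee_sensitivities(grid),
    )
    curves.validate()
    return curves
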
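"""Honeybee hexagon colour space: quantum catch, excitation, hexagon loci.

The processing chain for one reflectance spectrum R(λ) viewed against green
foliage B(λ) under illuminant I(λ) with receptor sensitivities S_i(λ):

    P_i = ∫ R I S_i dλ / ∫ B I S_i dλ        (von Kries adaptation)
    E_i = P_i / (P_i + 1)                     (phototransduction)
    x = (√3/2)(E_g − E_uv),  y = E_b − (E_uv + E_g)/2

Colour contrast ``cc`` is the Euclidean distance of the locus from the
achromatic centre; green contrast ``gc = |0.5 − E_g|`` is the achromatic
signal carried by the green receptor channel.  The adaptation background
itself maps to the centre (cc = 0, gc = 0) by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import GRID, Spectrum, StandardCurves
from .standards import default_curves

#: Behavioural colour-discrimination threshold used for the achromatic region
#: around the hexagon centre, in hexagon units.
DEFAULT_ACHROMATIC_RADIUS = 0.11

#: Hexagon sector labels in counter-clockwise order starting at the blue-green
#: edge direction (angle 30° with x to the right, y up).  The pure UV receptor
#: direction points to angle 210°, blue to 90° and green to 330°.
SECTORS = ("blue-green", "blue", "UV-blue", "UV", "UV-green", "green")


class DegenerateCurvesError(ValueError):
    """A background integral is zero; adaptation is undefined."""


@dataclass
class ReceptorExcitation:
    """Adapted excitations of the UV, blue and green receptors."""

    E_uv: float
    E_b: float
    E_g: float
    P_uv: float = np.nan
    P_b: float = np.nan
    P_g: float = np.nan

    def as_array(self) -> np.ndarray:
        return np.array([self.E_uv, self.E_b, self.E_g])


@dataclass
class HexagonLocus:
    """Position in the colour hexagon plus the two signal statistics."""

    x: float
    y: float
    cc: float
    gc: float
    sector: str
    achromatic: bool


def quantum_catch(s: Spectrum, curves: StandardCurves | None = None) -> np.ndarray:
    """Background-relative quantum catches (P_uv, P_b, P_g), trapezoid rule."""
    if curves is None:
        curves = default_curves()
    g = curves.grid
    if len(s) != g.size or not np.allclose(s.wavelength_nm, g):
        raise ValueError(f"{s.label!r}: spectrum not on the standard-curve grid")
    illum = curves.illuminant.reflectance
    bg = curves.background.reflectance
    out = np.empty(3)
    for i, sens in enumerate(curves.sensitivities):
        w = illum * sens.reflectance
        denom = np.trapezoid(bg * w, g)
        if denom <= 0:
            raise DegenerateCurvesError(f"zero background catch for {sens.label}")
        out[i] = np.trapezoid(s.reflectance * w, g) / denom
    return out


def excitation(P: np.ndarray) -> ReceptorExcitation:
    """Hyperbolic transduction E = P/(P+1); the background yields E = 0.5."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("negative quantum catch")
    E = P / (P + 1.0)
    return ReceptorExcitation(E[0], E[1], E[2], P[0], P[1], P[2])


def _sector(x: float, y: float) -> str:
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    return SECTORS[int(theta // 60.0) % 6]


def hexagon_locus(
    E: ReceptorExcitation, achromatic_radius: float = DEFAULT_ACHROMATIC_RADIUS
) -> HexagonLocus:
    """Map receptor excitations to a hexagon locus with cc, gc and sector."""
    x = (np.sqrt(3.0) / 2.0) * (E.E_g - E.E_uv)
    y = E.E_b - (E.E_uv + E.E_g) / 2.0
    cc = float(np.hypot(x, y))
    gc = float(abs(0.5 - E.E_g))
    return HexagonLocus(
        x=float(x),
        y=float(y),
        cc=cc,
        gc=gc,
        sector="achromatic" if cc == 0.0 else _sector(x, y),
        achromatic=cc < achromatic_radius,
    )


def spectrum_to_signals(
    s: Spectrum,
    curves: StandardCurves | None = None,
    achromatic_radius: float = DEFAULT_ACHROMATIC_RADIUS,
) -> HexagonLocus:
    """Full chain: reflectance spectrum → hexagon locus with cc and gc."""
    return hexagon_locus(excitation(quantum_catch(s, curves)), achromatic_radius)


class HexagonTransformer(TransformerMixin, BaseEstimator):
    """Transform reflectance spectra into bee hexagon colour signals.

    A stateless-by-default transformer: ``fit`` builds the standard viewing
    conditions (daylight illuminant, green-foliage adaptation background,
    honeybee receptor sensitivities) on the common wavelength grid and
    precomputes the background catches; ``transform`` maps an
    ``(n_samples, n_wavelengths)`` reflectance matrix to a signal table.

    Parameters
    ----------
    curves : StandardCurves, optional
        Viewing conditions; defaults to the shipped daylight/foliage/honeybee
        set.
    achromatic_radius : float
        Radius of the achromatic region in hexagon units.

    Attributes
    ----------
    weights_ : ndarray of shape (3, n_wavelengths)
        Illuminant × sensitivity integrand per receptor.
    background_catch_ : ndarray of shape (3,)
        Unnormalised background catches (the von Kries denominators).
    """

    def __init__(
        self,
        curves: StandardCurves | None = None,
        achromatic_radius: float = DEFAULT_ACHROMATIC_RADIUS,
    ):
        self.curves = curves
        self.achromatic_radius = achromatic_radius

    def fit(self, X=None, y=None) -> "HexagonTransformer":
        curves = self.curves if self.curves is not None else default_curves()
        curves.validate()
        g = curves.grid
        w = np.stack(
            [curves.illuminant.reflectance * s.reflectance for s in curves.sensitivities]
        )
        denom = np.trapezoid(curves.background.reflectance * w, g, axis=1)
        if np.any(denom <= 0):
            raise DegenerateCurvesError("zero background catch")
        self.grid_ = g
        self.weights_ = w
        self.background_catch_ = denom
        return self

    def transform(self, X, labels=None) -> pd.DataFrame:
        """Map reflectance rows (on ``grid_``) to the per-sample signal table.

        ``X`` may be an ``(n, n_wavelengths)`` array or a list of
        :class:`Spectrum` already on the common grid.
        """
        if not hasattr(self, "weights_"):
            raise AttributeError("HexagonTransformer is not fitted")
        if len(X) and isinstance(X[0], Spectrum):
            if labels is None:
                labels = [s.label for s in X]
            X = np.stack([s.reflectance for s in X])
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.grid_.size:
            raise ValueError(
                f"expected {self.grid_.size} wavelengths, got {X.shape[1]}"
            )
        P = np.trapezoid(X[:, None, :] * self.weights_[None, :, :], self.grid_, axis=2)
        P /= self.background_catch_[None, :]
        E = P / (P + 1.0)
        x = (np.sqrt(3.0) / 2.0) * (E[:, 2] - E[:, 0])
        y = E[:, 1] - (E[:, 0] + E[:, 2]) / 2.0
        cc = np.hypot(x, y)
        gc = np.abs(0.5 - E[:, 2])
        sector = np.array(
            ["achromatic" if c == 0 else _sector(xi, yi) for xi, yi, c in zip(x, y, cc)]
        )
        df = pd.DataFrame(
            {
                "E_uv": E[:, 0],
                "E_b": E[:, 1],
                "E_g": E[:, 2],
                "x": x,
                "y": y,
                "cc": cc,
                "gc": gc,
                "sector": sector,
                "achromatic": cc < self.achromatic_radius,
            }
        )
        if labels is not None:
            df.insert(0, "species", list(labels))
        return df


def signals_table(
    specs, curves: StandardCurves | None = None,
    achromatic_radius: float = DEFAULT_ACHROMATIC_RADIUS,
) -> pd.DataFrame:
    """Per-species signal table for a collection of spectra on the grid."""
    t = HexagonTransformer(curves=curves, achromatic_radius=achromatic_radius).fit()
    return t.transform(list(specs))


def spectrum_to_rgb(s: Spectrum) -> tuple[float, float, float]:
    """Approximate human-vision RGB rendering of a reflectance spectrum.

    Cosmetic only (plot tip colours); Gaussian approximations to the CIE
    standard-observer matching functions, daylight-weighted, companded with
    sRGB gamma.  Not used by any statistic.
    """
    g = s.wavelength_nm
    illum = np.interp(g, GRID, default_curves().illuminant.reflectance)

    def gauss(mu, sig):
        return np.exp(-0.5 * ((g - mu) / sig) ** 2)

    xbar = 1.056 * gauss(599.8, 37.9) + 0.362 * gauss(442.0, 16.0) - 0.065 * gauss(501.1, 20.4)
    ybar = 0.821 * gauss(568.8, 46.9) + 0.286 * gauss(530.9, 16.3)
    zbar = 1.217 * gauss(437.0, 11.8) + 0.681 * gauss(459.0, 26.0)
    X = np.trapezoid(s.reflectance * illum * xbar, g)
    Y = np.trapezoid(s.reflectance * illum * ybar, g)
    Z = np.trapezoid(s.reflectance * illum * zbar, g)
    norm = np.trapezoid(illum * ybar, g)
    X, Y, Z = X / norm, Y / norm, Z / norm
    M = np.array(
        [[3.2406, -1.5372, -0.4986], [-0.9689, 1.8758, 0.0415], [0.0557, -0.2040, 1.0570]]
    )
    rgb = M @ np.array([X, Y, Z])
    rgb = np.clip(rgb, 0.0, 1.0)
    rgb = np.where(rgb <= 0.0031308, 12.92 * rgb, 1.055 * rgb ** (1 / 2.4) - 0.055)
    return tuple(float(v) for v in rgb)
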
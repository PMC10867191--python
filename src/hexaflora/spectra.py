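"""Reading, validation, resampling and averaging of flower reflectance spectra.

Spectra are measured relative to a white standard from 300 to 700 nm, with
3-5 replicate flowers per species.  Values are fractions: slightly negative
readings (instrument noise near the dark reference) are clipped to zero with
a warning, while values above 1 are kept because glossy petals can exceed a
diffuse white standard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Common wavelength grid, nm.  All colorimetric integration happens on it.
GRID: np.ndarray = np.arange(300.0, 701.0, 1.0)

WAVELENGTH_MIN = 300.0
WAVELENGTH_MAX = 700.0


class SpectrumFormatError(ValueError):
    """Input file lacks required columns or is unparseable."""


class SpectrumDataError(ValueError):
    """Numeric content of a spectrum violates its invariants."""


@dataclass
class Spectrum:
    """A single reflectance (or radiance) curve.

    Parameters
    ----------
    wavelength_nm : array
        Strictly increasing wavelengths in nm.
    reflectance : array
        Same length as ``wavelength_nm``; non-negative after clipping.
    label : str
        Species (or species/replicate) identifier.
    n_replicates : int
        Number of replicate flowers averaged into this curve.
    """

    wavelength_nm: np.ndarray
    reflectance: np.ndarray
    label: str = ""
    n_replicates: int = 1
    out_of_range: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        rf = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or rf.ndim != 1 or wl.size != rf.size:
            raise SpectrumDataError(
                f"{self.label!r}: wavelength and reflectance must be equal-length vectors"
            )
        if wl.size >= 2 and np.all(np.diff(wl) < 0):  # descending scans are fine
            wl, rf = wl[::-1], rf[::-1]
        if np.any(np.diff(wl) <= 0):
            bad = int(np.argmax(np.diff(wl) <= 0)) + 1
            raise SpectrumDataError(
                f"{self.label!r}: wavelengths not strictly monotone at row {bad}"
            )
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(rf)):
            raise SpectrumDataError(f"{self.label!r}: non-finite values")
        n_neg = int(np.sum(rf < 0))
        if n_neg:
            logger.warning(
                "%s: clipped %d negative reflectance value(s) to 0", self.label, n_neg
            )
            rf = np.clip(rf, 0.0, None)
        self.out_of_range = int(np.sum((wl < WAVELENGTH_MIN) | (wl > WAVELENGTH_MAX)))
        self.wavelength_nm = wl
        self.reflectance = rf

    def __len__(self) -> int:
        return self.wavelength_nm.size


@dataclass
class StandardCurves:
    """Illuminant, adaptation background and the three receptor sensitivities.

    All curves share one wavelength grid.  Sensitivities are normalised to a
    maximum of 1; the illuminant is in relative quantum units.
    """

    illuminant: Spectrum
    background: Spectrum
    sensitivities: tuple[Spectrum, Spectrum, Spectrum]  # UV, blue, green

    @property
    def grid(self) -> np.ndarray:
        return self.illuminant.wavelength_nm

    def validate(self) -> None:
        g = self.grid
        for s in (self.background, *self.sensitivities):
            if len(s) != g.size or not np.allclose(s.wavelength_nm, g):
                raise SpectrumDataError("standard curves not on a common grid")
        for s in self.sensitivities:
            if np.any(s.reflectance < 0):
                raise SpectrumDataError("negative receptor sensitivity")


DEFAULT_DIALECT: dict = {
    "sep": None,  # sniffed by pandas
    "wavelength": "wavelength",
    "reflectance": "reflectance",
    "species": "species",
    "replicate": "replicate",
}


def load_dialect(path: str | Path) -> dict:
    """Read a column-mapping config (YAML) and merge with defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    out = dict(DEFAULT_DIALECT)
    out.update(user)
    return out


def _resolve_column(df: pd.DataFrame, name: str) -> str | None:
    lower = {c.lower(): c for c in df.columns}
    return lower.get(name.lower())


def read_spectra(path: str | Path, dialect: Mapping | None = None) -> list[Spectrum]:
    """Read reflectance spectra from a delimited text file.

    Two layouts are accepted: a plain two-column file (wavelength,
    reflectance) holding one replicate, or a long-format table with species
    and optional replicate columns.  Rows outside 300-700 nm are retained but
    counted in ``Spectrum.out_of_range``.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=d["sep"], engine="python", comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SpectrumFormatError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise SpectrumFormatError(f"{path}: need at least two numeric columns")

    wl_col = _resolve_column(df, d["wavelength"])
    rf_col = _resolve_column(df, d["reflectance"])
    sp_col = _resolve_column(df, d["species"])
    rep_col = _resolve_column(df, d["replicate"])

    if wl_col is None or rf_col is None:
        # headerless / positional two-column file
        if df.shape[1] == 2:
            df = pd.read_csv(path, sep=d["sep"], engine="python", header=None,
                             comment="#", skiprows=_count_header_rows(path, d))
            wl_col, rf_col = df.columns[:2]
            sp_col = rep_col = None
        else:
            raise SpectrumFormatError(
                f"{path}: columns {d['wavelength']!r}/{d['reflectance']!r} not found"
            )

    wl = pd.to_numeric(df[wl_col], errors="coerce")
    rf = pd.to_numeric(df[rf_col], errors="coerce")
    bad = wl.isna() | rf.isna()
    if bad.any():
        raise SpectrumDataError(
            f"{path}: unparseable numeric value at row {int(np.argmax(bad.values))}"
        )

    out: list[Spectrum] = []
    if sp_col is not None and sp_col in df.columns:
        keys = [sp_col] + ([rep_col] if rep_col in df.columns else [])
        for key, grp in df.groupby(keys, sort=False):
            label = key[0] if isinstance(key, tuple) else key
            rep = key[1] if isinstance(key, tuple) and len(key) > 1 else None
            full = f"{label}" if rep is None else f"{label}::{rep}"
            out.append(
                Spectrum(wl[grp.index].to_numpy(), rf[grp.index].to_numpy(), label=full)
            )
    else:
        out.append(Spectrum(wl.to_numpy(), rf.to_numpy(), label=path.stem))
    return out


def _count_header_rows(path: Path, d: Mapping) -> int:
    with open(path) as fh:
        first = fh.readline()
    tokens = first.replace(",", " ").replace("\t", " ").split()
    try:
        [float(t) for t in tokens]
        return 0
    except ValueError:
        return 1


def resample(s: Spectrum, grid: np.ndarray = GRID) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < s.wavelength_nm[0] - 1e-9 or grid[-1] > s.wavelength_nm[-1] + 1e-9:
        raise SpectrumDataError(
            f"{s.label!r}: grid [{grid[0]}, {grid[-1]}] outside data span "
            f"[{s.wavelength_nm[0]}, {s.wavelength_nm[-1]}]"
        )
    rf = np.interp(grid, s.wavelength_nm, s.reflectance)
    return Spectrum(grid, rf, label=s.label, n_replicates=s.n_replicates)


def species_of(label: str) -> str:
    """Species part of a ``species::replicate`` label."""
    return label.split("::", 1)[0]


def average_replicates(specs: Iterable[Spectrum]) -> list[Spectrum]:
    """Pointwise mean of replicate spectra, grouped by species label.

    All spectra must already share one grid; the replicate count is recorded
    on the averaged spectrum.
    """
    groups: dict[str, list[Spectrum]] = {}
    for s in specs:
        groups.setdefault(species_of(s.label), []).append(s)
    out = []
    for species, members in groups.items():
        g = members[0].wavelength_nm
        for m in members[1:]:
            if len(m) != g.size or not np.allclose(m.wavelength_nm, g):
                raise SpectrumDataError(
                    f"{species}: replicates on mixed grids; resample first"
                )
        mean = np.mean([m.reflectance for m in members], axis=0)
        out.append(Spectrum(g, mean, label=species, n_replicates=len(members)))
    return out


def write_spectra(specs: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra as a long-format CSV (species, wavelength, reflectance)."""
    frames = [
        pd.DataFrame(
            {
                "species": s.label,
                "wavelength": s.wavelength_nm,
                "reflectance": s.reflectance,
            }
        )
        for s in specs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectra_dir(path: str | Path, dialect: Mapping | None = None) -> list[Spectrum]:
    """Read every ``*.csv``/``*.tsv``/``*.txt`` file under a directory."""
    path = Path(path)
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in {".csv", ".tsv", ".txt"}
    )
    if not files:
        raise FileNotFoundError(f"no spectra files in {path}")
    out: list[Spectrum] = []
    for f in files:
        out.extend(read_spectra(f, dialect))
    return out
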
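"""End-to-end elevational analysis: signals → zones → PGLS → signal tests.

For every elevational zone the pipeline prunes the phylogeny to the species
present, fits PGLS models of green contrast on colour contrast (linear,
quadratic, log) and on flower size (linear), selects among the
colour-contrast forms by AIC (ties on adjusted R²), and estimates Pagel's λ
for green contrast, colour contrast and size with likelihood-ratio tests.
Zone summaries report the kernel-density mode and the t-based 95% CI of each
signal, mirroring the usual community-level summary tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import models as _m
from . import phylo as _p
from . import spectra as _s
from .vision import HexagonTransformer

logger = logging.getLogger(__name__)

#: Elevational zone bins, half-open [low, high) in m a.s.l.  The upper edge
#: of Upper-montane is set at 3000 m so that every elevation has a zone.
ZONE_BINS = (
    ("Foothills", 0.0, 500.0),
    ("Submontane", 500.0, 1500.0),
    ("Montane", 1500.0, 2500.0),
    ("Upper-montane", 2500.0, 3000.0),
    ("Alpine", 3000.0, float("inf")),
)
ZONE_ORDER = tuple(z[0] for z in ZONE_BINS)

#: Quadratic fits need n > 3 + 1; require a little headroom per zone.
MIN_ZONE_N = 8


def assign_zone(elev_mean) -> str | np.ndarray:
    """Elevational zone for a mean elevation (m a.s.l.); vectorised."""
    arr = np.asarray(elev_mean, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative elevation")
    edges = [500.0, 1500.0, 2500.0, 3000.0]
    idx = np.digitize(arr, edges, right=False)
    if arr.ndim == 0:
        return ZONE_ORDER[int(idx)]
    return np.asarray(ZONE_ORDER)[idx]


def kde_mode(values: Sequence[float], n_grid: int = 512) -> float:
    """Mode of a continuous sample: Gaussian KDE (Silverman bandwidth),
    argmax on a 512-point grid over the data range."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values for a density mode")
    if np.ptp(v) == 0:
        return float(v[0])
    kde = stats.gaussian_kde(v, bw_method="silverman")
    grid = np.linspace(v.min(), v.max(), n_grid)
    return float(grid[np.argmax(kde(grid))])


def t_ci(values: Sequence[float], level: float = 0.95) -> tuple[float, float, float]:
    """(mean, lo, hi): t-based confidence interval for the mean."""
    v = np.asarray(values, dtype=float)
    m = float(v.mean())
    if v.size < 2 or np.ptp(v) == 0:
        return m, m, m
    se = v.std(ddof=1) / np.sqrt(v.size)
    tq = stats.t.ppf(0.5 + level / 2.0, df=v.size - 1)
    return m, m - tq * se, m + tq * se


@dataclass
class ZoneSummary:
    zone: str
    n: int
    mode_gc: float | None
    mode_cc: float | None
    mode_size: float | None
    mean_gc: float
    ci_gc: tuple[float, float]
    mean_cc: float
    ci_cc: tuple[float, float]
    mean_size: float
    ci_size: tuple[float, float]

    def to_row(self) -> dict:
        return {
            "zone": self.zone, "n": self.n,
            "mode_gc": self.mode_gc, "mode_cc": self.mode_cc,
            "mode_size": self.mode_size,
            "mean_gc": self.mean_gc, "gc_lo": self.ci_gc[0], "gc_hi": self.ci_gc[1],
            "mean_cc": self.mean_cc, "cc_lo": self.ci_cc[0], "cc_hi": self.ci_cc[1],
            "mean_size": self.mean_size, "size_lo": self.ci_size[0],
            "size_hi": self.ci_size[1],
        }


def summarize_zone(records: pd.DataFrame, zone: str) -> ZoneSummary:
    """Per-zone mode / mean / 95% CI of gc, cc and flower size."""
    modes = {}
    for col in ("gc", "cc", "size_mm"):
        if len(records) >= 3:
            modes[col] = kde_mode(records[col])
        else:
            logger.warning("%s: n=%d < 3, mode omitted", zone, len(records))
            modes[col] = None
    mg, lg, hg = t_ci(records["gc"])
    mc, lc, hc = t_ci(records["cc"])
    ms, ls, hs = t_ci(records["size_mm"])
    return ZoneSummary(
        zone=zone, n=len(records),
        mode_gc=modes["gc"], mode_cc=modes["cc"], mode_size=modes["size_mm"],
        mean_gc=mg, ci_gc=(lg, hg), mean_cc=mc, ci_cc=(lc, hc),
        mean_size=ms, ci_size=(ls, hs),
    )


@dataclass
class PipelineResult:
    signals: pd.DataFrame           # per-species cc/gc/hexagon coordinates
    table: pd.DataFrame             # joined species table with zones
    zone_summary: pd.DataFrame      # mode/mean/CI per zone
    pgls_fits: pd.DataFrame         # all per-zone model fits (coefficients, λ, AIC)
    model_selection: pd.DataFrame   # AIC ranking per zone
    signal_tests: pd.DataFrame      # Pagel's λ per trait per zone
    report: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.signals.to_csv(out / "signals.csv", index=False)
        self.table.to_csv(out / "species_table.csv")
        self.zone_summary.to_csv(out / "zone_summary.csv", index=False)
        self.pgls_fits.to_csv(out / "pgls_fits.csv", index=False)
        self.model_selection.to_csv(out / "model_selection.csv", index=False)
        self.signal_tests.to_csv(out / "phylo_signal.csv", index=False)
        with open(out / "run_log.json", "w") as fh:
            json.dump(self.report, fh, indent=2, default=str)


def read_traits(path: str | Path) -> pd.DataFrame:
    """Species trait table: size (mm) and elevational range (m a.s.l.)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    sp = cols.get("species")
    if sp is None:
        raise ValueError("trait table needs a 'species' column")
    df = df.set_index(sp)
    if "size_mm" not in cols and "size" in cols:
        df = df.rename(columns={cols["size"]: "size_mm"})
    if "elev_mean" not in cols:
        if "elev_min" in cols and "elev_max" in cols:
            df["elev_mean"] = (df[cols["elev_min"]] + df[cols["elev_max"]]) / 2.0
        else:
            raise ValueError("trait table needs elev_mean or elev_min/elev_max")
    if (df["size_mm"] <= 0).any():
        bad = df.index[df["size_mm"] <= 0].tolist()
        raise ValueError(f"non-positive flower size for {bad}")
    return df


def zone_models(zone_table: pd.DataFrame, tree, zone: str,
                response: str = "gc") -> tuple[list[_m.PGLSFit], pd.DataFrame]:
    """Fit the candidate PGLS models for one zone; returns (fits, ranking)."""
    sub = _p.prune_to(tree, list(zone_table.index))
    cov = _p.phylo_cov(sub)
    y = zone_table[response]
    X = zone_table[["cc", "size_mm"]]
    specs = [
        _m.ModelSpec(response, "linear", ("cc",)),
        _m.ModelSpec(response, "quadratic", ("cc",)),
        _m.ModelSpec(response, "log", ("cc",)),
    ]
    fits = [_m.pgls_fit(y, sp, X, cov) for sp in specs]
    _, ranking = _m.compare_models(fits)
    ranking.insert(0, "zone", zone)
    size_fit = _m.pgls_fit(y, _m.ModelSpec(response, "linear", ("size_mm",)), X, cov)
    return fits + [size_fit], ranking


def run_pipeline(
    spectra: str | Path | Sequence[_s.Spectrum],
    tree: str | Path,
    traits: str | Path | pd.DataFrame,
    config: Mapping | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis and (optionally) write the output bundle.

    ``spectra`` may be a directory of delimited files, a single long-format
    file, or an in-memory collection of :class:`Spectrum`; ``traits`` a CSV
    path or DataFrame with species, size and elevational range; ``tree`` a
    Newick path or string.
    """
    cfg = dict(config or {})
    min_zone_n = int(cfg.get("min_zone_n", MIN_ZONE_N))
    average_first = bool(cfg.get("average_spectra_first", True))
    dialect = cfg.get("dialect")

    # --- spectra → per-species signals
    if isinstance(spectra, (str, Path)):
        p = Path(spectra)
        raw = _s.read_spectra_dir(p, dialect) if p.is_dir() else _s.read_spectra(p, dialect)
    else:
        raw = list(spectra)
    raw = [_s.resample(s, _s.GRID) for s in raw]
    hexa = HexagonTransformer(achromatic_radius=cfg.get("achromatic_radius", 0.11)).fit()
    if average_first:
        averaged = _s.average_replicates(raw)
        signals = hexa.transform(averaged)
    else:  # model every replicate, then average loci per species
        per_rep = hexa.transform(raw)
        per_rep["species"] = [_s.species_of(l) for l in per_rep["species"]]
        num = per_rep.drop(columns=["sector", "achromatic"])
        signals = num.groupby("species", sort=False).mean().reset_index()

    sig = signals.set_index("species")

    # --- traits, zones, join
    tr = traits if isinstance(traits, pd.DataFrame) else read_traits(traits)
    tr = tr.copy()
    tr["zone"] = assign_zone(tr["elev_mean"].to_numpy())

    common = [s for s in sig.index if s in tr.index]
    dropped_no_traits = sorted(set(sig.index) - set(common))
    dropped_no_spectra = sorted(set(tr.index) - set(common))
    table = sig.loc[common, ["E_uv", "E_b", "E_g", "x", "y", "cc", "gc"]].join(
        tr.loc[common, ["size_mm", "elev_mean", "zone"]]
    )

    phylo_tree = _p.read_newick(tree)
    tips = {lf.taxon.label for lf in phylo_tree.leaf_node_iter()}
    matched = _p.match_labels(tips, list(table.index))
    dropped_no_tree = sorted(set(table.index) - set(matched))
    table = table.loc[list(matched)]

    # --- per-zone statistics
    summaries, fit_rows, rank_frames, signal_rows = [], [], [], []
    skipped_zones = []
    for zone in ZONE_ORDER:
        zt = table[table["zone"] == zone]
        if len(zt) == 0:
            continue
        if len(zt) >= 3:
            summaries.append(summarize_zone(zt, zone))
        if len(zt) < min_zone_n:
            skipped_zones.append({"zone": zone, "n": len(zt)})
            continue
        fits, ranking = zone_models(zt, phylo_tree, zone)
        rank_frames.append(ranking)
        for f in fits:
            row = {"zone": zone, **f.to_dict()}
            fit_rows.append(row)
        sub = _p.prune_to(phylo_tree, list(zt.index))
        cov = _p.phylo_cov(sub)
        for traitname in ("gc", "cc", "size_mm"):
            est = _m.phylo_signal(zt[traitname], cov, trait=traitname)
            signal_rows.append(
                {"zone": zone, "trait": traitname, "lambda": est.lambda_hat,
                 "lambda_ci_low": est.lambda_ci[0],
                 "lambda_ci_high": est.lambda_ci[1],
                 "loglik": est.loglik, "loglik0": est.loglik0,
                 "p_lrt": est.p_lrt, "n": est.n}
            )

    zone_summary = pd.DataFrame([s.to_row() for s in summaries])
    result = PipelineResult(
        signals=signals,
        table=table,
        zone_summary=zone_summary,
        pgls_fits=pd.DataFrame(fit_rows),
        model_selection=(pd.concat(rank_frames, ignore_index=True)
                         if rank_frames else pd.DataFrame()),
        signal_tests=pd.DataFrame(signal_rows),
        report={
            "n_species_joined": len(table),
            "zone_counts": table["zone"].value_counts().to_dict(),
            "dropped_no_traits": dropped_no_traits,
            "dropped_no_spectra": dropped_no_spectra,
            "dropped_no_tree": dropped_no_tree,
            "skipped_zones": skipped_zones,
            "average_spectra_first": average_first,
        },
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
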
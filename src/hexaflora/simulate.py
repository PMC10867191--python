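"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a community flower-signal study: an ultrametric
phylogeny with polytomies, a chromatic colour-contrast trait evolving by
λ-transformed Brownian motion, green contrast linked to colour contrast by a
linear/quadratic regression with phylogenetically structured noise, flower
sizes log-normal with a mean that declines with elevation, species spread
over five elevational zones in realistic proportions, and 3-5 replicate
reflectance spectra per species whose hexagon signals reproduce the species'
target colour and green contrast (inverse design through the vision model).
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .phylo import phylo_cov
from .spectra import GRID, Spectrum, write_spectra
from .standards import default_curves
from .vision import HexagonTransformer

#: Observed community proportions across the five elevational zones
#: (foothills ... alpine), from a 714-species island flora.
ZONE_PROPORTIONS = (183 / 714, 258 / 714, 170 / 714, 67 / 714, 36 / 714)

ZONE_ELEV_RANGES = ((0.0, 500.0), (500.0, 1500.0), (1500.0, 2500.0),
                    (2500.0, 3000.0), (3000.0, 3300.0))
ZONE_NAMES = ("Foothills", "Submontane", "Montane", "Upper-montane", "Alpine")


class SimulationConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """All knobs of the generator, with study-like defaults."""

    n_species: int = 300
    seed: int = 0
    zone_proportions: tuple = ZONE_PROPORTIONS
    # tree
    birth_rate: float = 1.0
    polytomy_fraction: float = 0.2
    # traits
    true_lambda: float = 0.5
    bm_sigma: float = 1.0          # latent Brownian sd over unit tree height
    beta0: float = 0.15
    beta1: float = 0.25
    beta2: float = 0.0             # quadratic cc term
    noise_sd: float = 0.05         # phylogenetically structured residual sd
    cc_scale: float = 0.65         # logistic squash ceiling for colour contrast
    cc_slope: float = 1.0
    # size model: log-normal, location declining linearly with elevation
    size0_mm: float = 14.5
    size_elev_slope: float = 8.0e-5  # per metre, on the log scale
    size_log_sd: float = 0.45
    # spectra
    replicates_min: int = 3
    replicates_max: int = 5
    replicate_noise_sd: float = 0.005
    replicate_length_scale_nm: float = 50.0
    cc_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if abs(sum(self.zone_proportions) - 1.0) > 1e-9:
            raise SimulationConfigError("zone proportions must sum to 1")
        if self.birth_rate <= 0 or self.bm_sigma <= 0 or self.noise_sd < 0:
            raise SimulationConfigError("rates must be positive")


def sim_tree(n: int, config: SimConfig | None = None,
             seed: int | None = None) -> dendropy.Tree:
    """Yule tree scaled to unit height, with a fraction of internal nodes
    collapsed into polytomies (tip depths preserved, so still ultrametric)."""
    config = config or SimConfig()
    if n < 2:
        raise ValueError("need at least 2 tips")
    seed = config.seed if seed is None else seed
    rnd = random.Random(int(seed))
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=config.birth_rate, death_rate=0.0,
        num_extant_tips=n, rng=rnd,
    )
    tree.seed_node.edge.length = None  # drop the stem edge above the root
    # the process stops exactly at the nth birth, leaving zero-length pendant
    # edges; run the clock on until the (n+1)th event would occur
    extra = rnd.expovariate(n * config.birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # unit height
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    h = max(depths)
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length /= h
    # deterministic tip labels
    ns = tree.taxon_namespace
    for k, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"S{k + 1:04d}"
    # collapse a sample of internal (non-root) nodes into polytomies
    internal = [
        nd for nd in tree.preorder_node_iter()
        if not nd.is_leaf() and nd.parent_node is not None
    ]
    n_collapse = int(round(config.polytomy_fraction * len(internal)))
    for nd in rnd.sample(internal, n_collapse):
        if nd.parent_node is None:  # may have been re-parented already
            continue
        parent = nd.parent_node
        for ch in list(nd.child_nodes()):
            ch.edge.length += nd.edge.length
            nd.remove_child(ch)
            parent.add_child(ch)
        parent.remove_child(nd)
    return tree


def _zone_counts(n: int, proportions) -> list[int]:
    """Largest-remainder apportionment of species into zones."""
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts.tolist()


def sim_traits(tree: dendropy.Tree, config: SimConfig | None = None,
               rng: np.random.Generator | None = None) -> tuple[pd.DataFrame, dict]:
    """Simulate (cc, gc, size, elevation, zone) for the tips of ``tree``.

    Returns the species-indexed trait table and a dict with the generating
    parameters (for recovery tests).
    """
    config = config or SimConfig()
    rng = rng or np.random.default_rng(config.seed)
    cov = phylo_cov(tree)
    taxa = cov.taxa
    n = len(taxa)
    Cl = cov.with_lambda(config.true_lambda)
    L = np.linalg.cholesky(Cl + 1e-10 * np.eye(n))

    z = config.bm_sigma * (L @ rng.standard_normal(n))
    cc = config.cc_scale * expit(config.cc_slope * z)
    noise = config.noise_sd * (L @ rng.standard_normal(n))
    gc = config.beta0 + config.beta1 * cc + config.beta2 * cc**2 + noise
    gc = np.clip(gc, 0.0, 0.5)
    if np.all((gc == 0.0) | (gc == 0.5)):
        raise SimulationConfigError("all green-contrast values clipped at a bound")

    counts = _zone_counts(n, config.zone_proportions)
    zone_idx = np.repeat(np.arange(5), counts)
    zone_idx = zone_idx[rng.permutation(n)]
    lo = np.array([ZONE_ELEV_RANGES[i][0] for i in zone_idx])
    hi = np.array([ZONE_ELEV_RANGES[i][1] for i in zone_idx])
    elev = rng.uniform(lo, hi)
    half = rng.uniform(0.0, np.minimum(300.0, elev))
    # keep elev_mean inside the assigned zone bin
    half = np.minimum(half, np.minimum(elev - lo, hi - elev) * 0.999 + 1e-9)
    elev_min = elev - half
    elev_max = elev + half

    log_size = (np.log(config.size0_mm) - config.size_elev_slope * elev
                + config.size_log_sd * rng.standard_normal(n))
    size = np.exp(log_size)

    df = pd.DataFrame(
        {
            "species": taxa,
            "cc": cc,
            "gc": gc,
            "size_mm": size,
            "elev_min": elev_min,
            "elev_max": elev_max,
            "elev_mean": (elev_min + elev_max) / 2.0,
            "zone": [ZONE_NAMES[i] for i in zone_idx],
        }
    ).set_index("species")
    truth = {
        "beta0": config.beta0, "beta1": config.beta1, "beta2": config.beta2,
        "lambda": config.true_lambda, "noise_sd": config.noise_sd,
        "bm_sigma": config.bm_sigma, "cc_scale": config.cc_scale,
        "size0_mm": config.size0_mm, "size_elev_slope": config.size_elev_slope,
        "size_log_sd": config.size_log_sd, "n_species": n, "seed": config.seed,
    }
    return df, truth


def _flower_shape(rng: np.random.Generator) -> np.ndarray:
    """Random smooth flower-like profile on GRID: sigmoid step + Gaussian
    band, normalised to max 1."""
    edge = rng.uniform(380.0, 620.0)
    width = rng.uniform(10.0, 40.0)
    if rng.random() < 0.25:  # occasional short-wavelength-reflecting flower
        width = -width
    centre = rng.uniform(320.0, 680.0)
    bw = rng.uniform(20.0, 80.0)
    amp = rng.uniform(0.2, 1.0)
    f = expit((GRID - edge) / width) + amp * np.exp(-(((GRID - centre) / bw) ** 2))
    return f / f.max()


def _smooth_noise(rng: np.random.Generator, sd: float, length_scale: float) -> np.ndarray:
    """Smooth replicate-to-replicate perturbation: coarse Gaussian control
    points interpolated over the grid (GP-like, length scale in nm)."""
    knots = np.arange(GRID[0], GRID[-1] + length_scale, length_scale)
    vals = rng.standard_normal(knots.size)
    return sd * np.interp(GRID, knots, vals)


def sim_spectra(traits: pd.DataFrame, config: SimConfig | None = None,
                rng: np.random.Generator | None = None
                ) -> tuple[list[Spectrum], list[str]]:
    """Inverse-design replicate spectra matching each species' cc and gc.

    Each species' curve is a brightness-scaled blend of the green-foliage
    background (achromatic direction) and a random flower profile (chromatic
    direction); the two free parameters are solved so the hexagon locus hits
    the species' target colour contrast and green-receptor excitation.
    Species whose best design misses cc by more than ``cc_tolerance`` are
    returned in the flagged list (their best-effort spectra are still
    emitted).
    """
    config = config or SimConfig()
    rng = rng or np.random.default_rng(config.seed + 1)
    curves = default_curves()
    t = HexagonTransformer(curves=curves).fit()
    bg = curves.background.reflectance
    denom = t.background_catch_
    w = t.weights_

    out: list[Spectrum] = []
    flagged: list[str] = []
    for species, row in traits.iterrows():
        cc_target = float(row["cc"])
        # gc = |0.5 - E_g|: a bright or a dark flower both realise it; let
        # the search try both, starting with a random one
        signs = [1.0, -1.0] if rng.random() < 0.5 else [-1.0, 1.0]

        # search well inside the flag threshold so replicate noise and
        # averaging cannot push an accepted species past it
        search_tol = min(0.02, config.cc_tolerance)
        best = None
        for sign in signs:
            eg_target = float(np.clip(0.5 + sign * row["gc"], 0.03, 0.97))
            for _ in range(6):  # retry with a fresh random shape if needed
                shape = _flower_shape(rng)
                pF = np.trapezoid(shape[None, :] * w, GRID, axis=1) / denom

                def resid(params, pF=pF, eg=eg_target):
                    tt, ss = params
                    P = ss * ((1.0 - tt) + tt * pF)
                    E = P / (P + 1.0)
                    x = (np.sqrt(3.0) / 2.0) * (E[2] - E[0])
                    y = E[1] - (E[0] + E[2]) / 2.0
                    return [np.hypot(x, y) - cc_target, 2.0 * (E[2] - eg)]

                sol = min(
                    (optimize.least_squares(
                        resid, x0=x0, bounds=([0.0, 0.01], [1.0, 60.0]))
                     for x0 in ([0.5, 1.0], [0.9, 4.0])),
                    key=lambda s: float(np.sum(s.fun**2)),
                )
                err = float(np.hypot(sol.fun[0], sol.fun[1] / 2.0))
                if best is None or err < best[0]:
                    best = (err, sol.x, shape)
                if err <= search_tol:
                    break
            if best[0] <= search_tol:
                break
        err, (tt, ss), shape = best
        if err > config.cc_tolerance:
            flagged.append(species)
        base = ss * ((1.0 - tt) * bg + tt * shape)

        n_rep = int(rng.integers(config.replicates_min, config.replicates_max + 1))
        for r in range(1, n_rep + 1):
            noise = _smooth_noise(rng, config.replicate_noise_sd,
                                  config.replicate_length_scale_nm)
            out.append(Spectrum(GRID.copy(), np.clip(base + noise, 0.0, None),
                                label=f"{species}::{r}"))
    return out, flagged


def simulate_dataset(config: SimConfig | None = None,
                     out_dir: str | Path | None = None) -> dict:
    """Full synthetic study: tree + traits + replicate spectra (+ files).

    Returns a dict with keys ``tree``, ``traits``, ``spectra``, ``truth``,
    ``flagged``.  If ``out_dir`` is given, writes ``tree.nwk``,
    ``traits.csv``, ``spectra.csv`` and ``truth.json`` there.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    tree = sim_tree(config.n_species, config, seed=config.seed)
    traits, truth = sim_traits(tree, config, rng)
    spectra, flagged = sim_spectra(traits, config, rng)
    truth["flagged_species"] = flagged
    result = {"tree": tree, "traits": traits, "spectra": spectra,
              "truth": truth, "flagged": flagged}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tree.write(path=str(out / "tree.nwk"), schema="newick",
                   suppress_rooting=True)
        traits.to_csv(out / "traits.csv")
        write_spectra(spectra, out / "spectra.csv")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    return result
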
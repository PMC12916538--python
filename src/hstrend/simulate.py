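"""Synthetic landscapes and virtual species with known suitability trends.

Every downstream stage of the pipeline is validated against data generated
here: spatially autocorrelated annual predictor fields with piecewise
regional linear trends plus i.i.d. noise, and virtual species whose true
suitability is a product of Gaussian responses to the predictors, so the
sign of each cell's suitability trend is known exactly from the noise-free
deterministic part of the simulation.

The default configuration emulates the shape of the study system the
pipeline targets: a 30 x 29 lattice (870 valid cells), 23 annual layers,
six predictors (five continuous, one binary fire-presence layer), and 25
virtual species in five pseudo-taxonomic groups of five, each with 30
presence cells.  One predictor carries engineered regional dynamics over
five column bands — a pair of "degrading" bands whose values drift away
from the community niche centre, an unsuitable central ridge, and a pair
of "recovering" bands drifting toward the centre — so that "declining"
species (localized on the degrading pair by a static gradient predictor)
lose suitability over time while "improving" species (on the recovering
pair) gain it.  See :func:`default_predictors` for the full geometry and
the rationale.

All randomness flows from one seed through named substreams (predictors /
noise / species / presences / traits) so stages can be regenerated
independently and reproducibly.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .grid import (Grid, RasterLayer, PredictorStack, OccurrenceSet,
                   write_raster_stack, write_occurrences, write_ascii_grid)

GROUPS = ("flora", "amphibians", "reptiles", "birds", "mammals")
DIETS = ("herbivore", "carnivore", "omnivore", "detritivore", "autotroph")
HABITATS = ("forest", "grassland", "wetland", "rocky", "generalist")
CLIMATE = ("atlantic", "mediterranean", "transitional")
ACTIVITY = ("diurnal", "nocturnal", "cathemeral")
FEEDING = ("grazer", "browser", "predator", "filter", "none")
PHOTOSYNTHESIS = ("C3", "C4", "CAM", "none")
REPRODUCTION = ("oviparous", "viviparous", "seed", "spore")
STATUSES = ("LC", "LC", "LC", "NT", "VU", "EN", "CR", "DD", "NE")


def _substream(seed: int, *tags):
    keys = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        keys.append(zlib.crc32(str(t).encode()) if isinstance(t, str) else int(t))
    return np.random.default_rng(np.random.SeedSequence(keys))


@dataclass
class PredictorSpec:
    """One synthetic predictor: smoothed base field + regional structure.

    The landscape is divided into ``len(region_trends)`` equal column
    bands (west to east).  Band ``i`` adds ``region_offsets[i]`` to the
    base field and drifts linearly by ``region_trends[i]`` per year, so
    some areas improve and others degrade.  ``gradient=True`` replaces
    the random base field with a deterministic west-east ramp from -1 to
    +1 (plus smoothed noise), giving species a way to be spatially
    localized without any temporal trend.
    """

    name: str
    base_mean: float = 0.0
    base_sd: float = 1.0
    smooth_radius: int = 3
    region_trends: tuple = (0.0,)
    region_offsets: tuple | None = None
    region_scales: tuple | None = None
    attractor_offsets: tuple | None = None
    attractor_rows: int = 0
    attractor_scale: float | None = None
    noise_sd: float = 0.1
    binary: bool = False
    binary_p: float = 0.15
    gradient: bool = False

    def __post_init__(self):
        if self.region_offsets is None:
            self.region_offsets = tuple(0.0 for _ in self.region_trends)
        if len(self.region_offsets) != len(self.region_trends):
            raise ValueError("region_offsets must match region_trends")
        if self.region_scales is None:
            self.region_scales = tuple(1.0 for _ in self.region_trends)
        if len(self.region_scales) != len(self.region_trends):
            raise ValueError("region_scales must match region_trends")
        if (self.attractor_offsets is not None
                and len(self.attractor_offsets) != len(self.region_trends)):
            raise ValueError("attractor_offsets must match region_trends")


def default_predictors():
    """Six predictors echoing a remote-sensing candidate set.

    The vegetation index carries the engineered dynamics over five column
    bands: two "degrading" bands whose values drift away from the global
    mean (offset +1 drifting up, offset -1 drifting down), a static
    "ridge" band offset far from every species' niche (environmentally
    unsuitable, so it separates the two landscape halves), and two
    "recovering" bands that are the exact time reversal of the degrading
    ones — offset -(1+D) drifting up and +(1+D) drifting down, where
    D = 0.04 x 22 = 0.88 is the total drift over the default 23 years,
    so their values end one unit from the global mean just as the
    degrading bands start one unit from it.  A species centred at the
    global mean of the index therefore loses suitability in the
    degrading bands and gains it in the recovering ones, and in both
    cases a presence sample spread over the band pair has offsetting
    drifts, so its environmental distribution stays stationary over the
    years (which keeps annually refit niches anchored).  Each trending
    band carries narrow "attractor" row strips at the niche-crossing
    value, giving presences value-symmetric cells whose pooled
    distribution is invariant under the drift; interannual noise (0.3)
    keeps sub-signal model drift below the trend-detection threshold.
    The remaining predictors are a static west-east gradient (spatial
    localization), day/night surface temperature and time-since-fire
    (untrended nuisance fields), and a binary annual-burn layer.
    """
    return [
        PredictorSpec("evi",
                      region_trends=(0.04, -0.04, 0.0, 0.04, -0.04),
                      region_offsets=(1.0, -1.0, 3.0, -1.88, 1.88),
                      region_scales=(0.5, 0.5, 1.0, 0.5, 0.5),
                      attractor_offsets=(-0.44, 0.44, 3.0, -0.44, 0.44),
                      attractor_rows=4, noise_sd=0.3),
        PredictorSpec("grad", gradient=True, noise_sd=0.05),
        PredictorSpec("lst_day", noise_sd=0.15),
        PredictorSpec("lst_night", noise_sd=0.15),
        PredictorSpec("tsf", noise_sd=0.2),
        PredictorSpec("aab", binary=True, binary_p=0.15),
    ]


@dataclass
class VirtualSpecies:
    """A species with a known product-Gaussian suitability response."""

    species_id: str
    mu: dict                      # predictor -> response centre
    sigma: dict                   # predictor -> response width (> 0)
    n_presences: int = 30
    traits: dict = field(default_factory=dict)
    status_regional: str = "LC"
    status_european: str = "LC"
    cohort: str = "stable"        # declining | improving | stable

    def __post_init__(self):
        if any(s <= 0 for s in self.sigma.values()):
            raise ValueError("response widths must be > 0")


@dataclass
class SimulationConfig:
    n_rows: int = 30
    n_cols: int = 29
    n_years: int = 23
    start_year: int = 2001
    predictors: list = field(default_factory=default_predictors)
    n_species: int = 25
    n_presences: int = 30
    min_records: int = 15
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_years < 3:
            raise ValueError("need at least 3 years for trend analysis")
        if self.n_presences < self.min_records:
            raise ValueError("n_presences must satisfy the minimum-records filter")

    @property
    def years(self):
        return list(range(self.start_year, self.start_year + self.n_years))

    def grid(self) -> Grid:
        return Grid(self.n_rows, self.n_cols, origin_x=0.0,
                    origin_y=float(self.n_rows), cell_size=1.0)


def _region_of_cols(n_cols: int, n_regions: int) -> np.ndarray:
    """Column -> band index (0 = westernmost of ``n_regions`` equal bands)."""
    edges = np.array([n_cols * k / n_regions for k in range(1, n_regions)])
    return np.searchsorted(edges, np.arange(n_cols), side="right")


def _base_field(spec: PredictorSpec, rng, n_rows, n_cols) -> np.ndarray:
    w = rng.standard_normal((n_rows, n_cols))
    b = uniform_filter(w, size=2 * spec.smooth_radius + 1, mode="reflect")
    sd = b.std()
    if sd > 0:
        b = (b - b.mean()) / sd
    if spec.gradient:
        ramp = np.linspace(-1.0, 1.0, n_cols)
        return spec.base_mean + np.broadcast_to(ramp, (n_rows, n_cols)) + 0.1 * b
    reg = _region_of_cols(n_cols, len(spec.region_offsets))
    # standardize within each band so the regional offsets are exact:
    # the smoothed field has long-range correlation, and without this the
    # realized band means wander by several tenths between seeds
    for r in range(len(spec.region_offsets)):
        cols = reg == r
        blk = b[:, cols]
        sd = blk.std()
        b[:, cols] = (blk - blk.mean()) / sd if sd > 0 else 0.0
    offset2d = np.broadcast_to(
        np.asarray(spec.region_offsets, dtype=float)[reg],
        (n_rows, n_cols)).copy()
    scale2d = np.broadcast_to(
        np.asarray(spec.region_scales, dtype=float)[reg],
        (n_rows, n_cols)).copy()
    if spec.attractor_offsets is not None and spec.attractor_rows > 0:
        # the top and bottom row strips of each band take the attractor
        # offset instead: cells there sit tightly at the presence-
        # attracting value (so sampling weights are symmetric across a
        # band pair) while the band interior carries the trend geometry
        att = np.asarray(spec.attractor_offsets, dtype=float)[reg]
        k = spec.attractor_rows
        for sl in (slice(None, k), slice(n_rows - k, None)):
            offset2d[sl, :] = att
            if spec.attractor_scale is not None:
                scale2d[sl, :] = spec.attractor_scale
    return spec.base_mean + spec.base_sd * b * scale2d + offset2d


def _trend_field(spec: PredictorSpec, n_rows, n_cols) -> np.ndarray:
    reg = _region_of_cols(n_cols, len(spec.region_trends))
    tau = np.asarray(spec.region_trends, dtype=float)[reg]
    return np.broadcast_to(tau, (n_rows, n_cols)).copy()


def simulate_predictors(cfg: SimulationConfig, noise: bool = True) -> PredictorStack:
    """Generate the annual predictor stack.

    Continuous predictors follow value(cell, t) = B(cell) + tau(cell)*t +
    eps with B a kernel-smoothed white-noise field, tau piecewise-constant
    over column thirds, and eps ~ N(0, noise_sd) i.i.d.; binary predictors
    are Bernoulli(binary_p) per cell-year.  With ``noise=False`` the
    deterministic part is returned (binary layers become their constant
    expectation), which defines the ground-truth trends.
    """
    grid = cfg.grid()
    layers = {}
    for spec in cfg.predictors:
        rng_base = _substream(cfg.rng_seed, "predictors", spec.name)
        rng_noise = _substream(cfg.rng_seed, "noise", spec.name)
        if spec.binary:
            for t, y in enumerate(cfg.years):
                if noise:
                    v = (rng_noise.random((cfg.n_rows, cfg.n_cols))
                         < spec.binary_p).astype(float)
                else:
                    v = np.full((cfg.n_rows, cfg.n_cols), spec.binary_p)
                layers[(y, spec.name)] = RasterLayer(grid, v.ravel())
        else:
            B = _base_field(spec, rng_base, cfg.n_rows, cfg.n_cols)
            tau = _trend_field(spec, cfg.n_rows, cfg.n_cols)
            for t, y in enumerate(cfg.years):
                v = B + tau * t
                if noise and spec.noise_sd > 0:
                    v = v + rng_noise.normal(0.0, spec.noise_sd,
                                             (cfg.n_rows, cfg.n_cols))
                layers[(y, spec.name)] = RasterLayer(grid, v.ravel())
    return PredictorStack(grid, cfg.years, [s.name for s in cfg.predictors], layers)


def true_suitability(sp: VirtualSpecies, stack: PredictorStack, year) -> RasterLayer:
    """True suitability S*(cell) = exp(-sum_p (v_p - mu_p)^2 / (2 sigma_p^2))."""
    grid = stack.grid
    vid = grid.valid_cell_ids()
    expo = np.zeros(vid.size)
    for p, mu in sp.mu.items():
        v = stack.layers[(year, p)].values[vid]
        expo += (v - mu) ** 2 / (2.0 * sp.sigma[p] ** 2)
    return RasterLayer.from_valid(grid, np.exp(-expo))


def pooled_mean_suitability(sp: VirtualSpecies, stack: PredictorStack) -> RasterLayer:
    """Suitability of the time-averaged predictors (presence-sampling reference)."""
    grid = stack.grid
    vid = grid.valid_cell_ids()
    expo = np.zeros(vid.size)
    for p, mu in sp.mu.items():
        v = np.mean([stack.layers[(y, p)].values[vid] for y in stack.years], axis=0)
        expo += (v - mu) ** 2 / (2.0 * sp.sigma[p] ** 2)
    return RasterLayer.from_valid(grid, np.exp(-expo))


def sample_presences(sp: VirtualSpecies, stack: PredictorStack,
                     reference="pooled-mean", rng=None, seed: int = 0) -> OccurrenceSet:
    """Draw presence cells without replacement, proportionally to suitability.

    ``reference`` is either ``"pooled-mean"`` (suitability of the
    time-averaged predictors, the default) or a specific year.
    """
    if rng is None:
        rng = _substream(seed, "presences", sp.species_id)
    if reference == "pooled-mean":
        suit = pooled_mean_suitability(sp, stack)
    else:
        suit = true_suitability(sp, stack, reference)
    vid = stack.grid.valid_cell_ids()
    s = suit.values[vid]
    if (s > 0).sum() < sp.n_presences:
        raise ValueError(
            f"{sp.species_id}: only {(s > 0).sum()} cells with positive "
            f"suitability, cannot place {sp.n_presences} presences")
    p = s / s.sum()
    cells = rng.choice(vid, size=sp.n_presences, replace=False, p=p)
    return OccurrenceSet(species_id=sp.species_id,
                         cells=set(int(c) for c in cells),
                         traits=dict(sp.traits),
                         status_regional=sp.status_regional,
                         status_european=sp.status_european)


def _ols_slopes(series: np.ndarray) -> np.ndarray:
    """Column-wise OLS slope of values on time offsets 0..T-1."""
    T = series.shape[0]
    t = np.arange(T, dtype=float)
    tc = t - t.mean()
    return tc @ (series - series.mean(axis=0)) / (tc @ tc)


def true_trend_sign(sp: VirtualSpecies, cfg: SimulationConfig,
                    zero_tol: float = 1e-12) -> RasterLayer:
    """Sign of the OLS slope of the noise-free true-suitability series.

    Values in {-1, 0, +1} per valid cell; the ground truth against which
    recovered Sen-slope signs are scored.
    """
    det = simulate_predictors(cfg, noise=False)
    vid = det.grid.valid_cell_ids()
    S = np.stack([true_suitability(sp, det, y).values[vid] for y in det.years])
    slope = _ols_slopes(S)
    sign = np.where(slope > zero_tol, 1.0, np.where(slope < -zero_tol, -1.0, 0.0))
    return RasterLayer.from_valid(det.grid, sign)


# ---------------------------------------------------------------------------
# Virtual community construction
# ---------------------------------------------------------------------------

def _band_mean(cfg: SimulationConfig, det_stack: PredictorStack,
               predictor: str, bands, n_bands: int) -> float:
    """Mean first-year value of a predictor over a set of column bands."""
    reg = _region_of_cols(cfg.n_cols, n_bands)
    cols = np.arange(cfg.n_cols)[np.isin(reg, bands)]
    V = det_stack.layers[(cfg.years[0], predictor)].as_2d()
    return float(V[:, cols].mean())


def make_virtual_community(cfg: SimulationConfig,
                           trending_predictor: str = "evi",
                           locator_predictor: str = "grad"):
    """Build the default virtual species set with engineered trend cohorts.

    All species have a tight Gaussian response (width 0.5) centred at the
    global mean of the trending predictor, plus a response to the static
    west-east gradient (width 0.3) that localizes them: "declining"
    species occupy the two degrading bands, where predictor values drift
    away from the niche centre, and "improving" species the two
    recovering bands, where values drift toward it.  Because each cohort
    straddles a band pair with opposite drifts, the environmental
    distribution of its presence sample stays stationary over the years,
    which keeps the annually refit niche anchored.  Each group of five
    holds three declining and two improving species.  Traits are drawn
    reproducibly at random, except that the habitat label marks the
    declining cohort so group-level contrasts are recoverable.
    """
    det = simulate_predictors(cfg, noise=False)
    spec = next(s for s in cfg.predictors if s.name == trending_predictor)
    n_bands = len(spec.region_trends)

    mu_grad = {
        "declining": _band_mean(cfg, det, locator_predictor, (0, 1), n_bands),
        "improving": _band_mean(cfg, det, locator_predictor, (3, 4), n_bands),
    }
    cohorts = ("declining", "declining", "declining", "improving", "improving")
    habitat_by_cohort = {"declining": "regressing-specialist"}
    species = []
    for i in range(cfg.n_species):
        group = GROUPS[(i // 5) % len(GROUPS)]
        cohort = cohorts[i % 5]
        rng = _substream(cfg.rng_seed, "species", i)
        mu_primary = spec.base_mean + float(rng.normal(0.0, 0.1))
        mu_secondary = mu_grad[cohort] + float(rng.normal(0.0, 0.05))
        trng = _substream(cfg.rng_seed, "traits", i)
        traits = {
            "group": group,
            "diet": str(trng.choice(DIETS)),
            "habitat": habitat_by_cohort.get(cohort, str(trng.choice(HABITATS))),
            "climate_affinity": str(trng.choice(CLIMATE)),
            "activity": str(trng.choice(ACTIVITY)),
            "feeding": str(trng.choice(FEEDING)),
            "photosynthesis": str(trng.choice(PHOTOSYNTHESIS)),
            "reproduction": str(trng.choice(REPRODUCTION)),
        }
        species.append(VirtualSpecies(
            species_id=f"sp{i:03d}",
            mu={trending_predictor: mu_primary, locator_predictor: mu_secondary},
            sigma={trending_predictor: 0.5, locator_predictor: 0.2},
            n_presences=cfg.n_presences,
            traits=traits,
            status_regional=str(trng.choice(STATUSES)),
            status_european=str(trng.choice(STATUSES)),
            cohort=cohort,
        ))
    return species


@dataclass
class SimulationResult:
    cfg: SimulationConfig
    stack: PredictorStack
    species: list
    occurrences: list                # OccurrenceSet per species
    truth_signs: dict                # species_id -> RasterLayer in {-1,0,+1}


def simulate_dataset(cfg: SimulationConfig | None = None) -> SimulationResult:
    """Generate the full synthetic study: predictors, species, presences,
    and ground-truth trend-sign rasters."""
    cfg = cfg if cfg is not None else SimulationConfig()
    stack = simulate_predictors(cfg)
    species = make_virtual_community(cfg)
    occurrences = [sample_presences(sp, stack, seed=cfg.rng_seed) for sp in species]
    truth = {sp.species_id: true_trend_sign(sp, cfg) for sp in species}
    return SimulationResult(cfg, stack, species, occurrences, truth)


def write_simulation(result: SimulationResult, out_dir: str) -> None:
    """Write predictors, occurrences, traits and a ground-truth sidecar."""
    os.makedirs(out_dir, exist_ok=True)
    write_raster_stack(result.stack, os.path.join(out_dir, "stack"))
    grid = result.stack.grid
    write_occurrences(result.occurrences, grid,
                      os.path.join(out_dir, "occurrences.csv"))
    rows = []
    for sp in result.species:
        row = {"species_id": sp.species_id}
        row.update(sp.traits)
        row["status_regional"] = sp.status_regional
        row["status_european"] = sp.status_european
        rows.append(row)
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "traits.csv"), index=False)
    truth_dir = os.path.join(out_dir, "truth")
    os.makedirs(truth_dir, exist_ok=True)
    sidecar = {}
    for sp in result.species:
        layer = result.truth_signs[sp.species_id]
        fn = f"sign_{sp.species_id}.asc"
        write_ascii_grid(layer, os.path.join(truth_dir, fn))
        sidecar[sp.species_id] = {
            "cohort": sp.cohort,
            "mu": sp.mu,
            "sigma": sp.sigma,
            "sign_raster": fn,
        }
    with open(os.path.join(truth_dir, "truth.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
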
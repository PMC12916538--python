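"""Presence/background maximum-entropy habitat-suitability modelling.

The model estimates the distribution q over background cells that has
maximum entropy subject to (L1-regularized) constraints tying the expected
features under q to their empirical means at the presence cells.
Equivalently, it fits a Gibbs distribution q(cell) ∝ exp(λ·f(cell)) by
maximizing the penalized log-likelihood

    L(λ) = mean_presence[λ·f] − log Σ_background exp(λ·f) − Σ_j β_j |λ_j|

which is concave in λ.  Features are standardized linear and quadratic
terms of the continuous predictors (binary predictors enter linearly);
β_j = β_multiplier · s_j/√m with s_j the feature's standard deviation over
the m presences, floored at a small ε.  Suitability is reported on the
logistic scale s = c·r/(1+c·r) with r the background-relative raw rate
q·|B| and c = e^H (H = entropy of q), so an average-background cell scores
near 0.5 for a typical model.

This is a deliberately simplified re-implementation of the MaxEnt family:
linear+quadratic features only, a single β rule, logistic output.  All
knobs are exposed; the deviations from the canonical defaults are
documented in the README.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .grid import Grid, RasterLayer, PredictorStack, OccurrenceSet

BETA_SD_FLOOR = 1e-6


def _is_binary(stack: PredictorStack, predictor: str) -> bool:
    vid = stack.grid.valid_cell_ids()
    for y in stack.years:
        v = stack.layers[(y, predictor)].values[vid]
        if not np.isin(v, (0.0, 1.0)).all():
            return False
    return True


@dataclass
class FeatureSet:
    """Feature mapping for one year, calibrated on the background sample.

    Standardization parameters (mean/sd per continuous predictor) and the
    clamp range of every feature come from the background only, so models
    can be projected to cells outside the training region with features
    clamped to the environmental range the model has seen.
    """

    grid: Grid
    feature_names: list
    predictor_values: dict            # predictor -> per-cell values (full grid)
    recipes: list                     # (kind, predictor) with kind in lin/quad/bin
    standardize: dict                 # predictor -> (mean, sd) on background
    clamp_lo: np.ndarray
    clamp_hi: np.ndarray
    excluded: list = field(default_factory=list)  # degenerate features

    @property
    def n_features(self) -> int:
        return len(self.recipes)

    def matrix(self, cells, clamp: bool = False) -> np.ndarray:
        """Feature matrix for the given cell ids, shape (len(cells), n_features).

        Large requests (the background / full grid, reused across fits)
        are memoized.
        """
        cells = np.asarray(cells, dtype=int)
        key = None
        if cells.size >= 256:
            if not hasattr(self, "_cache"):
                object.__setattr__(self, "_cache", {})
            key = (hash(cells.tobytes()), clamp)
            if key in self._cache:
                return self._cache[key]
        F = np.empty((cells.size, self.n_features))
        for k, (kind, pred) in enumerate(self.recipes):
            v = self.predictor_values[pred][cells]
            if kind == "bin":
                F[:, k] = v
            else:
                mu, sd = self.standardize[pred]
                z = (v - mu) / sd
                F[:, k] = z if kind == "lin" else z * z
        if clamp:
            np.clip(F, self.clamp_lo, self.clamp_hi, out=F)
        if key is not None:
            self._cache[key] = F
        return F


def build_features(stack: PredictorStack, year, background) -> FeatureSet:
    """Build the standardized linear+quadratic feature set for one year.

    Zero-variance features (on the background) are excluded and flagged;
    if nothing informative remains the year is unusable and a hard error
    is raised.
    """
    background = np.asarray(background, dtype=int)
    if background.size == 0:
        raise ValueError("background must be non-empty")
    predictor_values = {}
    recipes, names, excluded = [], [], []
    standardize = {}
    for p in stack.predictor_names:
        vals = stack.layers[(year, p)].values
        predictor_values[p] = vals
        bg = vals[background]
        if _is_binary(stack, p):
            if np.std(bg) == 0:
                excluded.append(f"{p}:bin")
                continue
            recipes.append(("bin", p))
            names.append(f"{p}:bin")
        else:
            mu, sd = float(np.mean(bg)), float(np.std(bg))
            if sd == 0:
                excluded.append(f"{p}:lin")
                excluded.append(f"{p}:quad")
                continue
            standardize[p] = (mu, sd)
            recipes.append(("lin", p))
            names.append(f"{p}:lin")
            recipes.append(("quad", p))
            names.append(f"{p}:quad")
    if not recipes:
        raise ValueError(f"uninformative year {year}: all features degenerate")
    fs = FeatureSet(stack.grid, names, predictor_values, recipes, standardize,
                    clamp_lo=np.empty(0), clamp_hi=np.empty(0), excluded=excluded)
    Fbg = fs.matrix(background)
    fs.clamp_lo = Fbg.min(axis=0)
    fs.clamp_hi = Fbg.max(axis=0)
    return fs


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model for one (species, year, replicate)."""

    features: FeatureSet
    lam: np.ndarray
    beta: np.ndarray
    background: np.ndarray
    log_z: float            # log Σ_background exp(λ·f)
    entropy: float          # H of the fitted q over background
    converged: bool
    objective_path: list = field(default_factory=list)
    year: int = 0
    replicate: int = 0

    def raw_distribution(self) -> np.ndarray:
        """q over the background cells (sums to 1)."""
        eta = self.features.matrix(self.background) @ self.lam
        return np.exp(eta - logsumexp(eta))


def fit_maxent(features: FeatureSet, presences, background,
               beta_multiplier: float = 1.0, tol: float = 1e-9,
               max_iter: int = 1000, record_path: bool = False) -> MaxentModel:
    """Maximize the L1-penalized MaxEnt log-likelihood.

    The non-smooth |λ_j| penalty is handled exactly by splitting
    λ = u − w with u, w ≥ 0, giving a smooth bound-constrained concave
    problem solved with L-BFGS-B.  Deterministic given its inputs; if the
    iteration budget is exhausted the best iterate is returned with
    ``converged=False``.
    """
    presences = np.asarray(presences, dtype=int)
    background = np.asarray(background, dtype=int)
    if presences.size < 2:
        raise ValueError("fit_maxent needs at least 2 presences")
    Fp = features.matrix(presences)
    Fb = features.matrix(background)
    m = presences.shape[0]
    s = Fp.std(axis=0)
    beta = beta_multiplier * np.maximum(s, BETA_SD_FLOOR) / np.sqrt(m)
    fbar = Fp.mean(axis=0)
    k = features.n_features

    path = []

    def negobj(uw):
        lam = uw[:k] - uw[k:]
        eta = Fb @ lam
        lz = logsumexp(eta)
        q = np.exp(eta - lz)
        nll = -(fbar @ lam) + lz + beta @ (uw[:k] + uw[k:])
        g_lam = -fbar + q @ Fb
        grad = np.concatenate([g_lam + beta, -g_lam + beta])
        return nll, grad

    x0 = np.zeros(2 * k)
    res = minimize(
        negobj, x0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * k),
        callback=(lambda xk: path.append(-negobj(xk)[0])) if record_path else None,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-6},
    )
    uw = res.x
    lam = uw[:k] - uw[k:]
    eta = Fb @ lam
    lz = float(logsumexp(eta))
    q = np.exp(eta - lz)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = float(-(q * np.where(q > 0, np.log(q), 0.0)).sum())
    return MaxentModel(features=features, lam=lam, beta=beta,
                       background=background, log_z=lz, entropy=H,
                       converged=bool(res.success or res.status == 0),
                       objective_path=path)


def predict_suitability(model: MaxentModel, features: FeatureSet | None = None,
                        cells=None) -> RasterLayer:
    """Logistic-scale suitability for the requested cells (default: all valid).

    s = c·r/(1+c·r) with r = q·|B| (the cell's raw rate relative to a
    uniform background) and c = e^H; features are clamped to the
    background range before scoring, so projection outside the training
    region is well-defined.
    """
    fs = features if features is not None else model.features
    if cells is None:
        cells = fs.grid.valid_cell_ids()
    cells = np.asarray(cells, dtype=int)
    eta = fs.matrix(cells, clamp=True) @ model.lam
    # c·r with c = e^(H - log|B|) and r = q·|B| — equivalently e^H·q:
    # a uniform model (H = log|B|, q = 1/|B|) scores exactly 1/2 everywhere
    log_cr = model.entropy + eta - model.log_z
    s = np.where(log_cr > 30, 1.0,
                 np.exp(np.minimum(log_cr, 30))
                 / (1.0 + np.exp(np.minimum(log_cr, 30))))
    out = np.full(fs.grid.n_cells, np.nan)
    out[cells] = s
    layer_vals = np.where(np.isnan(out), -9999.0, out)
    grid = fs.grid
    mask = np.zeros(grid.n_cells, dtype=bool)
    mask[cells] = True
    sub = Grid(grid.n_rows, grid.n_cols, grid.origin_x, grid.origin_y,
               grid.cell_size, mask & grid.valid_mask.ravel())
    return RasterLayer(sub, layer_vals, nodata=-9999.0)


def auc_rank(pres_scores, bg_scores) -> float:
    """Mann-Whitney AUC: P(presence score > background score), ties 0.5."""
    p = np.asarray(pres_scores, dtype=float)
    b = np.sort(np.asarray(bg_scores, dtype=float))
    if p.size == 0 or b.size == 0:
        raise ValueError("auc_rank needs non-empty score sets")
    less = np.searchsorted(b, p, side="left")
    upto = np.searchsorted(b, p, side="right")
    wins = less.sum() + 0.5 * (upto - less).sum()
    return float(wins / (p.size * b.size))


@dataclass
class ReplicateResult:
    model: MaxentModel
    train_cells: np.ndarray
    test_cells: np.ndarray
    auc_train: float
    auc_test: float
    suitability: RasterLayer


@dataclass
class HsiSeries:
    """Annual habitat-suitability stack for one species (replicate mean)."""

    species_id: str
    grid: Grid
    years: list
    hsi: dict                      # year -> RasterLayer in [0,1]
    auc_table: list = field(default_factory=list)  # (year, rep, auc_train, auc_test)

    def mean_auc(self):
        a = np.array([[r[2], r[3]] for r in self.auc_table])
        return float(a[:, 0].mean()), float(a[:, 1].mean())


def species_substream(seed: int, species_id: str, year: int, replicate: int):
    """Named, order-independent RNG substream for one replicate."""
    tag = zlib.crc32(str(species_id).encode())
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag, int(year), replicate])
    )


def train_test_split_size(n: int, train_frac: float = 0.7) -> int:
    """Training-set size: round-half-up of train_frac·n."""
    return int(np.floor(train_frac * n + 0.5))


def run_species_year(sp: OccurrenceSet, stack: PredictorStack, year,
                     n_replicates: int = 10, train_frac: float = 0.7,
                     seed: int = 0, background=None, features: FeatureSet | None = None,
                     beta_multiplier: float = 1.0):
    """Fit and evaluate the replicate models for one species and year.

    Each replicate shuffles the presence cells with its own substream,
    splits 70/30 (round-half-up on the training side), fits on the
    training cells against the full background (all valid-cell centroids
    of the training region), and scores train and test AUC against the
    background.  Returns a list of :class:`ReplicateResult`.
    """
    presences = sp.sorted_cells()
    n = presences.size
    n_train = train_test_split_size(n, train_frac)
    if n_train >= n or n_train < 2:
        raise ValueError(f"cannot split {n} presences into non-empty train/test")
    if background is None:
        background = stack.grid.valid_cell_ids()
    background = np.asarray(background, dtype=int)
    if features is None:
        features = build_features(stack, year, background)

    results = []
    for rep in range(n_replicates):
        rng = species_substream(seed, sp.species_id, year, rep)
        perm = rng.permutation(n)
        train = presences[perm[:n_train]]
        test = presences[perm[n_train:]]
        model = fit_maxent(features, train, background,
                           beta_multiplier=beta_multiplier)
        model.year = int(year)
        model.replicate = rep
        suit = predict_suitability(model, features)
        bg_scores = suit.values[background]
        auc_tr = auc_rank(suit.values[train], bg_scores)
        auc_te = auc_rank(suit.values[test], bg_scores)
        results.append(ReplicateResult(model, train, test, auc_tr, auc_te, suit))
    return results


def hsi_series(sp: OccurrenceSet, stack: PredictorStack, years=None,
               n_replicates: int = 10, train_frac: float = 0.7, seed: int = 0,
               background=None, beta_multiplier: float = 1.0) -> HsiSeries:
    """Annual HSI stack: cellwise mean of the replicate suitability rasters."""
    years = list(stack.years if years is None else years)
    if background is None:
        background = stack.grid.valid_cell_ids()
    hsi = {}
    auc_table = []
    for y in years:
        reps = run_species_year(sp, stack, y, n_replicates=n_replicates,
                                train_frac=train_frac, seed=seed,
                                background=background,
                                beta_multiplier=beta_multiplier)
        vals = np.mean([r.suitability.values for r in reps], axis=0)
        vid = stack.grid.valid_cell_ids()
        layer = np.full(stack.grid.n_cells, -9999.0)
        layer[vid] = np.clip(vals[vid], 0.0, 1.0)
        hsi[y] = RasterLayer(stack.grid, layer, nodata=-9999.0)
        for r in reps:
            auc_table.append((y, r.model.replicate, r.auc_train, r.auc_test))
    return HsiSeries(sp.species_id, stack.grid, years, hsi, auc_table)
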
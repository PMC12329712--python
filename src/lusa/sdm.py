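"""Per-species logistic habitat modelling.

The chain mirrors common presence/pseudo-absence SDM practice: occurrence
cleaning with one-record-per-cell thinning, random pseudo-absences outside
the expert range mask (default 1000 per species), correlation pruning of the
ten environmental predictors, exhaustive AIC subset selection of a weighted
logistic regression (classes balanced by per-point weights
``w = N / (2 N_class)``), a TSS-optimal probability threshold, five-fold
stratified cross-validation for retention (mean AUC > 0.5 and mean
max-TSS > 0), expert-range clipping of projections, richness stacking, and
the mean relative range-change statistic.

Model fitting is delegated to statsmodels (binomial GLM with variance
weights); AUC, TSS and threshold search are implemented here against their
rank/confusion-matrix definitions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .grids import GridGeometry
from .synthetic import ENV_LAYERS, EnvStack


class SeparationWarning(UserWarning):
    """Perfect or quasi-perfect separation in a logistic fit."""


@dataclass
class SpeciesDataset:
    """Design matrix, labels and balanced weights for one species."""

    species_id: str
    X: pd.DataFrame
    y: np.ndarray
    weights: np.ndarray
    range_mask: np.ndarray | None = None
    presences: pd.DataFrame | None = None
    pseudo_absences: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if set(np.unique(self.y)) - {0, 1}:
            raise ValueError("labels must be 0/1")
        if (self.weights <= 0).any():
            raise ValueError("weights must be > 0")


@dataclass
class LogisticFit:
    """Weighted logistic regression result."""

    predictors: list[str]
    params: pd.Series  # includes "const"
    bse: pd.Series
    llf: float
    aic: float
    converged: bool
    separation: bool = False

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.params["const"])
        for name in self.predictors:
            eta = eta + self.params[name] * X[name].to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class CVResult:
    auc_mean: float
    tss_mean: float
    fold_auc: list[float]
    fold_tss: list[float]

    @property
    def retained(self) -> bool:
        return self.auc_mean > 0.5 and self.tss_mean > 0.0


@dataclass
class SDModel:
    """Fitted, thresholded habitat model for one species."""

    species_id: str
    selected_predictors: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    threshold: float
    cv_auc_mean: float
    cv_tss_mean: float
    retained: bool
    seed: int | None = None
    fit: LogisticFit | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "species_id": self.species_id,
            "selected_predictors": list(self.selected_predictors),
            "coefficients": dict(self.coefficients),
            "threshold": self.threshold,
            "cv_auc_mean": self.cv_auc_mean,
            "cv_tss_mean": self.cv_tss_mean,
            "retained": self.retained,
            "seed": self.seed,
        }


@dataclass
class RichnessMap:
    counts: np.ndarray
    year: int
    scenario: str
    geometry: GridGeometry


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


def clean_occurrences(records: pd.DataFrame, geometry: GridGeometry) -> pd.DataFrame:
    """Drop invalid/out-of-bounds coordinates and thin to one record per cell.

    Deterministic: the first record (input order) in each occupied cell is
    kept.  May return an empty frame.
    """
    rec = records.copy()
    ok = np.isfinite(rec["x"].to_numpy(float)) & np.isfinite(rec["y"].to_numpy(float))
    rec = rec.loc[ok]
    inside = geometry.contains(rec["x"].to_numpy(), rec["y"].to_numpy())
    rec = rec.loc[inside]
    if rec.empty:
        return rec.reset_index(drop=True)
    row, col = geometry.cell_of(rec["x"].to_numpy(), rec["y"].to_numpy())
    cell = row * geometry.shape[1] + col
    keep = ~pd.Series(cell, index=rec.index).duplicated()
    return rec.loc[keep].reset_index(drop=True)


def sample_pseudo_absences(
    range_mask: np.ndarray,
    geometry: GridGeometry,
    n: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample n pseudo-absence points uniformly over cells outside the range.

    The expert range mask demarcates suitable area; its complement is the
    sampling frame.  Reproducible given the seed.
    """
    unsuitable = np.flatnonzero(~np.asarray(range_mask, dtype=bool).ravel())
    if unsuitable.size == 0:
        raise ValueError("unsuitable area is empty; cannot sample pseudo-absences")
    rng = np.random.default_rng(seed)
    cells = rng.choice(unsuitable, size=n)
    rows, cols = np.divmod(cells, range_mask.shape[1])
    x, y = geometry.cell_center(rows, cols)
    jitter = geometry.cell_size * 0.45
    x = x + rng.uniform(-jitter, jitter, size=n)
    y = y + rng.uniform(-jitter, jitter, size=n)
    return pd.DataFrame({"x": x, "y": y})


def balanced_weights(y: np.ndarray) -> np.ndarray:
    """Per-point weights equalising total presence and absence weight:
    ``w = N / (2 N_class)``."""
    y = np.asarray(y)
    n = y.size
    n1 = int(y.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    w = np.where(y == 1, n / (2.0 * n1), n / (2.0 * n0))
    return w


def build_species_dataset(
    species_id: str,
    presences: pd.DataFrame,
    range_mask: np.ndarray,
    env: EnvStack,
    n_absences: int = 1000,
    seed: int | None = None,
) -> SpeciesDataset:
    """Assemble the fitting dataset: thin presences, sample pseudo-absences,
    extract the ten predictors at every point, and balance class weights."""
    pres = clean_occurrences(presences, env.geometry)
    absn = sample_pseudo_absences(range_mask, env.geometry, n=n_absences, seed=seed)
    pts_x = np.concatenate([pres["x"].to_numpy(), absn["x"].to_numpy()])
    pts_y = np.concatenate([pres["y"].to_numpy(), absn["y"].to_numpy()])
    X = pd.DataFrame(env.values_at(pts_x, pts_y), columns=list(ENV_LAYERS))
    y = np.concatenate([np.ones(len(pres), int), np.zeros(len(absn), int)])
    return SpeciesDataset(
        species_id=species_id,
        X=X,
        y=y,
        weights=balanced_weights(y),
        range_mask=np.asarray(range_mask, dtype=bool),
        presences=pres,
        pseudo_absences=absn,
    )


# ---------------------------------------------------------------------------
# predictor pruning, fitting, selection
# ---------------------------------------------------------------------------


def prune_correlated(X: pd.DataFrame, threshold: float = 0.7) -> list[str]:
    """Retain predictors with no pairwise |Pearson r| >= threshold.

    Constant predictors are dropped with a warning.  Among a violating pair,
    the member with the larger mean |r| against the other retained
    predictors is dropped; ties go to the later column.  Deterministic.
    """
    cols = list(X.columns)
    const = [c for c in cols if np.isclose(X[c].std(ddof=0), 0.0)]
    if const:
        warnings.warn(f"dropping constant predictors: {const}", UserWarning,
                      stacklevel=2)
        cols = [c for c in cols if c not in const]
    if len(cols) < 2:
        return cols
    corr = X[cols].corr().abs()
    retained = list(cols)
    while True:
        sub = corr.loc[retained, retained].to_numpy()
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] < threshold:
            break
        mean_r = sub.mean(axis=0)
        # drop the member of the worst pair with larger mean correlation;
        # tie -> the later predictor in column order
        if mean_r[i] > mean_r[j]:
            drop = i
        elif mean_r[j] > mean_r[i]:
            drop = j
        else:
            drop = max(i, j)
        retained.pop(drop)
        if len(retained) < 2:
            break
    return retained


def fit_weighted_logistic(
    X: pd.DataFrame,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    predictors: list[str] | None = None,
) -> LogisticFit:
    """Weighted Bernoulli MLE with logit link (statsmodels binomial GLM).

    Perfect separation is flagged (coefficients still returned with a
    :class:`SeparationWarning`); non-convergence raises.
    """
    predictors = list(predictors if predictors is not None else X.columns)
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    design = sm.add_constant(X[predictors].to_numpy(), has_constant="add")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, design, family=sm.families.Binomial(), var_weights=w)
        res = model.fit(maxiter=200, tol=1e-10)
        for wmsg in caught:
            if "separat" in str(wmsg.message).lower():
                separation = True
    if not separation and np.abs(res.params).max() > 1e3:
        separation = True
    if separation:
        warnings.warn(
            f"perfect separation detected ({predictors})", SeparationWarning,
            stacklevel=2,
        )
    if not res.converged and not separation:
        raise RuntimeError("logistic fit did not converge")
    names = ["const"] + predictors
    params = pd.Series(res.params, index=names)
    bse = pd.Series(res.bse, index=names)
    k = len(names)
    return LogisticFit(
        predictors=predictors,
        params=params,
        bse=bse,
        llf=float(res.llf),
        aic=float(2 * k - 2 * res.llf),
        converged=bool(res.converged),
        separation=separation,
    )


def weighted_log_likelihood(
    params: dict[str, float], X: pd.DataFrame, y: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Weighted Bernoulli log-likelihood of arbitrary coefficients."""
    w = np.ones(len(X)) if weights is None else np.asarray(weights, float)
    eta = np.full(len(X), params.get("intercept", params.get("const", 0.0)))
    for name, beta in params.items():
        if name not in ("intercept", "const"):
            eta = eta + beta * X[name].to_numpy()
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    y = np.asarray(y, float)
    return float(np.sum(w * (y * np.log(p) + (1 - y) * np.log1p(-p))))


def select_by_aic(
    X: pd.DataFrame,
    y: np.ndarray,
    weights: np.ndarray | None,
    candidates: list[str],
) -> tuple[list[str], LogisticFit]:
    """Exhaustive AIC search over all non-empty predictor subsets.

    AIC = 2k - 2 ln L with k counting the intercept.  Ties resolve to the
    smaller subset, then lexicographic candidate order (guaranteed by the
    enumeration order).
    """
    if not candidates:
        raise ValueError("no candidate predictors")
    if len(candidates) > 10:
        raise ValueError("exhaustive search limited to 10 candidates")
    best: tuple[list[str], LogisticFit] | None = None
    n_failed = 0
    for size in range(1, len(candidates) + 1):
        for subset in itertools.combinations(range(len(candidates)), size):
            preds = [candidates[i] for i in subset]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", SeparationWarning)
                    fit = fit_weighted_logistic(X, y, weights, predictors=preds)
            except Exception:
                n_failed += 1
                continue
            if best is None or fit.aic < best[1].aic - 1e-9:
                best = (preds, fit)
    if best is None:
        raise RuntimeError(f"all {n_failed} candidate fits failed")
    return best


# ---------------------------------------------------------------------------
# skill statistics and thresholding
# ---------------------------------------------------------------------------


def tss(tp: float, fn: float, tn: float, fp: float) -> float:
    """True Skill Statistic: sensitivity + specificity - 1, in [-1, 1]."""
    if tp + fn <= 0 or tn + fp <= 0:
        raise ValueError("TSS needs at least one presence and one absence")
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(random presence outscores random absence), ties 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _tss_curve(scores: np.ndarray, labels: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = labels.sum()
    n0 = labels.size - n1
    pred = scores[None, :] >= thresholds[:, None]
    tp = (pred & (labels == 1)).sum(axis=1)
    fp = (pred & (labels == 0)).sum(axis=1)
    return tp / n1 + (n0 - fp) / n0 - 1.0


def optimize_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """TSS-maximising probability threshold.

    Candidates are every distinct score plus 0 and 1; prediction is
    ``score >= threshold``.  Returns ``(threshold, tss_at_threshold)``; ties
    resolve to the smallest threshold.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    cand = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    curve = _tss_curve(scores, labels, cand)
    best = curve.max()
    thr = float(cand[np.flatnonzero(curve >= best - 1e-12)[0]])
    return thr, float(best)


# ---------------------------------------------------------------------------
# cross-validation and model assembly
# ---------------------------------------------------------------------------


def cross_validate(
    X: pd.DataFrame,
    y: np.ndarray,
    predictors: list[str],
    k: int = 5,
    seed: int | None = None,
) -> CVResult:
    """Stratified k-fold CV of a weighted logistic model.

    Per fold: fit on the training folds (per-fold balanced weights), score
    the held-out fold with AUC and the maximum TSS over thresholds.
    """
    y = np.asarray(y, int)
    if min(int(y.sum()), int((1 - y).sum())) < k:
        raise ValueError(f"need at least {k} records of each class for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_auc, fold_tss = [], []
    for train, test in skf.split(X, y):
        w = balanced_weights(y[train])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparationWarning)
            fit = fit_weighted_logistic(X.iloc[train], y[train], w, predictors=predictors)
        scores = fit.predict(X.iloc[test])
        fold_auc.append(auc(scores, y[test]))
        fold_tss.append(optimize_threshold(scores, y[test])[1])
    return CVResult(
        auc_mean=float(np.mean(fold_auc)),
        tss_mean=float(np.mean(fold_tss)),
        fold_auc=fold_auc,
        fold_tss=fold_tss,
    )


def fit_species_model(
    dataset: SpeciesDataset,
    corr_threshold: float = 0.7,
    cv_folds: int = 5,
    seed: int | None = None,
) -> SDModel:
    """Full per-species chain: prune, AIC-select, threshold, cross-validate.

    The TSS threshold is fitted on the full dataset after CV; CV supplies
    retention metrics only.
    """
    candidates = prune_correlated(dataset.X, threshold=corr_threshold)
    predictors, fit = select_by_aic(dataset.X, dataset.y, dataset.weights, candidates)
    scores = fit.predict(dataset.X)
    threshold, _ = optimize_threshold(scores, dataset.y)
    cv = cross_validate(dataset.X, dataset.y, predictors, k=cv_folds, seed=seed)
    coeffs = {"intercept": float(fit.params["const"])}
    coeffs.update({p: float(fit.params[p]) for p in predictors})
    return SDModel(
        species_id=dataset.species_id,
        selected_predictors=predictors,
        coefficients=coeffs,
        threshold=threshold,
        cv_auc_mean=cv.auc_mean,
        cv_tss_mean=cv.tss_mean,
        retained=cv.retained,
        seed=seed,
        fit=fit,
    )


# ---------------------------------------------------------------------------
# projection, richness, range change
# ---------------------------------------------------------------------------


def suitability_map(model: SDModel, env: EnvStack) -> np.ndarray:
    """Predicted occurrence probability per cell."""
    eta = np.full(env.geometry.shape, model.coefficients["intercept"])
    for name in model.selected_predictors:
        eta = eta + model.coefficients[name] * env.layers[name]
    return 1.0 / (1.0 + np.exp(-eta))


def project_range(model: SDModel, env: EnvStack, range_mask: np.ndarray) -> np.ndarray:
    """Boolean distribution: probability >= threshold, clipped to the expert
    range mask."""
    range_mask = np.asarray(range_mask, dtype=bool)
    if range_mask.shape != env.geometry.shape:
        raise ValueError("range mask shape mismatch")
    return (suitability_map(model, env) >= model.threshold) & range_mask


def stack_richness(
    distributions: dict[str, np.ndarray],
    geometry: GridGeometry,
    year: int,
    scenario: str = "",
) -> RichnessMap:
    """Species count per grid cell."""
    counts = np.zeros(geometry.shape, dtype=int)
    for sp, dist in distributions.items():
        if dist.shape != geometry.shape:
            raise ValueError(f"distribution for {sp!r} has wrong shape")
        counts += dist.astype(int)
    return RichnessMap(counts=counts, year=year, scenario=scenario, geometry=geometry)


def mean_range_change(
    distributions_t: dict[str, np.ndarray],
    distributions_base: dict[str, np.ndarray],
) -> float:
    """Mean over species of the relative distribution-area change, percent.

    Species with zero baseline area are excluded with a warning.
    """
    if set(distributions_t) != set(distributions_base):
        raise ValueError("species sets differ between timesteps")
    changes = []
    for sp in distributions_base:
        a0 = float(np.asarray(distributions_base[sp], bool).sum())
        a1 = float(np.asarray(distributions_t[sp], bool).sum())
        if a0 == 0:
            warnings.warn(f"species {sp!r} has zero baseline area; excluded",
                          UserWarning, stacklevel=2)
            continue
        changes.append(100.0 * (a1 - a0) / a0)
    if not changes:
        raise ValueError("no species with positive baseline area")
    return float(np.mean(changes))
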
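"""Ordination and supervised classification of per-sample mutation spectra.

Samples are summarized by their per-animal trinucleotide mutation vectors and
compared with:

* the binomial dissimilarity between count vectors,
  ``d(x, y) = sum_i [x_i ln(x_i/m_i) + y_i ln(y_i/m_i)] / n_i`` with
  ``n_i = x_i + y_i`` and ``m_i = n_i / 2`` (channels with ``n_i = 0`` are
  skipped; ``0 ln 0 = 0``);
* non-metric multidimensional scaling (NMDS), minimizing the stress
  ``sqrt(sum (f(x_i) - d_i)^2 / sum d_i^2)`` where ``d_i`` are configuration
  distances and ``f`` the monotone (isotonic) transform of the observed
  dissimilarities;
* the Mantel permutation test of correlation between two distance matrices;
* a nearest-shrunken-centroid (NSC) classifier with soft-thresholded,
  standardized centroid differences and a Gaussian discriminant giving class
  membership probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)


# ---- distances -------------------------------------------------------------


def binomial_distance(x, y) -> float:
    """Binomial dissimilarity between two nonnegative count vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative entry in count vector")
    n = x + y
    if not n.any():
        raise ValueError("both vectors are all-zero")
    mask = n > 0
    xm, ym, nm = x[mask], y[mask], n[mask]
    m = nm / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        tx = np.where(xm > 0, xm * np.log(xm / m), 0.0)
        ty = np.where(ym > 0, ym * np.log(ym / m), 0.0)
    return float(np.sum((tx + ty) / nm))


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distance")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("nonzero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def pairwise_binomial(counts: pd.DataFrame) -> DistanceMatrix:
    """All-pairs binomial distances between rows (samples) of a count table."""
    labels = list(counts.index)
    X = counts.to_numpy(dtype=float)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = binomial_distance(X[i], X[j])
    return DistanceMatrix(labels=labels, values=d)


# ---- NMDS ------------------------------------------------------------------


@dataclass
class NmdsResult:
    coords: np.ndarray  # samples x k
    fitted: np.ndarray  # monotone-transformed dissimilarities (upper triangle)
    observed: np.ndarray  # observed dissimilarities (upper triangle)
    stress: float
    converged: bool
    n_restarts: int
    seed: int
    labels: list[str] = field(default_factory=list)


def _config_distances(X: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return pdist(X)


def _stress(conf_d: np.ndarray, disparities: np.ndarray) -> float:
    denom = np.sum(conf_d**2)
    if denom == 0:
        return np.inf
    return float(np.sqrt(np.sum((conf_d - disparities) ** 2) / denom))


def _pcoa_init(dist: DistanceMatrix, k: int) -> np.ndarray:
    """Classical (principal-coordinates) scaling as a deterministic start."""
    D2 = dist.values**2
    n = dist.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:k]
    w_top = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(w_top)


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> NmdsResult:
    """Non-metric MDS by alternating isotonic regression and Guttman updates.

    Within each restart the stress sequence is non-increasing (a step that
    would increase stress terminates the restart); the best configuration
    over all restarts is returned.  Restart 1 starts from classical metric
    scaling, the rest from seeded random Gaussian configurations.
    """
    if dist.n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k}")
    delta = dist.upper()
    order = np.argsort(delta, kind="stable")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, bool] | None = None
    n = dist.n
    for restart in range(n_restarts):
        if restart == 0:
            X = _pcoa_init(dist, k)
        else:
            X = rng.normal(size=(n, k))
        prev_stress = np.inf
        disp_vec = None
        converged = False
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        for _ in range(max_iter):
            d = _config_distances(X)
            # monotone transform: isotonic fit of configuration distances
            # on the observed dissimilarity order
            fitted_sorted = iso.fit_transform(delta[order], d[order])
            disp = np.empty_like(d)
            disp[order] = fitted_sorted
            stress = _stress(d, disp)
            if stress > prev_stress + 1e-15:
                break  # guard: keep the non-increasing stress invariant
            disp_vec = disp
            if prev_stress - stress < tol * max(prev_stress, 1e-300) or stress < 1e-12:
                prev_stress = stress
                X_best_iter = X
                converged = True
                break
            prev_stress = stress
            X_best_iter = X
            # Guttman transform with current disparities
            D = np.zeros((n, n))
            iu = np.triu_indices(n, k=1)
            D[iu] = d
            D += D.T
            ratio = np.zeros((n, n))
            Disp = np.zeros((n, n))
            Disp[iu] = disp
            Disp += Disp.T
            nz = D > 0
            ratio[nz] = Disp[nz] / D[nz]
            B = -ratio
            np.fill_diagonal(B, ratio.sum(axis=1))
            X = B @ X / n
        if disp_vec is None:  # first evaluation already degenerate
            d = _config_distances(X)
            fitted_sorted = iso.fit_transform(delta[order], d[order])
            disp_vec = np.empty_like(d)
            disp_vec[order] = fitted_sorted
            prev_stress = _stress(d, disp_vec)
            X_best_iter = X
        if best is None or prev_stress < best[0]:
            best = (prev_stress, X_best_iter.copy(), disp_vec.copy(), converged)
    stress, X, disp, converged = best
    return NmdsResult(
        coords=X,
        fitted=disp,
        observed=delta,
        stress=stress,
        converged=converged,
        n_restarts=n_restarts,
        seed=seed,
        labels=list(dist.labels),
    )


# ---- Mantel test -----------------------------------------------------------


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """One-sided (greater) Mantel test of matrix correlation.

    r is the Pearson correlation of the off-diagonal upper triangles;
    the null distribution permutes the sample labels of ``d2``;
    ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)``.
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels and order")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    x = d1.upper()
    y = d2.upper()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = d1.n
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = d2.values[np.ix_(perm, perm)][np.triu_indices(n, k=1)]
        if np.corrcoef(x, yp)[0, 1] >= r_obs - 1e-12:
            exceed += 1
    return r_obs, (1 + exceed) / (n_perm + 1)


# ---- nearest shrunken centroids --------------------------------------------


@dataclass
class NscModel:
    """Nearest-shrunken-centroid classifier for two-class spectra."""

    classes: list[str]
    channels: list[str]
    centroids: np.ndarray  # classes x channels
    overall_centroid: np.ndarray
    pooled_sd: np.ndarray
    s0: float
    delta: float
    shrunken_d: np.ndarray  # classes x channels
    shrunken_centroids: np.ndarray
    priors: np.ndarray
    cv_errors: pd.DataFrame | None = None

    @property
    def active_channels(self) -> list[str]:
        active = np.any(self.shrunken_d != 0.0, axis=0)
        return [c for c, a in zip(self.channels, active) if a]

    def discriminant(self, X: np.ndarray) -> np.ndarray:
        """Score of each class: squared standardized distance - 2 ln prior."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        s = self.pooled_sd + self.s0
        scores = np.empty((X.shape[0], len(self.classes)))
        for k in range(len(self.classes)):
            z = (X - self.shrunken_centroids[k]) / s
            scores[:, k] = np.sum(z**2, axis=1) - 2.0 * np.log(self.priors[k])
        return scores

    def predict(self, X) -> np.ndarray:
        scores = self.discriminant(X)
        return np.array([self.classes[i] for i in scores.argmin(axis=1)])

    def predict_proba(self, X) -> np.ndarray:
        """Softmax of -score/2 over classes (Gaussian discriminant)."""
        scores = self.discriminant(np.asarray(X, dtype=float))
        z = -scores / 2.0
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


def _shrink(d: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


def _nsc_fit_at_delta(
    X: np.ndarray, y: np.ndarray, classes: list[str], channels: list[str],
    delta: float, priors: np.ndarray,
) -> NscModel:
    n, p = X.shape
    overall = X.mean(axis=0)
    centroids = np.vstack([X[y == c].mean(axis=0) for c in classes])
    nk = np.array([(y == c).sum() for c in classes])
    within_ss = np.zeros(p)
    for k, c in enumerate(classes):
        within_ss += ((X[y == c] - centroids[k]) ** 2).sum(axis=0)
    pooled_sd = np.sqrt(within_ss / (n - len(classes)))
    s0 = float(np.median(pooled_sd))
    mk = np.sqrt(1.0 / nk - 1.0 / n)
    denom = mk[:, None] * (pooled_sd + s0)[None, :]
    d = (centroids - overall) / denom
    d_shr = _shrink(d, delta)
    shrunken_centroids = overall + denom * d_shr
    return NscModel(
        classes=list(classes),
        channels=list(channels),
        centroids=centroids,
        overall_centroid=overall,
        pooled_sd=pooled_sd,
        s0=s0,
        delta=delta,
        shrunken_d=d_shr,
        shrunken_centroids=shrunken_centroids,
        priors=priors,
    )


def nsc_train(
    spectra: pd.DataFrame,
    labels,
    delta_grid: np.ndarray | None = None,
    cv_folds: int = 6,
    seed: int = 0,
    priors: str = "equal",
) -> NscModel:
    """Train an NSC model on per-sample channel percentages.

    ``spectra`` is samples x channels (percent proportions); ``labels`` the
    two class labels per sample.  The shrinkage threshold is chosen from
    ``delta_grid`` (default: 30 even steps from 0 to max |d|) by
    ``cv_folds``-fold stratified cross-validation, ties broken toward the
    largest delta (most parsimonious model).  Fold assignment is
    deterministic given ``seed``.
    """
    X = spectra.to_numpy(dtype=float)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) != 2:
        raise ValueError("nsc_train expects exactly two classes")
    nk = np.array([(y == c).sum() for c in classes])
    if (nk < 2).any():
        raise ValueError("need at least 2 samples per class")
    prior_vec = (
        np.full(2, 0.5) if priors == "equal" else nk / nk.sum()
    )
    if delta_grid is None:
        base = _nsc_fit_at_delta(X, y, classes, list(spectra.columns), 0.0, prior_vec)
        dmax = np.abs((base.centroids - base.overall_centroid) /
                      (np.sqrt(1.0 / nk - 1.0 / len(y))[:, None]
                       * (base.pooled_sd + base.s0)[None, :])).max()
        delta_grid = np.linspace(0.0, dmax, 30)
    folds = min(cv_folds, int(nk.min()))
    if folds < cv_folds:
        logger.warning("reducing CV folds from %d to %d (smallest class size)", cv_folds, folds)
    fold_of = np.empty(len(y), dtype=int)
    rng = np.random.default_rng(seed)
    for c in classes:
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % folds
    errors = []
    for delta in delta_grid:
        wrong = 0
        for f in range(folds):
            tr, te = fold_of != f, fold_of == f
            model = _nsc_fit_at_delta(X[tr], y[tr], classes, list(spectra.columns), delta, prior_vec)
            wrong += int((model.predict(X[te]) != y[te]).sum())
        errors.append(wrong)
    errors = np.asarray(errors)
    # ties toward the largest delta: scan from the sparsest model down
    best_idx = len(errors) - 1 - int(np.argmin(errors[::-1]))
    model = _nsc_fit_at_delta(
        X, y, classes, list(spectra.columns), float(delta_grid[best_idx]), prior_vec
    )
    model.cv_errors = pd.DataFrame({"delta": delta_grid, "cv_errors": errors})
    return model


# ---- the two-class Gaussian discriminant on named channels -----------------


@dataclass
class DiscriminantParams:
    """Closed-form two-class Gaussian discriminant on a few channels.

    Means and scales are in percent-of-SNVs units.  ``exposed_mean`` and
    ``control_mean`` are the class centroids; ``scale`` the pooled
    per-channel SDs used to standardize the squared distances.
    """

    channels: list[str]
    exposed_mean: np.ndarray
    control_mean: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.exposed_mean = np.asarray(self.exposed_mean, dtype=float)
        self.control_mean = np.asarray(self.control_mean, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if not (
            len(self.channels)
            == self.exposed_mean.size
            == self.control_mean.size
            == self.scale.size
        ):
            raise ValueError("channels, means and scales must have equal length")
        if (self.scale <= 0).any():
            raise ValueError("scales must be positive")


def bap_reference_discriminant() -> DiscriminantParams:
    """The three-channel discriminant reported for the BaP study.

    Channels C[C>A]A, C[C>A]C and G[C>A]C with high-dose centroid
    (4.23, 10.3, 4.00)%, control centroid (1.38, 1.64, 0.80)% and pooled SDs
    (1.81, 4.11, 1.93)%.
    """
    return DiscriminantParams(
        channels=["C[C>A]A", "C[C>A]C", "G[C>A]C"],
        exposed_mean=[4.23, 10.3, 4.00],
        control_mean=[1.38, 1.64, 0.80],
        scale=[1.81, 4.11, 1.93],
    )


def prob_exposed(x, params: DiscriminantParams) -> float:
    """Probability that a channel-percent vector belongs to the exposed class.

    ``A`` and ``B`` are the squared standardized distances to the exposed and
    control centroids; the result is
    ``exp(-A/2) / (exp(-A/2) + exp(-B/2))``, evaluated in log space.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != params.exposed_mean.shape:
        raise ValueError("length mismatch between x and discriminant parameters")
    a = float(np.sum(((x - params.exposed_mean) / params.scale) ** 2))
    b = float(np.sum(((x - params.control_mean) / params.scale) ** 2))
    return float(expit((b - a) / 2.0))


def prob_control(x, params: DiscriminantParams) -> float:
    """Complement of :func:`prob_exposed` (A and B swapped)."""
    return 1.0 - prob_exposed(x, params)


def percent_spectra(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize a samples x channels count table to percent of SNVs."""
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("sample with zero SNVs cannot be normalized")
    return counts.div(totals, axis=0) * 100.0
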
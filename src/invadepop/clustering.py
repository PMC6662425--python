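"""Population structure: PCA of genotypes and a least-squares admixture model.

The admixture estimator factorizes the observed dosage matrix (scaled to
allele frequencies, ``X = dosage / 2``) as ``X ~ Q F`` where ``Q`` holds
per-individual membership proportions (rows on the probability simplex) and
``F`` holds per-cluster allele frequencies in ``[0, 1]``. Missing calls are
masked out of the objective (not imputed). The fit is a block projected
gradient descent, deterministic given a seed, with a provably non-increasing
objective (fixed 1/L steps on each quadratic block).

This is a deliberately simple stand-in for spatial Bayesian admixture
samplers: the downstream pipeline only needs memberships and a cluster
number. K is selected by masked-entry cross-validation (mask a fraction of
observed calls, fit, score squared prediction error on the masked entries)
with a one-standard-error rule, in place of information-criterion model
choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Sample scores on top components and explained-variance fractions."""

    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    components: np.ndarray = field(repr=False)
    degenerate: bool = False


@dataclass
class AdmixtureModel:
    """Q (samples x K memberships), F (K x loci frequencies) and fit info."""

    Q: np.ndarray
    F: np.ndarray
    objective: float
    objective_history: list[float] = field(repr=False)
    K: int = 0
    seed: int | None = None
    n_iter: int = 0
    converged: bool = False

    def hard_labels(self) -> np.ndarray:
        return self.Q.argmax(axis=1)


@dataclass
class KSelection:
    ks: list[int]
    cv_errors: dict[int, list[float]]  # per K, one error per CV repeat
    chosen: int


def _imputed_dosages(g: GenotypeMatrix) -> np.ndarray:
    """Dosages with per-locus mean imputation of missing calls."""
    d = g.dosages()
    means = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    idx = np.where(np.isnan(d))
    d[idx] = means[idx[1]]
    return d


def pca_genotypes(g: GenotypeMatrix, n_components: int = 10,
                  scale: bool = False) -> PcaResult:
    """PCA of the (mean-imputed, centered) dosage matrix.

    A matrix with zero variance (all genotypes identical) is flagged
    ``degenerate`` and returns zero scores.
    """
    X = _imputed_dosages(g)
    max_rank = min(g.n_samples, g.n_loci)
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds max rank {max_rank}")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    if not np.any(Xc):
        logger.warning("all genotypes identical: PCA degenerate")
        return PcaResult(
            scores=np.zeros((g.n_samples, n_components)),
            explained_variance_ratio=np.zeros(n_components),
            components=np.zeros((n_components, g.n_loci)),
            degenerate=True,
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xc)
    return PcaResult(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        components=pca.components_,
    )


def _project_rows_to_simplex(Q: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    K = Q.shape[1]
    u = np.sort(Q, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, K + 1)
    cond = u - css / ind > 0
    rho = K - cond[:, ::-1].argmax(axis=1)  # last true index + 1
    theta = css[np.arange(Q.shape[0]), rho - 1] / rho
    return np.maximum(Q - theta[:, None], 0.0)


def estimate_admixture(
    g: GenotypeMatrix,
    K: int,
    seed: int | None = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    mask: np.ndarray | None = None,
) -> AdmixtureModel:
    """Fit the K-cluster least-squares admixture model.

    ``mask`` optionally restricts the objective to a subset of the observed
    entries (used by :func:`select_k` for cross-validation). Initialization
    is K-means on PCA scores; the whole procedure is deterministic given
    ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > g.n_samples:
        raise ValueError(f"K={K} exceeds the number of samples ({g.n_samples})")
    X = g.dosages() / 2.0
    W = ~np.isnan(X)
    if mask is not None:
        W = W & mask
    X0 = np.where(W, X, 0.0)
    Wf = W.astype(np.float64)

    # --- initialization: K-means++ on PCA scores
    n_comp = min(max(K, 2), min(g.n_samples, g.n_loci), 10)
    scores = pca_genotypes(g, n_components=n_comp).scores
    if K == 1:
        labels = np.zeros(g.n_samples, dtype=int)
    else:
        km = KMeans(n_clusters=K, n_init=4, random_state=seed)
        labels = km.fit_predict(scores)
    Q = np.full((g.n_samples, K), 0.1 / max(K, 1))
    Q[np.arange(g.n_samples), labels] += 0.9
    Q /= Q.sum(axis=1, keepdims=True)
    # F init: per-cluster weighted mean frequency over observed entries
    denom = Q.T @ Wf
    F = (Q.T @ X0) / np.where(denom > 0, denom, 1.0)
    F = np.clip(F, 0.0, 1.0)

    def residual():
        return np.where(W, Q @ F - X0, 0.0)

    def objective(R):
        return 0.5 * float(np.sum(R * R))

    R = residual()
    history = [objective(R)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # F block: projected gradient, step 1/L with L = lambda_max(Q^T Q)
        lip_f = np.linalg.norm(Q.T @ Q, 2)
        if lip_f > 0:
            F = np.clip(F - (Q.T @ R) / lip_f, 0.0, 1.0)
            R = residual()
        # Q block: projected gradient onto the simplex
        lip_q = np.linalg.norm(F @ F.T, 2)
        if lip_q > 0:
            Q = _project_rows_to_simplex(Q - (R @ F.T) / lip_q)
            R = residual()
        obj = objective(R)
        assert obj <= history[-1] + 1e-9 * max(1.0, history[-1]), \
            "admixture objective increased"
        history.append(obj)
        denom_prev = max(history[-2], 1e-300)
        if abs(history[-2] - obj) / denom_prev < tol:
            converged = True
            break
    return AdmixtureModel(
        Q=Q, F=F, objective=history[-1], objective_history=history,
        K=K, seed=seed, n_iter=it, converged=converged,
    )


def select_k(
    g: GenotypeMatrix,
    k_range,
    seeds=(0, 1, 2),
    holdout_fraction: float = 0.05,
    max_iter: int = 200,
    tol: float = 1e-5,
    min_relative_gain: float = 0.10,
) -> KSelection:
    """Choose K by masked-entry cross-validation with a plateau rule.

    For each CV repeat a random ``holdout_fraction`` of the observed calls is
    masked, the model is fit on the rest for every K, and the squared
    prediction error on the masked entries is recorded. In predominantly
    selfing data the error keeps decreasing past the true cluster number
    (extra components soak up real family/lineage substructure within
    clusters), so the curve has no minimum; K is instead grown while each
    additional cluster still improves the mean masked-prediction error by at
    least ``min_relative_gain`` of the baseline (smallest-K) error — the
    point where the curve plateaus.
    """
    ks = sorted(int(k) for k in k_range)
    if not ks:
        raise ValueError("k_range must be non-empty")
    if len(ks) == 1:
        return KSelection(ks=ks, cv_errors={ks[0]: []}, chosen=ks[0])
    X = g.dosages() / 2.0
    observed = np.argwhere(~np.isnan(X))
    n_hold = int(round(holdout_fraction * len(observed)))
    if n_hold < 1 or n_hold >= len(observed):
        raise ValueError("holdout_fraction leaves no usable train/test split")
    errors: dict[int, list[float]] = {k: [] for k in ks}
    for s in seeds:
        rng = np.random.default_rng(s)
        pick = rng.choice(len(observed), size=n_hold, replace=False)
        hold = observed[pick]
        train_mask = np.ones(X.shape, dtype=bool)
        train_mask[hold[:, 0], hold[:, 1]] = False
        for k in ks:
            model = estimate_admixture(g, k, seed=s, max_iter=max_iter,
                                       tol=tol, mask=train_mask)
            pred = model.Q @ model.F
            err = float(np.mean((pred[hold[:, 0], hold[:, 1]]
                                 - X[hold[:, 0], hold[:, 1]]) ** 2))
            errors[k].append(err)
    means = {k: float(np.mean(v)) for k, v in errors.items()}
    baseline = means[ks[0]]
    chosen = ks[0]
    for prev, k in zip(ks, ks[1:]):
        if baseline > 0 and (means[prev] - means[k]) >= min_relative_gain * baseline:
            chosen = k
        else:
            break
    return KSelection(ks=ks, cv_errors=errors, chosen=chosen)
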
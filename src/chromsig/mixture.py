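"""EM clustering of FPCA scores under a diagonal Gaussian mixture.

Because the Karhunen-Loeve scores of a Gaussian process are
uncorrelated, the q-vector of scores of a profile from cluster k is
modelled as a product of univariate Gaussians, giving the mixture
density

    f(C) = sum_k pi_k  prod_j  N(C_j; mu_jk, var_jk),

fitted by EM with k-means warm starts. The characteristic pattern of a
cluster is the elementwise mean of its member profiles (on both the raw
count and log scales); cluster numbering is made canonical by sorting
clusters by descending mean total raw signal, so the last cluster is
always the least active one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .profiles import PROFILE_LEN, ProfileMatrix

logger = logging.getLogger(__name__)

VAR_FLOOR = 1e-8


@dataclass
class MixtureModel:
    """Fitted K-component diagonal-covariance Gaussian mixture.

    ``means[k, j]`` / ``variances[k, j]`` parameterize the univariate
    density of score j in cluster k+1; ``labels`` are 1-based hard
    assignments (argmax responsibility).
    """

    K: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    responsibilities: np.ndarray
    log_likelihood: float
    labels: np.ndarray
    n_iter: int
    converged: bool


@dataclass
class CharacteristicPattern:
    """Mean profile of one cluster, the template used for scanning."""

    cluster_id: int
    mean_raw: np.ndarray
    mean_log: np.ndarray
    n_members: int

    def __post_init__(self) -> None:
        if len(self.mean_raw) != PROFILE_LEN or len(self.mean_log) != PROFILE_LEN:
            raise ValueError(f"characteristic pattern must have length {PROFILE_LEN}")
        if self.n_members < 1:
            raise ValueError("cluster must have at least one member")


def _log_density(X: np.ndarray, weights, means, variances) -> np.ndarray:
    """(n, K) matrix of log pi_k + log N(x; mu_k, diag var_k)."""
    # (n,K,q) broadcast is fine at the sizes used (n ~ 1e3-1e4, Kq small)
    diff = X[:, None, :] - means[None, :, :]
    ll = -0.5 * (np.log(2 * np.pi * variances)[None] + diff**2 / variances[None]).sum(axis=2)
    return ll + np.log(weights)[None]


def _em_once(X: np.ndarray, K: int, init_seed: int, tol: float, max_iter: int):
    n, q = X.shape
    km = KMeans(n_clusters=K, n_init=1, random_state=init_seed).fit(X)
    means = km.cluster_centers_.copy()
    weights = np.bincount(km.labels_, minlength=K).astype(float)
    if np.any(weights == 0):
        return None
    variances = np.empty((K, q))
    for k in range(K):
        member = X[km.labels_ == k]
        variances[k] = np.maximum(member.var(axis=0), VAR_FLOOR) if len(member) > 1 \
            else np.maximum(X.var(axis=0), VAR_FLOOR)
    weights /= n

    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        logr = _log_density(X, weights, means, variances)
        norm = logsumexp(logr, axis=1)
        ll = float(norm.sum())
        if not np.isfinite(ll):
            return None
        # EM guarantee: the log-likelihood never decreases
        assert ll >= prev_ll - 1e-8 * (1 + abs(prev_ll)), "EM log-likelihood decreased"
        resp = np.exp(logr - norm[:, None])
        if abs(ll - prev_ll) <= tol * (1 + abs(prev_ll)):
            return weights, means, variances, resp, ll, it, True
        prev_ll = ll

        Nk = resp.sum(axis=0)
        if np.any(Nk < 1e-10):
            return None  # empty component: degenerate run
        weights = Nk / n
        means = (resp.T @ X) / Nk[:, None]
        variances = np.maximum((resp.T @ X**2) / Nk[:, None] - means**2, VAR_FLOOR)

    return weights, means, variances, resp, ll, max_iter, False


def fit_em(
    scores: np.ndarray,
    K: int,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixtureModel:
    """Fit the K-component diagonal Gaussian mixture by restarted EM.

    Each restart is initialized from a k-means solution with a distinct
    sub-seed derived from ``seed``; the best run by log-likelihood wins.
    A run whose component weights underflow (empty component) is
    discarded; if every restart degenerates an error is raised.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    n = X.shape[0]
    if not (n > K >= 1):
        raise ValueError(f"need n > K >= 1, got n={n}, K={K}")

    sub_seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31 - 1)
    best = None
    for ss in sub_seeds:
        result = _em_once(X, K, int(ss), tol, max_iter)
        if result is None:
            logger.info("EM restart (seed %d) degenerated; discarded", ss)
            continue
        if best is None or result[4] > best[4]:
            best = result
    if best is None:
        raise RuntimeError("all EM restarts degenerated (empty components)")

    weights, means, variances, resp, ll, n_iter, converged = best
    labels = resp.argmax(axis=1) + 1
    return MixtureModel(K, weights, means, variances, resp, ll, labels, n_iter, converged)


def bic(model: MixtureModel, n: int) -> float:
    """Bayesian information criterion; lower is better."""
    q = model.means.shape[1]
    n_params = (model.K - 1) + 2 * model.K * q
    return -2.0 * model.log_likelihood + n_params * np.log(n)


def select_K(
    scores: np.ndarray,
    K_range=range(2, 7),
    seed: int = 0,
    n_restarts: int = 10,
    matrix_log: ProfileMatrix | None = None,
    out_dir=None,
) -> pd.DataFrame:
    """Fit every K in ``K_range`` and tabulate diagnostics.

    Returns one row per K with log-likelihood, BIC, cluster sizes and a
    ``suggested`` flag on the BIC minimum. The final choice of K is the
    user's: cluster homogeneity is judged from the per-K heatmaps, which
    are written to ``out_dir`` when a log-scale profile matrix is given.
    """
    Ks = list(K_range)
    if not Ks:
        raise ValueError("K_range is empty")
    n = np.atleast_2d(scores).shape[0]
    rows, models = [], {}
    for K in Ks:
        m = fit_em(scores, K, seed=seed, n_restarts=n_restarts)
        models[K] = m
        sizes = np.bincount(m.labels - 1, minlength=K).tolist()
        rows.append({"K": K, "log_likelihood": m.log_likelihood,
                     "BIC": bic(m, n), "cluster_sizes": sizes})
    df = pd.DataFrame(rows)
    df["suggested"] = df["BIC"] == df["BIC"].min()
    if matrix_log is not None and out_dir is not None:
        from pathlib import Path
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for K, m in models.items():
            save_cluster_heatmap(matrix_log, m.labels, out_dir / f"heatmap_K{K}.png")
    return df


def characteristic_patterns(matrix_raw: ProfileMatrix, labels: np.ndarray) -> list[CharacteristicPattern]:
    """Per-cluster elementwise mean profile, on raw and log scales.

    The log-scale mean is the mean of the log-transformed member
    profiles (not the log of the raw mean).
    """
    if matrix_raw.transform_state != "raw":
        raise ValueError("characteristic_patterns needs the raw-count matrix")
    labels = np.asarray(labels)
    if len(labels) != matrix_raw.n:
        raise ValueError("labels length does not match matrix")
    K = int(labels.max())
    patterns = []
    log_values = np.log1p(matrix_raw.values)
    for k in range(1, K + 1):
        member = labels == k
        if not member.any():
            raise ValueError(f"cluster {k} is empty")
        patterns.append(CharacteristicPattern(
            k, matrix_raw.values[member].mean(axis=0),
            log_values[member].mean(axis=0), int(member.sum()),
        ))
    return patterns


def canonicalize(model: MixtureModel, matrix_raw: ProfileMatrix) -> MixtureModel:
    """Renumber clusters by descending mean total raw signal.

    Makes cluster identity stable across runs: cluster K is always the
    least active ("inactive promoter") cluster.
    """
    totals = matrix_raw.values.sum(axis=1)
    mean_total = np.array([
        totals[model.labels == k + 1].mean() if np.any(model.labels == k + 1) else -np.inf
        for k in range(model.K)
    ])
    order = np.argsort(-mean_total, kind="stable")
    remap = np.empty(model.K, dtype=int)
    remap[order] = np.arange(model.K)
    return replace(
        model,
        weights=model.weights[order],
        means=model.means[order],
        variances=model.variances[order],
        responsibilities=model.responsibilities[:, order],
        labels=remap[model.labels - 1] + 1,
    )


def save_cluster_heatmap(matrix_log: ProfileMatrix, labels: np.ndarray, path) -> None:
    """Cluster-sorted heatmap of per-bin z-scores of the log counts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = matrix_log.values if matrix_log.transform_state == "log" \
        else np.log1p(matrix_log.values)
    sd = values.std(axis=0)
    sd[sd == 0] = 1.0
    z = (values - values.mean(axis=0)) / sd
    order = np.argsort(labels, kind="stable")
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(z[order], aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3,
                   interpolation="nearest")
    boundaries = np.flatnonzero(np.diff(np.sort(labels))) + 0.5
    for b in boundaries:
        ax.axhline(b, color="black", lw=0.5)
    ax.set_xlabel("concatenated bin (4 marks x 100)")
    ax.set_ylabel("profiles (sorted by cluster)")
    fig.colorbar(im, ax=ax, label="z-score of log count")
    fig.savefig(path, dpi=100)
    plt.close(fig)
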
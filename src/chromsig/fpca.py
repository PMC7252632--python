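"""Dense-grid functional principal component analysis of 400-bin profiles.

Each log-scale profile is treated as a realization of a stochastic
process Y(t) on the grid t = 1..400 and represented by the truncated
Karhunen-Loeve expansion

    Y(t) ~ mu(t) + sum_{j=1}^{q} C_j psi_j(t),

where mu is the cross-sectional mean, the psi_j are orthonormal
eigenfunctions of the sample covariance, and the scores C_j are
uncorrelated with variance lambda_j. On a dense regular grid no
covariance smoothing is needed: the eigenpairs come straight from the
eigendecomposition of the 400x400 sample covariance of the centred
profiles, with grid spacing treated as 1 so inner products are plain
dot products. q is the smallest number of components whose cumulative
fraction of variance explained (FVE) reaches a threshold (default 0.90).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .profiles import ProfileMatrix


@dataclass
class FPCAModel:
    """Fitted FPCA decomposition.

    Attributes
    ----------
    mu : (T,) mean function on the grid.
    psi : (T, q) orthonormal eigenfunctions, columns in decreasing
        eigenvalue order, sign-fixed so each column's largest-magnitude
        element is positive.
    eigenvalues : (q,) non-increasing, non-negative.
    scores : (n, q) per-profile scores C_j = <y - mu, psi_j>.
    fve : (q,) cumulative fraction of variance explained.
    total_variance : trace of the sample covariance.
    """

    mu: np.ndarray
    psi: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    fve: np.ndarray
    q: int
    total_variance: float

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path,
            mu=self.mu, psi=self.psi, eigenvalues=self.eigenvalues,
            scores=self.scores, fve=self.fve,
            manifest=np.array(json.dumps({
                "q": self.q, "total_variance": self.total_variance,
                "grid_length": len(self.mu), "n_profiles": self.scores.shape[0],
            })),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FPCAModel":
        with np.load(path) as z:
            manifest = json.loads(str(z["manifest"]))
            return cls(z["mu"], z["psi"], z["eigenvalues"], z["scores"],
                       z["fve"], manifest["q"], manifest["total_variance"])


def _as_log_array(matrix) -> np.ndarray:
    if isinstance(matrix, ProfileMatrix):
        if matrix.transform_state != "log":
            raise ValueError("FPCA expects log-transformed profiles")
        return matrix.values
    return np.atleast_2d(np.asarray(matrix, dtype=float))


def fit_fpca(matrix, fve_threshold: float = 0.90, q_override: int | None = None) -> FPCAModel:
    """Fit FPCA by eigendecomposition of the sample covariance.

    Parameters
    ----------
    matrix
        Log-scale :class:`ProfileMatrix` (or plain (n, T) array).
    fve_threshold
        q is the smallest j with cumulative FVE >= this fraction.
    q_override
        Fix q directly, ignoring the FVE rule.
    """
    Y = _as_log_array(matrix)
    n, T = Y.shape
    if n < 2:
        raise ValueError(f"need at least 2 profiles to estimate covariance, got {n}")
    if not (0 < fve_threshold <= 1):
        raise ValueError(f"fve_threshold must be in (0, 1], got {fve_threshold}")

    mu = Y.mean(axis=0)
    Yc = Y - mu
    cov = (Yc.T @ Yc) / (n - 1)
    total_var = float(np.trace(cov))

    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    # deterministic sign: largest-magnitude element of each psi_j positive
    flip = np.sign(evecs[np.abs(evecs).argmax(axis=0), np.arange(T)])
    flip[flip == 0] = 1.0
    evecs = evecs * flip

    if total_var > 0:
        cum_fve = np.cumsum(evals) / total_var
    else:
        cum_fve = np.ones(T)
    if q_override is not None:
        if not (1 <= q_override <= T):
            raise ValueError(f"q_override must be in [1, {T}], got {q_override}")
        q = int(q_override)
    else:
        q = int(np.searchsorted(cum_fve, fve_threshold - 1e-12) + 1)
        q = min(q, T)

    psi = evecs[:, :q]
    scores = Yc @ psi
    return FPCAModel(mu, psi, evals[:q], scores, cum_fve[:q], q, total_var)


def project(model: FPCAModel, profile: np.ndarray) -> np.ndarray:
    """Score a profile (or stack of profiles) against a fitted model."""
    y = np.asarray(profile, dtype=float)
    if y.shape[-1] != len(model.mu):
        raise ValueError(f"profile length {y.shape[-1]} != grid length {len(model.mu)}")
    return (y - model.mu) @ model.psi


def reconstruct(model: FPCAModel, scores: np.ndarray) -> np.ndarray:
    """Rebuild the smooth curve mu + sum_j C_j psi_j from scores."""
    c = np.asarray(scores, dtype=float)
    if c.shape[-1] != model.q:
        raise ValueError(f"scores length {c.shape[-1]} != q = {model.q}")
    return model.mu + c @ model.psi.T
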
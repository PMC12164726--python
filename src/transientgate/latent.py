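"""20-factor latent model of population firing rates.

Maximum-likelihood factor analysis fit by EM on the sample covariance
(equivalent to the per-sample formulation but O(channels^2) per iteration,
which matters inside leave-one-out loops), followed by an SVD of the loading
matrix to build the orthonormal latent basis every downstream analysis works
in. Latent scores are by default the orthonormal projection of centered rates
(variance accounting in the latent space is then exact); posterior-mean
scoring is available as an option.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


class FactorLatentSpace(BaseEstimator, TransformerMixin):
    """Factor-analysis latent space with orthonormal basis.

    Parameters
    ----------
    n_factors : int
        Latent dimensionality (20 throughout the pipeline).
    max_iter : int
        EM iteration cap. Non-convergence sets ``converged_ = False``.
    tol : float
        Relative log-likelihood improvement below which EM stops.
    scoring : {"projection", "posterior"}
        "projection": z = basis' (x - mean). "posterior": EM posterior factor
        mean.

    Attributes
    ----------
    loadings_ : ndarray (n_channels, n_factors)
    channel_means_ : ndarray (n_channels,)
    noise_variances_ : ndarray (n_channels,)
    basis_ : ndarray (n_channels, n_factors), orthonormal columns
    loglike_ : list of per-iteration log-likelihoods (monotone non-decreasing)
    converged_ : bool
    dropped_channels_ : ndarray of channel indices excluded as constant
    """

    def __init__(self, n_factors: int = 20, max_iter: int = 500, tol: float = 1e-8,
                 scoring: str = "projection", psi_floor: float = 1e-8):
        self.n_factors = n_factors
        self.max_iter = max_iter
        self.tol = tol
        self.scoring = scoring
        self.psi_floor = psi_floor

    def fit(self, X, y=None):
        """Fit on rates, shape (n_bins, n_channels)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_bins, n_channels)")
        n, p = X.shape
        k = self.n_factors
        if n <= k:
            raise ValueError(f"need more bins ({n}) than factors ({k})")
        if self.scoring not in ("projection", "posterior"):
            raise ValueError("scoring must be 'projection' or 'posterior'")

        mean_full = X.mean(axis=0)
        var_full = X.var(axis=0)
        active = var_full > 1e-12
        dropped = np.flatnonzero(~active)
        if dropped.size:
            warnings.warn(f"dropping {dropped.size} constant channel(s): "
                          f"{dropped.tolist()}", RuntimeWarning, stacklevel=2)
        if active.sum() <= k:
            raise ValueError("not enough non-constant channels for the factor count")

        Xa = X[:, active]
        mu = Xa.mean(axis=0)
        Xc = Xa - mu
        S = (Xc.T @ Xc) / n
        pa = S.shape[0]

        # deterministic PCA initialization
        evals, evecs = np.linalg.eigh(S)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        resid = max(evals[k:].mean(), self.psi_floor) if pa > k else self.psi_floor
        L = evecs[:, :k] * np.sqrt(np.maximum(evals[:k] - resid, self.psi_floor))
        psi = np.maximum(np.diag(S) - (L ** 2).sum(axis=1), self.psi_floor)

        lls: list[float] = []
        ll_old = -np.inf
        converged = False
        const = pa * np.log(2 * np.pi)
        for _ in range(self.max_iter):
            Lp = L / psi[:, None]
            G = np.linalg.inv(np.eye(k) + L.T @ Lp)      # posterior covariance
            SLp = S @ Lp
            B = G + G @ (Lp.T @ SLp) @ G                 # E[zz'] under the model
            L = SLp @ G @ np.linalg.inv(B)
            psi = np.maximum(np.diag(S) - np.einsum("ij,ij->i", L, SLp @ G),
                             self.psi_floor)
            C = L @ L.T + np.diag(psi)
            sign, logdet = np.linalg.slogdet(C)
            ll = -0.5 * n * (const + logdet + np.trace(np.linalg.solve(C, S)))
            lls.append(ll)
            if np.isfinite(ll_old) and ll - ll_old <= self.tol * abs(ll_old):
                converged = True
                break
            ll_old = ll
        if not converged:
            warnings.warn(f"factor-analysis EM did not converge in "
                          f"{self.max_iter} iterations", RuntimeWarning, stacklevel=2)

        loadings = np.zeros((p, k))
        loadings[active] = L
        noise_var = np.full(p, self.psi_floor)
        noise_var[active] = psi
        u, _, _ = np.linalg.svd(loadings, full_matrices=False)
        u *= np.sign(u[np.abs(u).argmax(axis=0), np.arange(k)])  # sign convention

        self.n_features_in_ = p
        self.loadings_ = loadings
        self.channel_means_ = mean_full
        self.noise_variances_ = noise_var
        self.basis_ = u
        self.loglike_ = lls
        self.n_iter_ = len(lls)
        self.converged_ = converged
        self.dropped_channels_ = dropped
        self.active_channels_ = np.flatnonzero(active)
        return self

    def transform(self, X) -> np.ndarray:
        """Latent trajectories, shape (n_bins, n_factors)."""
        check_is_fitted(self, "basis_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected (n_bins, {self.n_features_in_}) rates, got {X.shape}")
        Xc = X - self.channel_means_
        if self.scoring == "projection":
            return Xc @ self.basis_
        # posterior factor mean mapped into the orthonormal basis coordinates
        a = self.active_channels_
        L, psi = self.loadings_[a], self.noise_variances_[a]
        Lp = L / psi[:, None]
        G = np.linalg.inv(np.eye(self.n_factors) + L.T @ Lp)
        z_factor = Xc[:, a] @ Lp @ G                      # posterior means
        return z_factor @ (L.T @ self.basis_)             # express in basis coords

    def inverse_transform(self, Z) -> np.ndarray:
        """Rank-k reconstruction of rates from latent trajectories."""
        check_is_fitted(self, "basis_")
        Z = np.asarray(Z, dtype=float)
        return Z @ self.basis_.T + self.channel_means_


def fit_factor_model(rates: np.ndarray, n_factors: int = 20, max_iter: int = 500,
                     tol: float = 1e-8) -> FactorLatentSpace:
    """Fit the latent model on a (channels x bins) rate matrix."""
    return FactorLatentSpace(n_factors=n_factors, max_iter=max_iter, tol=tol).fit(
        np.asarray(rates).T)


def project(rates: np.ndarray, model: FactorLatentSpace) -> np.ndarray:
    """Project a (channels x bins) rate matrix to (bins x n_factors) latents."""
    return model.transform(np.asarray(rates).T)
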
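"""Relevance vector regression (sparse Bayesian linear-kernel regression).

The model is y = Phi w + e with Gaussian noise of variance sigma^2, a
zero-mean Gaussian prior of per-basis precision alpha_m on each weight,
and basis functions phi_m(x) = k(x, x_m) over the training samples plus a
bias column.  Hyperparameters are set by type-II maximum likelihood
(evidence maximization); bases whose evidence does not support a finite
alpha are excluded, leaving a sparse set of "relevance vectors".  With a
linear kernel this behaves like a self-regularizing kernel ridge
regression and needs no tuned hyperparameters, which is why it is the
customary learner for connectome-based prediction.

Fitting uses the sequential (fast marginal likelihood) algorithm: bases
are added to, re-estimated in, or deleted from the active set one at a
time, each step choosing the action with the largest analytic increase
of the log marginal likelihood.  For basis m with sparsity and quality
factors s_m and q_m, the evidence is maximized at

    alpha_m = s_m^2 / (q_m^2 - s_m)   if q_m^2 > s_m, else alpha_m = inf.

The sequential scheme is used instead of full-design re-estimation
because the linear kernel over n samples with few selected edges is
heavily rank-deficient, and simultaneous alpha updates on near-duplicate
bases can enter limit cycles instead of converging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lapack, solve_triangular

from ._utils import IntegrityError

__all__ = ["RVR"]


def _chol_solve(hess: np.ndarray, rhs: np.ndarray):
    """Solve hess @ x = rhs via Cholesky; returns (x, inverse of hess)."""
    L, info = lapack.dpotrf(hess, lower=1, clean=1)
    if info != 0:
        jitter = 1e-10 * max(np.trace(hess), 1.0) / hess.shape[0]
        L, info = lapack.dpotrf(
            hess + jitter * np.eye(hess.shape[0]), lower=1, clean=1
        )
        if info != 0:
            raise np.linalg.LinAlgError("posterior Hessian not positive definite")
    z = solve_triangular(L, rhs, lower=True, check_finite=False)
    x = solve_triangular(L, z, lower=True, trans="T", check_finite=False)
    inv_l, info = lapack.dtrtri(L, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("triangular inverse failed")
    sigma = inv_l.T @ inv_l
    return x, sigma


@dataclass
class RVR:
    """Relevance vector machine for regression with a linear kernel.

    Parameters
    ----------
    max_iter : maximum sequential add/re-estimate/delete actions.
    tol : convergence threshold on the change of log alpha during
        re-estimation (converged when no add/delete improves the evidence
        and the largest re-estimation step is below ``tol``).
    alpha_ceiling : alphas above this count as infinite (basis excluded).
    noise_every : the noise variance is re-estimated every this many
        actions (and at convergence), following standard practice for the
        sequential scheme.
    alignment_max : a basis is never added while its absolute cosine with
        an active basis exceeds this; near-duplicate kernel columns would
        otherwise make the active Gram numerically singular.
    update_hyperparams : set False to skip evidence maximization and fit
        the full design at fixed hyperparameters ``alpha_init`` and
        ``beta_init`` (no sparsity); the posterior mean then coincides
        with the penalized-least-squares solution for ridge penalty
        alpha/beta, which serves as the module's independent oracle.
    alpha_init, beta_init : fixed hyperparameters for that mode
        (``beta_init=None`` uses 1 / (0.1 * var(y))).
    """

    max_iter: int = 500
    tol: float = 1e-6
    alpha_ceiling: float = 1e9
    noise_every: int = 5
    alignment_max: float = 1.0 - 1e-3
    update_hyperparams: bool = True
    alpha_init: float = 1e-6
    beta_init: float | None = None

    converged_: bool = field(init=False, default=False)
    n_features_in_: int = field(init=False, default=0)

    def _design(self, X: np.ndarray) -> np.ndarray:
        """Bias column + linear kernel against the training rows."""
        return np.hstack([np.ones((X.shape[0], 1)), X @ self._X_train.T])

    # ------------------------------------------------------------------
    def fit(self, X, y) -> "RVR":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        n, d = X.shape
        if n != y.size:
            raise ValueError("X and y disagree on the number of samples")
        if n < 2:
            raise ValueError("need at least 2 samples")
        if d < 1:
            raise ValueError("need at least 1 feature")
        self._X_train = X.copy()
        self.n_features_in_ = d

        phi = self._design(X)
        if self.update_hyperparams:
            self._fit_sequential(phi, y)
        else:
            self._fit_fixed(phi, y)
        return self

    def _fit_fixed(self, phi: np.ndarray, y: np.ndarray) -> None:
        """Full-design posterior at frozen hyperparameters (ridge limit)."""
        n, m = phi.shape
        beta = (
            float(self.beta_init)
            if self.beta_init is not None
            else 1.0 / max(0.1 * y.var(), 1e-9)
        )
        hess = beta * (phi.T @ phi)
        hess.flat[:: m + 1] += self.alpha_init
        mu, _ = _chol_solve(hess, beta * (phi.T @ y))
        self.active_ = np.arange(m)
        self.weights_ = mu
        self.alpha_ = np.full(m, float(self.alpha_init))
        self.beta_ = beta
        self.converged_ = True
        self.relevance_vectors_ = np.arange(phi.shape[0])

    def _fit_sequential(self, phi: np.ndarray, y: np.ndarray) -> None:
        n, m_full = phi.shape
        gram = phi.T @ phi
        phity = phi.T @ y
        gram_diag = np.diag(gram).copy()
        beta = (
            float(self.beta_init)
            if self.beta_init is not None
            else 1.0 / max(0.1 * y.var(), 1e-9)
        )

        alpha = np.full(m_full, np.inf)
        active: list[int] = []
        mu = np.zeros(0)
        sigma = np.zeros((0, 0))
        self.converged_ = False

        def refresh_posterior():
            nonlocal mu, sigma
            if not active:
                mu = np.zeros(0)
                sigma = np.zeros((0, 0))
                return
            idx = np.array(active)
            hess = beta * gram[np.ix_(idx, idx)]
            hess.flat[:: len(idx) + 1] += alpha[idx]
            mu, sigma = _chol_solve(hess, beta * phity[idx])

        def update_noise() -> float:
            """Re-estimate beta from current residuals; returns |d log beta|."""
            nonlocal beta
            if not active:
                return 0.0
            idx = np.array(active)
            resid = y - phi[:, idx] @ mu
            gamma_sum = len(idx) - float(np.sum(alpha[idx] * np.diag(sigma)))
            new_beta = float(
                np.clip(
                    (n - gamma_sum) / max(float(resid @ resid), 1e-12),
                    1e-12,
                    1e12,
                )
            )
            change = abs(np.log(new_beta) - np.log(beta))
            beta = new_beta
            refresh_posterior()
            return change

        def sq_factors():
            """Common sparsity/quality factors S, Q for every basis.

            Computed as beta times a Schur-complement form (the beta^2
            Woodbury expression cancels catastrophically once the noise
            precision gets large); the S bracket is analytically
            non-negative, so numerical negatives are floored.
            """
            if not active:
                return beta * gram_diag, beta * phity
            idx = np.array(active)
            w = gram[:, idx]
            t = w @ (beta * sigma)
            s_bracket = gram_diag - np.einsum("ij,ij->i", t, w)
            S = beta * np.maximum(s_bracket, 1e-300)
            Q = beta * (phity - t @ phity[idx])
            return S, Q

        # seed with the basis of largest normalized projection onto y
        proj = np.where(gram_diag > 0, phity**2 / np.maximum(gram_diag, 1e-300), 0.0)
        first = int(np.argmax(proj))
        S0 = beta * gram_diag[first]
        Q0 = beta * phity[first]
        if Q0**2 > S0:
            alpha[first] = S0**2 / (Q0**2 - S0)
            active.append(first)
        refresh_posterior()

        for it in range(self.max_iter):
            S, Q = sq_factors()
            in_model = np.zeros(m_full, dtype=bool)
            if active:
                in_model[np.array(active)] = True
            # convert common factors to exclusive s, q for active bases
            s, q = S.copy(), Q.copy()
            with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
                if active:
                    idx = np.array(active)
                    denom = alpha[idx] - S[idx]
                    ok = np.abs(denom) > 1e-300
                    s[idx] = np.where(ok, alpha[idx] * S[idx] / denom, np.inf)
                    q[idx] = np.where(ok, alpha[idx] * Q[idx] / denom, 0.0)
                theta = q**2 - s

            # evidence change for each candidate action
            delta_l = np.full(m_full, -np.inf)
            with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
                new_alpha = np.where(
                    theta > 0, s**2 / np.maximum(theta, 1e-300), np.inf
                )
            with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
                # additions (alignment-guarded)
                add = (~in_model) & (theta > 0) & (S > 1e-12)
                if active and np.any(add):
                    idx = np.array(active)
                    cand = np.flatnonzero(add)
                    cos = np.abs(gram[np.ix_(cand, idx)]) / np.sqrt(
                        np.outer(gram_diag[cand], gram_diag[idx])
                    )
                    add[cand[cos.max(axis=1) > self.alignment_max]] = False
                delta_l[add] = 0.5 * (
                    (Q[add] ** 2 - S[add]) / S[add]
                    + np.log(S[add] / Q[add] ** 2)
                )
                # re-estimations
                re = in_model & (theta > 0)
                if np.any(re):
                    diff = 1.0 / new_alpha[re] - 1.0 / alpha[re]
                    delta_l[re] = 0.5 * (
                        Q[re] ** 2 / (S[re] + 1.0 / diff)
                        - np.log1p(S[re] * diff)
                    )
                # deletions
                rm = in_model & (theta <= 0)
                if np.any(rm):
                    delta_l[rm] = 0.5 * (
                        Q[rm] ** 2 / (S[rm] - alpha[rm])
                        - np.log(1.0 - S[rm] / alpha[rm])
                    )
            delta_l = np.where(np.isfinite(delta_l), delta_l, -np.inf)

            best = int(np.argmax(delta_l))
            best_gain = delta_l[best]
            settled = False
            if not np.isfinite(best_gain) or best_gain <= 0:
                settled = True
            elif in_model[best] and theta[best] > 0:
                step = abs(np.log(new_alpha[best]) - np.log(alpha[best]))
                alpha[best] = new_alpha[best]
                refresh_posterior()
                # structure settled once no add/delete pays off and the
                # best surviving re-estimation step is below tolerance
                structural = delta_l.copy()
                structural[in_model & (theta > 0)] = -np.inf
                settled = step < self.tol and np.max(structural) <= 0
            elif in_model[best]:
                if len(active) == 1:
                    settled = True
                else:
                    alpha[best] = np.inf
                    active.remove(best)
                    refresh_posterior()
            else:
                alpha[best] = new_alpha[best]
                active.append(best)
                refresh_posterior()

            if settled:
                # structure converged at the current noise level; accept
                # only if the noise estimate itself has stabilized
                if update_noise() < 1e-3:
                    self.converged_ = True
                    break
            elif (it + 1) % self.noise_every == 0:
                update_noise()
        else:
            self.converged_ = False

        idx = np.array(sorted(active), dtype=int)
        # final posterior on the sorted active set
        if idx.size:
            hess = beta * gram[np.ix_(idx, idx)]
            hess.flat[:: len(idx) + 1] += alpha[idx]
            mu, _ = _chol_solve(hess, beta * phity[idx])
        else:
            mu = np.zeros(0)
        self.active_ = idx
        self.weights_ = mu
        self.alpha_ = alpha[idx]
        self.beta_ = beta
        # 0 marks the bias; basis m>0 corresponds to training sample m-1
        self.relevance_vectors_ = np.array([i - 1 for i in idx if i > 0], dtype=int)

    # ------------------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise IntegrityError(
                f"expected {self.n_features_in_} feature columns aligned with "
                f"the fitted model, got shape {X.shape}"
            )
        if self.active_.size == 0:
            return np.zeros(X.shape[0])
        phi = self._design(X)[:, self.active_]
        return phi @ self.weights_
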
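"""Maximum-likelihood population-effects (MLPE) mixed model for pairwise data.

Pairwise genetic similarity y_pq between individuals p and q is regressed on a
pairwise distance d_pq (effective resistance or geographic distance) under a
log link with additive Gaussian error:

    eta_pq = b0 + b1 * d_pq + u_p + u_q,   u_i ~ N(0, s2_u) iid
    y_pq   ~ N(exp(eta_pq), s2_eps)

The shared individual random effects u induce positive covariance between any
two pairs that share an individual — the MLPE covariance structure that
accounts for the non-independence of pairwise observations.  Parameters
maximize the Laplace-approximate marginal likelihood (exact for the identity
link, where the model is an ordinary linear mixed model).

The fit profiles both the mode of (beta, u) and the residual variance, leaving
a one-dimensional search over the variance ratio lambda = s2_u / s2_eps, which
keeps per-fit cost low enough for genetic-algorithm objective evaluations and
bootstrap replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin


@dataclass
class ModelFit:
    """Summary of one MLPE fit."""

    name: str
    beta: np.ndarray            # link-scale fixed effects (b0[, b1])
    sigma_u2: float
    sigma_eps2: float
    loglik: float
    n_pairs: int
    n_individuals: int
    k: int
    aicc: float
    r2m: float
    r2c: float
    converged: bool = True

    @property
    def slope(self) -> float:
        return float(self.beta[1]) if len(self.beta) > 1 else 0.0

    def summary_row(self) -> dict:
        return {"model": self.name, "loglik": self.loglik, "AICc": self.aicc,
                "R2m": self.r2m, "R2c": self.r2c, "beta1": self.slope,
                "sigma_u2": self.sigma_u2, "sigma_eps2": self.sigma_eps2,
                "n_pairs": self.n_pairs}


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion.

    AICc = −2ℓ + 2k + 2k(k+1)/(n − k − 1); requires n > k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc needs n > k + 1 (n={n}, k={k})")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _pair_index(n: int) -> np.ndarray:
    """All unordered pairs (p < q) of n individuals, row-major."""
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


class MLPERegressor(BaseEstimator, RegressorMixin):
    """MLPE mixed-effects regression of pairwise similarity on distance.

    Parameters
    ----------
    link : {"log", "identity"}
        Mean structure exp(eta) (default, exponential distance decay) or eta.
    standardize : bool
        Standardize the predictor to zero mean / unit variance before fitting;
        the reported slope is then on the standardized scale.
    with_slope : bool
        False fits the intercept-only (panmixia) submodel.
    n_restarts : int
        Jittered restarts of the inner mode search at the selected variance
        ratio, to guard against poor local modes.
    seed : int
        Seed for the restart jitter (deterministic fits).

    Attributes (after ``fit``)
    ----------
    beta_, sigma_u2_, sigma_eps2_, u_, loglik_, aicc_, r2m_, r2c_, k_,
    n_pairs_, n_individuals_, converged_
    """

    def __init__(self, link: str = "log", standardize: bool = True,
                 with_slope: bool = True, n_restarts: int = 3,
                 seed: int = 0, max_inner: int = 50, xatol: float = 1e-4):
        self.link = link
        self.standardize = standardize
        self.with_slope = with_slope
        self.n_restarts = n_restarts
        self.seed = seed
        self.max_inner = max_inner
        self.xatol = xatol

    # -- inner penalized Gauss-Newton mode search ---------------------------

    def _mu(self, eta):
        return np.exp(eta) if self.link == "log" else eta

    def _inner(self, X, Z_pairs, y, lam, theta0):
        """Mode of (beta, u) for penalty ||u||^2 / lam; returns theta and the
        profiled sum S = ||y - mu||^2 + ||u||^2 / lam."""
        P, p = X.shape
        n = self.n_individuals_
        theta = theta0.copy()
        pen = np.zeros(p + n)
        pen[p:] = 1.0 / lam

        def objective(th):
            eta = X @ th[:p] + th[p + Z_pairs[:, 0]] + th[p + Z_pairs[:, 1]]
            mu = self._mu(eta)
            return float(((y - mu) ** 2).sum() + (th[p:] ** 2 @ pen[p:])), mu

        f_old, mu = objective(theta)
        for _ in range(self.max_inner):
            eta = X @ theta[:p] + theta[p + Z_pairs[:, 0]] \
                + theta[p + Z_pairs[:, 1]]
            mu = self._mu(eta)
            w = mu if self.link == "log" else np.ones(P)
            r = y - mu
            # J = diag(w) [X  Z]; normal equations in (p + n)
            Jx = X * w[:, None]
            A = np.zeros((p + n, p + n))
            A[:p, :p] = Jx.T @ Jx
            g = np.zeros(p + n)
            g[:p] = Jx.T @ r
            w2 = w * w
            wr = w * r
            for c in (0, 1):
                idx = Z_pairs[:, c]
                np.add.at(g, p + idx, wr)
                blk = np.zeros((n, p))
                for jp in range(p):
                    np.add.at(blk[:, jp], idx, w2 * X[:, jp])
                A[p:, :p] += blk
            A[:p, p:] = A[p:, :p].T
            dZZ = np.zeros(n)
            np.add.at(dZZ, Z_pairs[:, 0], w2)
            np.add.at(dZZ, Z_pairs[:, 1], w2)
            off = np.zeros((n, n))
            np.add.at(off, (Z_pairs[:, 0], Z_pairs[:, 1]), w2)
            A[p:, p:] = off + off.T
            A[p + np.arange(n), p + np.arange(n)] = dZZ
            A[np.arange(p + n), np.arange(p + n)] += pen
            g -= pen * theta
            try:
                step = np.linalg.solve(
                    A + 1e-10 * np.eye(p + n), g)
            except np.linalg.LinAlgError:
                break
            # backtracking line search
            t = 1.0
            for _ls in range(30):
                f_new, mu_new = objective(theta + t * step)
                if f_new <= f_old:
                    break
                t *= 0.5
            else:
                break
            theta = theta + t * step
            if f_old - f_new <= 1e-12 * (abs(f_old) + 1e-12):
                f_old, mu = f_new, mu_new
                break
            f_old, mu = f_new, mu_new
        return theta, f_old, mu

    def _profile_loglik(self, X, Z_pairs, y, lam, theta0):
        """Profiled Laplace log-likelihood at variance ratio lam, plus the
        profiled residual variance and mode."""
        P = len(y)
        n = self.n_individuals_
        theta, S, mu = self._inner(X, Z_pairs, y, lam, theta0)
        w2 = (mu ** 2 if self.link == "log" else np.ones(P))
        dZZ = np.zeros(n)
        np.add.at(dZZ, Z_pairs[:, 0], w2)
        np.add.at(dZZ, Z_pairs[:, 1], w2)
        off = np.zeros((n, n))
        np.add.at(off, (Z_pairs[:, 0], Z_pairs[:, 1]), w2)
        M = lam * (off + off.T + np.diag(dZZ)) + np.eye(n)
        sign, logdet = np.linalg.slogdet(M)
        s2_eps = max(S / P, 1e-300)
        ll = (-0.5 * P * np.log(2 * np.pi * s2_eps) - 0.5 * P
              - 0.5 * logdet)
        return ll, s2_eps, theta

    # -- public API ---------------------------------------------------------

    def fit(self, d, y, pairs):
        """Fit the model.

        Parameters
        ----------
        d : array (P,) or None
            Pairwise predictor; ignored when ``with_slope`` is False.
        y : array (P,)
            Pairwise similarity response.
        pairs : array (P, 2) of int
            Individual indices of each pair (distinct within a row).
        """
        y = np.asarray(y, dtype=float).ravel()
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        P = len(y)
        if pairs.shape[0] != P:
            raise ValueError("pairs and y length mismatch")
        if np.any(pairs[:, 0] == pairs[:, 1]):
            raise ValueError("pairs must reference two distinct individuals")
        ids = np.unique(pairs)
        remap = -np.ones(ids.max() + 1, dtype=np.int64)
        remap[ids] = np.arange(ids.size)
        Z_pairs = remap[pairs]
        n = ids.size
        if n < 3:
            raise ValueError("need at least 3 individuals")
        self.n_individuals_ = n

        if self.with_slope:
            d = np.asarray(d, dtype=float).ravel()
            if not np.all(np.isfinite(d)):
                raise ValueError("predictor contains non-finite values; drop "
                                 "disconnected pairs upstream")
            if self.standardize:
                sd = d.std()
                d_use = (d - d.mean()) / (sd if sd > 0 else 1.0)
            else:
                d_use = d
            X = np.column_stack([np.ones(P), d_use])
        else:
            X = np.ones((P, 1))
        p = X.shape[1]

        # starting values from the link-scale least squares fit
        if self.link == "log":
            y0 = np.log(np.clip(y, 1e-8, None))
        else:
            y0 = y
        beta0, *_ = np.linalg.lstsq(X, y0, rcond=None)
        theta0 = np.concatenate([beta0, np.zeros(n)])

        state = {"theta": theta0}

        def neg_ll(t):
            lam = np.exp(t)
            ll, _, theta = self._profile_loglik(X, Z_pairs, y, lam,
                                                state["theta"])
            state["theta"] = theta
            return -ll

        res = minimize_scalar(neg_ll, bounds=(-14.0, 14.0), method="bounded",
                              options={"xatol": self.xatol, "maxiter": 80})
        t_hat = float(res.x)
        lam = np.exp(t_hat)

        # jittered restarts of the inner mode search at the selected ratio
        rng = np.random.default_rng(self.seed)
        best = None
        starts = [state["theta"]]
        for _ in range(max(self.n_restarts - 1, 0)):
            j = theta0.copy()
            j[:p] = beta0 + 0.1 * rng.standard_normal(p)
            starts.append(j)
        for th0 in starts:
            ll, s2e, theta = self._profile_loglik(X, Z_pairs, y, lam, th0)
            if best is None or ll > best[0]:
                best = (ll, s2e, theta)
        ll, s2_eps, theta = best

        self.beta_ = theta[:p]
        self.u_ = theta[p:]
        self.sigma_eps2_ = float(s2_eps)
        self.sigma_u2_ = float(lam * s2_eps)
        self.loglik_ = float(ll)
        self.n_pairs_ = P
        self.k_ = p + 2
        self.aicc_ = aicc(self.loglik_, self.k_, P)
        self.converged_ = bool(res.success)
        self._Xcols = p
        self._fixed_eta = X @ self.beta_
        self._mu_hat = self._mu(
            self._fixed_eta + self.u_[Z_pairs[:, 0]] + self.u_[Z_pairs[:, 1]])
        self.r2m_, self.r2c_ = r2_nakagawa(self)
        return self

    def predict(self, d, pairs=None):
        """Marginal mean for new predictor values (fixed effects only)."""
        if self.with_slope:
            d = np.asarray(d, dtype=float).ravel()
            eta = self.beta_[0] + self.beta_[1] * d
        else:
            eta = np.full(len(np.atleast_1d(d)), self.beta_[0])
        return self._mu(eta)

    def to_modelfit(self, name: str = "model") -> ModelFit:
        return ModelFit(name=name, beta=self.beta_.copy(),
                        sigma_u2=self.sigma_u2_, sigma_eps2=self.sigma_eps2_,
                        loglik=self.loglik_, n_pairs=self.n_pairs_,
                        n_individuals=self.n_individuals_, k=self.k_,
                        aicc=self.aicc_, r2m=self.r2m_, r2c=self.r2c_,
                        converged=self.converged_)


def r2_nakagawa(fit: MLPERegressor) -> tuple[float, float]:
    """Marginal and conditional R² on the link scale.

    R²m = s2_f / (s2_f + 2 s2_u + s2_eps,link), R²c adds 2 s2_u to the
    numerator; s2_f is the variance of the fixed-effect linear predictor and
    the residual variance is mapped to the link scale by the delta method
    (s2_eps / mu² for the log link).  Each pair carries two independent
    individual effects, hence the factor 2.
    """
    s2_f = 0.0 if fit._Xcols == 1 else float(np.var(fit._fixed_eta))
    if fit.link == "log":
        s2_eps_link = float(np.mean(fit.sigma_eps2_ /
                                    np.maximum(fit._mu_hat ** 2, 1e-300)))
    else:
        s2_eps_link = fit.sigma_eps2_
    denom = s2_f + 2.0 * fit.sigma_u2_ + s2_eps_link
    if denom <= 0:
        return 0.0, 0.0
    r2m = s2_f / denom
    r2c = (s2_f + 2.0 * fit.sigma_u2_) / denom
    return float(r2m), float(r2c)


def fit_mlpe(y, d, pairs, link: str = "log", with_slope: bool = True,
             name: str = "model", standardize: bool = True,
             n_restarts: int = 3, seed: int = 0,
             xatol: float = 1e-4) -> ModelFit:
    """Functional wrapper over :class:`MLPERegressor`."""
    est = MLPERegressor(link=link, standardize=standardize,
                        with_slope=with_slope, n_restarts=n_restarts,
                        seed=seed, xatol=xatol)
    est.fit(d, y, pairs)
    return est.to_modelfit(name)


def design_from_matrices(similarity, distance) -> tuple:
    """Long-form pairwise design from square similarity/distance matrices.

    Returns (y, d, pairs); infinite distances (disconnected pairs) are
    dropped with their count reported as the fourth element.
    """
    S = np.asarray(similarity, dtype=float)
    D = np.asarray(distance, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n) or D.shape != (n, n):
        raise ValueError("similarity and distance must be square and equal")
    pairs = _pair_index(n)
    y = S[pairs[:, 0], pairs[:, 1]]
    d = D[pairs[:, 0], pairs[:, 1]]
    ok = np.isfinite(d)
    return y[ok], d[ok], pairs[ok], int((~ok).sum())
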
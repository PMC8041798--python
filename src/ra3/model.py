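"""The RA3 latent-variable model and its EM/ICM fitting procedure.

The generative model for a TF-IDF-normalized profile ``y_j`` (p peaks) of
cell ``j`` with covariates ``x_j`` (q entries, intercept first) is

.. math::

    y_j \\mid \\lambda_j \\sim N_p(\\lambda_j, \\sigma^2 I),\\qquad
    \\lambda_j = \\beta x_j + W h_j,\\qquad
    W = [W_1\\; W_2\\; W_3],

where ``W1`` (p x K1) is fixed to PCA loadings of reference data, and
``W2`` (p x K2), ``W3`` (p x K3) carry Gaussian priors
``w_k ~ N(0, alpha_k^{-1} I)``.  Latent scores are standard normal on the
``h_1`` and ``h_3`` blocks, while each ``h_2`` entry follows a
spike-and-slab mixture selected by a Bernoulli(theta) indicator
``gamma_kj``: variance ``tau0^2 < 1`` in the spike and ``tau1^2 > 1`` in
the slab.  A cell whose indicator switches on loads strongly on a ``W2``
direction, which is how rare subpopulations absent from the reference are
picked out.

Fitting treats ``H`` as missing data and maximizes the expected complete
log-likelihood ``Q`` by EM, with the M-step solved by iterative
conditional modes (ICM): the binary indicators, the loadings ``W*``, the
precisions ``alpha``, the covariate coefficients ``beta`` and the noise
variance ``sigma^2`` are each set to their conditional optimum in turn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import stats

from ra3.preprocess import NormalizedMatrix
from ra3.reference import ProjectionBasis

logger = logging.getLogger(__name__)

__all__ = [
    "HyperParams",
    "CovariateMatrix",
    "ModelState",
    "LatentPosterior",
    "FitResult",
    "initialize_state",
    "e_step",
    "m_step_continuous",
    "m_step_gamma",
    "compute_objective",
    "compute_elbo",
    "fit",
    "postprocess_h2",
    "latent_representation",
    "intercept_only",
]


@dataclass(frozen=True)
class HyperParams:
    """Fixed hyperparameters of the model and the EM loop.

    ``tau0 = 0.9`` / ``tau1 = 5`` set the spike/slab standard deviations,
    ``theta = 0.1`` the prior slab probability (roughly the expected size
    of a rare subpopulation), and ``K2 = K3 = 5`` the number of free
    loading directions.  ``K1`` follows the reference (number of samples
    minus one, capped at 30).
    """

    K1: int
    K2: int = 5
    K3: int = 5
    tau0: float = 0.9
    tau1: float = 5.0
    theta: float = 0.1
    max_iter: int = 500
    rel_tol: float = 1e-6
    seed: int = 0
    # M-step uses the cross moment E(H1) E(H*)^T by default; the exact
    # posterior cross moment (including the covariance block) is available
    # as a correctness option.
    exact_cross_moment: bool = False
    # cap on the loading precisions: a free direction that captures nothing
    # is driven to alpha -> inf (automatic-relevance pruning); the cap stops
    # the runaway without changing which directions survive
    alpha_max: float = 1e8

    def __post_init__(self) -> None:
        if not (self.K1 >= 1 and self.K2 >= 1 and self.K3 >= 1):
            raise ValueError("K1, K2, K3 must be positive")
        if not self.tau0 < 1 < self.tau1:
            raise ValueError("need tau0 < 1 < tau1")
        if not 0 < self.theta < 1:
            raise ValueError("theta must be in (0, 1)")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")

    @property
    def K(self) -> int:
        return self.K1 + self.K2 + self.K3

    def spike_slab_rows(self) -> slice:
        """Global row indices of the K2 (spike-and-slab) block."""
        return slice(self.K1, self.K1 + self.K2)


@dataclass
class CovariateMatrix:
    """Known covariates, q x n, with the all-ones intercept as first row."""

    X: np.ndarray
    names: list[str] = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        q, n = self.X.shape
        if not np.allclose(self.X[0], 1.0):
            raise ValueError("first covariate row must be the all-ones intercept")
        if np.linalg.matrix_rank(self.X) < q:
            raise ValueError("covariate matrix is not full row rank (collinear)")
        if self.names is None:
            self.names = ["intercept"] + [f"covariate_{i}" for i in range(1, q)]

    @property
    def q(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]


def intercept_only(n: int) -> CovariateMatrix:
    """Design matrix with only the intercept (no measured covariates)."""
    return CovariateMatrix(np.ones((1, n)), ["intercept"])


@dataclass
class ModelState:
    """All free parameters plus the fixed basis W1.

    ``Gamma`` is the K x n indicator matrix; rows outside the
    spike-and-slab block are pinned to 1 (their priors are plain standard
    normals) and only the K2 block is ever updated.
    """

    W1: np.ndarray
    W2: np.ndarray
    W3: np.ndarray
    alpha: np.ndarray  # length K2 + K3, diagonal of A
    beta: np.ndarray  # p x q
    sigma2: float
    Gamma: np.ndarray  # K x n, binary

    def __post_init__(self) -> None:
        if np.any(self.alpha <= 0):
            raise ValueError("alpha entries must be positive")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    @property
    def K1(self) -> int:
        return self.W1.shape[1]

    @property
    def K2(self) -> int:
        return self.W2.shape[1]

    @property
    def K3(self) -> int:
        return self.W3.shape[1]

    @property
    def W(self) -> np.ndarray:
        return np.hstack([self.W1, self.W2, self.W3])

    @property
    def W_star(self) -> np.ndarray:
        return np.hstack([self.W2, self.W3])

    def set_w_star(self, W_star: np.ndarray) -> None:
        self.W2 = W_star[:, : self.K2].copy()
        self.W3 = W_star[:, self.K2 :].copy()

    def copy(self) -> "ModelState":
        return ModelState(
            self.W1, self.W2.copy(), self.W3.copy(), self.alpha.copy(),
            self.beta.copy(), float(self.sigma2), self.Gamma.copy(),
        )


@dataclass
class LatentPosterior:
    """Gaussian posterior of the latent scores, one mean column per cell.

    The posterior covariance depends on the cell only through its
    spike-and-slab indicator column, so cells sharing a pattern share one
    covariance matrix; ``pattern_index`` maps cells to ``pattern_covs``.
    """

    mean: np.ndarray  # K x n
    pattern_covs: np.ndarray  # u x K x K
    pattern_index: np.ndarray  # length n

    def cov(self, j: int) -> np.ndarray:
        return self.pattern_covs[self.pattern_index[j]]

    def second_moment(self, j: int) -> np.ndarray:
        mu = self.mean[:, j]
        return np.outer(mu, mu) + self.cov(j)

    @property
    def sum_cov(self) -> np.ndarray:
        counts = np.bincount(self.pattern_index, minlength=len(self.pattern_covs))
        return np.einsum("u,ukl->kl", counts.astype(float), self.pattern_covs)

    def sum_second_moment(self) -> np.ndarray:
        """Sum over cells of E(h_j h_j^T)."""
        return self.mean @ self.mean.T + self.sum_cov

    def second_moment_diag(self) -> np.ndarray:
        """K x n matrix of diagonal second moments E(h_j h_j^T)_kk."""
        var_diag = np.einsum("ukk->uk", self.pattern_covs)
        return self.mean**2 + var_diag[self.pattern_index].T

    def entropy(self) -> float:
        """Total differential entropy of the posterior over all cells."""
        K = self.mean.shape[0]
        n = self.mean.shape[1]
        counts = np.bincount(self.pattern_index, minlength=len(self.pattern_covs))
        logdets = np.array([np.linalg.slogdet(c)[1] for c in self.pattern_covs])
        return float(
            0.5 * counts @ logdets + 0.5 * n * K * (1.0 + np.log(2.0 * np.pi))
        )


@dataclass
class FitResult:
    """Posterior means, post-processed representation, and the Q trace."""

    H1: np.ndarray
    H2: np.ndarray
    H2_post: np.ndarray
    H3: np.ndarray
    objective_trace: list
    state: ModelState
    converged: bool
    posterior: LatentPosterior = None

    @property
    def n_iterations(self) -> int:
        return len(self.objective_trace)


# ---------------------------------------------------------------------------
# initialization


def _varimax(scores: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Orthogonal varimax rotation matrix R for a score matrix (n x k)."""
    n, k = scores.shape
    R = np.eye(k)
    if k == 1:
        return R
    d = 0.0
    for _ in range(max_iter):
        L = scores @ R
        grad = scores.T @ (L**3 - L @ np.diag((L**2).sum(axis=0)) / n)
        u, s, vt = np.linalg.svd(grad)
        R = u @ vt
        d_new = s.sum()
        if d_new <= d * (1 + tol):
            break
        d = d_new
    return R


def _as_dense(Y) -> np.ndarray:
    if isinstance(Y, NormalizedMatrix):
        return Y.dense()
    if sp.issparse(Y):
        return np.asarray(Y.todense(), dtype=np.float64)
    return np.asarray(Y, dtype=np.float64)


def _basis_matrix(W1) -> np.ndarray:
    return W1.W1 if isinstance(W1, ProjectionBasis) else np.asarray(W1, dtype=np.float64)


def initialize_state(
    Y, X: CovariateMatrix, W1, hp: HyperParams
) -> ModelState:
    """Warm-started parameters for the EM loop.

    ``W2`` starts from PCA of the residual after removing the ``W1``
    projection, rotated by varimax of the PC scores — varimax searches the
    principal subspace for directions on which a small number of cells
    score extremely, mimicking the spike-and-slab prior.  ``sigma`` starts
    at the standard deviation of the residual after removing the combined
    ``[W1, W2]`` projection; ``A`` at identity, ``beta`` at zero,
    spike-and-slab indicators at 0 and ``W3`` at seeded standard normals.
    """
    Yd = _as_dense(Y)
    W1m = _basis_matrix(W1)
    p, n = Yd.shape
    if W1m.shape[0] != p:
        raise ValueError("W1 peak dimension does not match Y")
    if W1m.shape[1] != hp.K1:
        raise ValueError(f"basis has {W1m.shape[1]} columns but hp.K1 = {hp.K1}")
    if X.n != n:
        raise ValueError("covariate matrix does not match number of cells")

    resid = Yd - W1m @ (W1m.T @ Yd)
    centered = resid - resid.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if hp.K2 > rank:
        raise ValueError(
            f"K2 = {hp.K2} exceeds the rank {rank} of the W1-residual"
        )
    V = U[:, : hp.K2]  # p x K2 loadings
    scores = (Vt[: hp.K2].T * s[: hp.K2])  # n x K2 PC scores
    R = _varimax(scores)
    W2 = V @ R

    B = np.hstack([W1m, W2])  # orthonormal: W2 lies in W1's orthocomplement
    resid2 = Yd - B @ (B.T @ Yd)
    sigma = resid2.std()
    if sigma <= 0:
        sigma = 1e-6

    rng = np.random.default_rng(hp.seed)
    # random directions with ~unit column norm: W3 must start subordinate
    # to the warm-started W2 columns (also unit norm), else the free
    # Gaussian block can capture the distinct-subpopulation direction
    # before the spike-and-slab block does and trap EM there
    W3 = rng.standard_normal((p, hp.K3)) / np.sqrt(p)

    Gamma = np.ones((hp.K, n), dtype=np.int8)
    Gamma[hp.spike_slab_rows()] = 0
    return ModelState(
        W1=W1m,
        W2=W2,
        W3=W3,
        alpha=np.ones(hp.K2 + hp.K3),
        beta=np.zeros((p, X.q)),
        sigma2=float(sigma**2),
        Gamma=Gamma,
    )


# ---------------------------------------------------------------------------
# E-step


def _prior_variances(state: ModelState, hp: HyperParams) -> np.ndarray:
    """K x n matrix of prior variances d_kj (the diagonal of D_j per cell)."""
    n = state.Gamma.shape[1]
    d = np.ones((hp.K, n))
    g2 = state.Gamma[hp.spike_slab_rows()].astype(np.float64)
    d[hp.spike_slab_rows()] = (1 - g2) * hp.tau0**2 + g2 * hp.tau1**2
    return d


def _solve_posterior_cov(Asym: np.ndarray) -> np.ndarray:
    """Invert the symmetric posterior precision with escalating jitter."""
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            L = np.linalg.cholesky(Asym + jitter * np.eye(Asym.shape[0]))
        except np.linalg.LinAlgError:
            continue
        inv_l = np.linalg.inv(L)
        return inv_l.T @ inv_l
    raise np.linalg.LinAlgError(
        "posterior precision not positive definite after jitter up to 1e-6; "
        f"condition number {np.linalg.cond(Asym):.3e}"
    )


def e_step(Y, X: CovariateMatrix, state: ModelState, hp: HyperParams) -> LatentPosterior:
    """Posterior moments of the latent scores given current parameters.

    For cell j the posterior is Gaussian with covariance
    ``(sigma^-2 W'W + D_j^-1)^-1`` and mean
    ``sigma^-2 Sigma_j W'(y_j - beta x_j)``; ``D_j`` holds the prior
    variances (ones outside the spike-and-slab block).  One covariance is
    solved per distinct indicator pattern, not per cell.
    """
    Yd = _as_dense(Y)
    W = state.W
    G = W.T @ W
    resid = Yd - state.beta @ X.X
    WtR = W.T @ resid / state.sigma2  # K x n

    d = _prior_variances(state, hp)
    patterns, pattern_index = np.unique(d.T, axis=0, return_inverse=True)
    K = hp.K
    covs = np.empty((len(patterns), K, K))
    for u, dvec in enumerate(patterns):
        covs[u] = _solve_posterior_cov(G / state.sigma2 + np.diag(1.0 / dvec))
    mean = np.empty((K, Yd.shape[1]))
    for u in range(len(patterns)):
        cells = pattern_index == u
        mean[:, cells] = covs[u] @ WtR[:, cells]
    return LatentPosterior(mean, covs, pattern_index)


# ---------------------------------------------------------------------------
# M-step


def _phi(gamma: np.ndarray, hp: HyperParams) -> np.ndarray:
    """Prior precision phi(gamma) on the spike-and-slab block."""
    g = gamma.astype(np.float64)
    return (1 - g) / hp.tau0**2 + g / hp.tau1**2


def m_step_gamma(
    posterior: LatentPosterior, state: ModelState, hp: HyperParams
) -> ModelState:
    """Element-wise conditional-mode update of the indicators.

    Each gamma_kj on the spike-and-slab block picks the value of
    ``f(g) = -E(h_j h_j')_kk phi(g)/2 + log(phi(g))/2
    + g log(theta) + (1-g) log(1-theta)`` that is larger, with ties broken
    toward the spike (0).  Rows outside the block stay pinned at 1.
    """
    new = state.copy()
    rows = hp.spike_slab_rows()
    e2 = posterior.second_moment_diag()[rows]  # K2 x n
    phi0, phi1 = 1.0 / hp.tau0**2, 1.0 / hp.tau1**2
    f0 = -0.5 * e2 * phi0 + 0.5 * np.log(phi0) + np.log(1 - hp.theta)
    f1 = -0.5 * e2 * phi1 + 0.5 * np.log(phi1) + np.log(hp.theta)
    new.Gamma[rows] = (f1 > f0).astype(np.int8)
    return new


def update_w_star(
    Yd: np.ndarray,
    X: CovariateMatrix,
    posterior: LatentPosterior,
    state: ModelState,
    hp: HyperParams,
) -> np.ndarray:
    """Conditional optimum of the free loadings W* = [W2 W3]."""
    K1 = hp.K1
    EH = posterior.mean
    EH1, EHs = EH[:K1], EH[K1:]
    S_star = EHs @ EHs.T + posterior.sum_cov[K1:, K1:]
    resid = Yd - state.beta @ X.X
    if hp.exact_cross_moment:
        cross = EH1 @ EHs.T + posterior.sum_cov[:K1, K1:]
        numer = resid @ EHs.T - state.W1 @ cross
    else:
        numer = (resid - state.W1 @ EH1) @ EHs.T
    system = S_star + state.sigma2 * np.diag(state.alpha)
    return np.linalg.solve(system.T, numer.T).T


def update_alpha(state: ModelState, alpha_max: float = 1e8) -> np.ndarray:
    """alpha_k = p / ||w_k||^2 for the free loading columns.

    Precisions are capped at ``alpha_max``: a direction the data do not
    support shrinks toward zero norm, and uncapped its precision would run
    away super-exponentially.  The cap sits below the conditional optimum
    on the concave increasing branch of Q, so monotonicity is unaffected.
    """
    Ws = state.W_star
    norms = (Ws**2).sum(axis=0)
    alive = norms > 0
    if not alive.any():
        raise ValueError("every free loading column collapsed to zero")
    out = np.full(len(norms), alpha_max)
    with np.errstate(over="ignore", divide="ignore"):
        out[alive] = np.minimum(Ws.shape[0] / norms[alive], alpha_max)
    return out


def update_beta(
    Yd: np.ndarray, X: CovariateMatrix, posterior: LatentPosterior, state: ModelState
) -> np.ndarray:
    """Least-squares update of the covariate coefficients."""
    target = Yd - state.W @ posterior.mean
    XXt = X.X @ X.X.T
    if np.linalg.cond(XXt) > 1e12:
        raise ValueError("covariates are collinear: X X^T is singular")
    return np.linalg.solve(XXt.T, (target @ X.X.T).T).T


def update_sigma2(
    Yd: np.ndarray, X: CovariateMatrix, posterior: LatentPosterior, state: ModelState
) -> float:
    """Closed-form noise-variance update from the expected residual sum of squares."""
    p, n = Yd.shape
    resid = Yd - state.beta @ X.X
    W = state.W
    G = W.T @ W
    rss = (
        float((resid**2).sum())
        - 2.0 * float(np.sum((W.T @ resid) * posterior.mean))
        + float(np.sum(G * posterior.sum_second_moment()))
    )
    return max(rss / (p * n), 1e-12)


def m_step_continuous(
    Y, X: CovariateMatrix, posterior: LatentPosterior, state: ModelState, hp: HyperParams
) -> ModelState:
    """ICM sweep over the continuous blocks in the order W* -> alpha -> beta -> sigma^2.

    Each update is the conditional optimum given the posterior moments and
    the most recent values of previously updated blocks; alpha follows W*
    because its update consumes the fresh loading norms.
    """
    Yd = _as_dense(Y)
    new = state.copy()
    new.set_w_star(update_w_star(Yd, X, posterior, new, hp))
    new.alpha = update_alpha(new, hp.alpha_max)
    new.beta = update_beta(Yd, X, posterior, new)
    new.sigma2 = update_sigma2(Yd, X, posterior, new)
    return new


# ---------------------------------------------------------------------------
# objective


def compute_objective(
    Y, X: CovariateMatrix, posterior: LatentPosterior, state: ModelState, hp: HyperParams
) -> float:
    """Expected complete log-likelihood Q (up to parameter-free constants).

    Sum of the Gaussian data term, the N(0, alpha_k^-1 I) prior on the free
    loadings, the (spike-and-slab) prior on the latent scores with the
    diagonal second moments entering linearly, and the Bernoulli prior on
    the indicators.
    """
    Yd = _as_dense(Y)
    p, n = Yd.shape
    W = state.W
    G = W.T @ W
    resid = Yd - state.beta @ X.X
    ss = posterior.sum_second_moment()
    data = -(n * p / 2) * np.log(state.sigma2) - 0.5 / state.sigma2 * (
        float((resid**2).sum())
        - 2.0 * float(np.sum((W.T @ resid) * posterior.mean))
        + float(np.sum(G * ss))
    )
    w_norms = (state.W_star**2).sum(axis=0)
    w_prior = float(np.sum(0.5 * p * np.log(state.alpha) - 0.5 * state.alpha * w_norms))
    phi = np.ones((hp.K, n))
    phi[hp.spike_slab_rows()] = _phi(state.Gamma[hp.spike_slab_rows()], hp)
    e2 = posterior.second_moment_diag()
    h_prior = -0.5 * float(np.sum(e2 * phi - np.log(phi)))
    g2 = state.Gamma[hp.spike_slab_rows()].astype(np.float64)
    gamma_prior = float(np.sum(g2 * np.log(hp.theta) + (1 - g2) * np.log(1 - hp.theta)))
    return data + w_prior + h_prior + gamma_prior


def compute_elbo(
    Y, X: CovariateMatrix, posterior: LatentPosterior, state: ModelState, hp: HyperParams
) -> float:
    """EM evidence lower bound: Q plus the posterior entropy of H.

    This is the quantity EM provably never decreases.  Q alone can dip
    when an E-step trades expected complete log-likelihood for posterior
    entropy, so the fitting loop traces and tests the bound.
    """
    return compute_objective(Y, X, posterior, state, hp) + posterior.entropy()


# ---------------------------------------------------------------------------
# fitting loop and post-processing


def fit(Y, X: CovariateMatrix | None, W1, hp: HyperParams) -> FitResult:
    """Run EM until the relative change in the objective falls below ``hp.rel_tol``.

    Each iteration performs the E-step, the indicator update, the
    continuous ICM sweep, and records the evidence lower bound
    (:func:`compute_elbo`).  The posterior means from the last
    iteration are split into ``H1``/``H2``/``H3``; ``H2`` is post-processed
    (zero-mean rows dropped, survivors winsorized) into ``H2_post``, and
    the downstream representation is the vertical stack of ``H1`` and
    ``H2_post``.
    """
    Yd = _as_dense(Y)
    if X is None:
        X = intercept_only(Yd.shape[1])
    state = initialize_state(Yd, X, W1, hp)
    trace: list[float] = []
    converged = False
    posterior = None
    for it in range(hp.max_iter):
        posterior = e_step(Yd, X, state, hp)
        state = m_step_gamma(posterior, state, hp)
        state = m_step_continuous(Yd, X, posterior, state, hp)
        q = compute_elbo(Yd, X, posterior, state, hp)
        if not np.isfinite(q):
            raise RuntimeError(f"objective diverged (non-finite Q) at iteration {it}")
        trace.append(q)
        if it > 0 and abs(trace[-1] - trace[-2]) / (abs(trace[-1]) + 1.0) < hp.rel_tol:
            converged = True
            break
    # final E-step so the reported moments reflect the final parameters
    posterior = e_step(Yd, X, state, hp)
    EH = posterior.mean
    H1 = EH[: hp.K1]
    H2 = EH[hp.spike_slab_rows()]
    H3 = EH[hp.K1 + hp.K2 :]
    H2_post = postprocess_h2(H2)
    return FitResult(H1, H2, H2_post, H3, trace, state, converged, posterior)


def postprocess_h2(H2: np.ndarray, alpha_level: float = 0.05) -> np.ndarray:
    """Drop zero-mean rows of E(H2) and winsorize the survivors.

    Each row is tested with a two-sided one-sample t-test against mean
    zero (no multiple-testing correction — K2 is small); rows that do not
    reject at ``alpha_level`` are discarded.  Remaining rows are clamped at
    their own 5th and 95th percentiles (linear-interpolation percentiles),
    which damps the handful of noisy low-depth cells that can dominate a
    component.
    """
    H2 = np.atleast_2d(np.asarray(H2, dtype=np.float64))
    n = H2.shape[1]
    if n < 3:
        raise ValueError("need at least 3 cells for the zero-mean t-test")
    kept = []
    for row in H2:
        sd = row.std(ddof=1)
        if sd < 1e-8:
            # constant row: keep only a genuinely displaced one; a pruned
            # (all-but-zero) component is numeric residue, not signal
            reject = abs(row.mean()) > 1e-6
        else:
            reject = stats.ttest_1samp(row, 0.0).pvalue < alpha_level
        if reject:
            lo, hi = np.percentile(row, [5, 95])
            kept.append(np.clip(row, lo, hi))
    if not kept:
        logger.warning("post-processing dropped every H2 row (all zero-mean)")
        return np.empty((0, n))
    return np.vstack(kept)


def latent_representation(fit_result: FitResult) -> np.ndarray:
    """Downstream representation: E(H1) stacked over post-processed E(H2)."""
    if fit_result.H2_post.shape[0] == 0:
        return fit_result.H1.copy()
    return np.vstack([fit_result.H1, fit_result.H2_post])


def latent_row_names(fit_result: FitResult) -> list[str]:
    k1 = fit_result.H1.shape[0]
    k2p = fit_result.H2_post.shape[0]
    return [f"H1_{i + 1}" for i in range(k1)] + [f"H2_{i + 1}" for i in range(k2p)]
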
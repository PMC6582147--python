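"""Closed-form Bayesian linear mixed model for fine-mapping.

The model for a phenotype vector ``y`` of length ``n`` is

    y = X b + Z a + g + e
    b ~ N(0, phi   * sigma_e^2 * I)     covariates (intercept included)
    a ~ N(0, gamma * sigma_e^2 * I)     candidate-variant effects
    g ~ N(0, eta   * sigma_e^2 * G)     polygenic effect, G a relationship matrix
    e ~ N(0,         sigma_e^2 * R)     residual, R diagonal with differential
                                        weights from phenotype reliability
    P(sigma_e^2) proportional to 1/sigma_e^2   (Jeffreys prior)

phi, gamma and eta are treated as known variance ratios; eta relates to
heritability by eta = h^2 / (1 - h^2).  A reliability r^2 in (0, 1] maps to
the residual weight R_ii = 1/r^2 - 1 (floored, see ``reliability_to_weight``).

After whitening with M = (eta*G + R)^(-1/2) the residual covariance is
sigma_e^2 * I and the marginal likelihood P(D|M) — all effects and
sigma_e^2 integrated out — has the closed form implemented in
``log_marginal_likelihood``.  Bayes factors between nested variant sets and
large-phi/gamma frequentist p-values (partial F-tests on the whitened data)
follow from it.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import linalg, special, stats

__all__ = [
    "ModelSpec",
    "WhitenedData",
    "ModelFit",
    "Whitener",
    "make_eta",
    "eta_to_h2",
    "reliability_to_weight",
    "whiten",
    "log_marginal_likelihood",
    "log_bayes_factor",
    "conditional_test",
    "fit_null_reml",
    "sample_null_log_bf",
]

DEFAULT_PHI = 1e8
DEFAULT_GAMMA = 1e8
RELIABILITY_FLOOR = 1e-6
EIG_REL_TOL = 1e-10
COLLINEARITY_R = 0.9999


class ConditioningError(np.linalg.LinAlgError):
    """eta*G + R (or a model Gram matrix) is singular beyond tolerance."""


class DegenerateVariantError(ValueError):
    """Candidate variant is constant or collinear after whitening."""


def make_eta(h2: float) -> float:
    """Polygenic variance ratio eta = h^2 / (1 - h^2) for h^2 in [0, 1)."""
    if not 0.0 <= h2 < 1.0:
        raise ValueError(f"h2 must be in [0, 1), got {h2}")
    return h2 / (1.0 - h2)


def eta_to_h2(eta: float) -> float:
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    return eta / (1.0 + eta)


def reliability_to_weight(r2, floor: float = RELIABILITY_FLOOR):
    """Residual weight R_ii = 1/r^2 - 1 for reliability r^2 in (0, 1].

    Perfect reliability gives a zero weight, which would make the residual
    covariance singular when eta = 0; the result is floored at ``floor``.
    Accepts scalars or arrays.
    """
    r2 = np.asarray(r2, dtype=float)
    if np.any(r2 <= 0) or np.any(r2 > 1):
        raise ValueError("reliability must lie in (0, 1]")
    w = np.maximum(1.0 / r2 - 1.0, floor)
    return float(w) if w.ndim == 0 else w


@dataclasses.dataclass
class ModelSpec:
    """Design and variance structure for one marginal-likelihood evaluation.

    ``covariates`` must include the intercept column.  ``relatedness`` may be
    None (eta is then ignored), a dense symmetric PSD matrix, or a
    precomputed ``(eigenvalues, eigenvectors)`` pair.
    """

    covariates: np.ndarray
    variants: np.ndarray | None = None
    relatedness: np.ndarray | tuple | None = None
    residual_weights: np.ndarray | float = 1.0
    phi: float = DEFAULT_PHI
    gamma: float = DEFAULT_GAMMA
    eta: float = 0.0

    def __post_init__(self):
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] == 1 and self.covariates.shape[1] > 1:
            self.covariates = self.covariates.T
        n = self.covariates.shape[0]
        if self.variants is None:
            self.variants = np.empty((n, 0))
        self.variants = np.asarray(self.variants, dtype=float).reshape(n, -1)
        self.residual_weights = np.broadcast_to(
            np.asarray(self.residual_weights, dtype=float), (n,)
        ).copy()
        if np.any(self.residual_weights <= 0) or not np.all(
            np.isfinite(self.residual_weights)
        ):
            raise ValueError("residual weights must be strictly positive and finite")
        if self.phi <= 0 or self.gamma <= 0:
            raise ValueError("phi and gamma must be positive")
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")

    @property
    def n(self) -> int:
        return self.covariates.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_variants(self) -> int:
        return self.variants.shape[1]

    def with_variants(self, variants) -> "ModelSpec":
        return dataclasses.replace(self, variants=variants)


@dataclasses.dataclass
class WhitenedData:
    transformed_response: np.ndarray
    transformed_design: np.ndarray
    log_jacobian: float
    n_effective: int


@dataclasses.dataclass
class ModelFit:
    """Result of testing a variant (or variant set) against a nested null."""

    log_marginal: float
    log_bf: float
    scaled_log_bf: float
    p_value: float
    beta: float = np.nan
    se: float = np.nan


class Whitener:
    """Factorisation of V = eta*G + R, reused across variant models.

    Computes M = V^(-1/2) by symmetric eigendecomposition; eigenvalues of G
    below -tol are clipped to zero, eigenvalues of V below
    ``EIG_REL_TOL * max`` raise a conditioning error.
    """

    def __init__(self, eta: float, relatedness, residual_weights: np.ndarray):
        w = np.asarray(residual_weights, dtype=float)
        n = w.shape[0]
        self.n = n
        if eta == 0.0 or relatedness is None:
            self._diagonal = True
            self._m_diag = 1.0 / np.sqrt(w)
            self.log_det = float(np.sum(np.log(w)))
            return
        self._diagonal = False
        if isinstance(relatedness, tuple):
            evals, evecs = relatedness
            G = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
        else:
            G = np.asarray(relatedness, dtype=float)
            if G.shape != (n, n):
                raise ValueError("relatedness matrix not conformable")
            G = 0.5 * (G + G.T)
        V = eta * G + np.diag(w)
        evals, evecs = linalg.eigh(V)
        top = evals[-1]
        if top <= 0 or evals[0] < -EIG_REL_TOL * top * 10:
            raise ConditioningError("eta*G + R is not positive definite")
        floor = EIG_REL_TOL * top
        if np.any(evals < floor) and np.all(evals < floor):
            raise ConditioningError("eta*G + R singular beyond tolerance")
        evals = np.maximum(evals, floor)
        self._evecs = evecs
        self._inv_sqrt = 1.0 / np.sqrt(evals)
        self.log_det = float(np.sum(np.log(evals)))

    @property
    def log_jacobian(self) -> float:
        return -0.5 * self.log_det

    def apply(self, arr: np.ndarray) -> np.ndarray:
        """M @ arr for a vector or (n x k) matrix."""
        arr = np.asarray(arr, dtype=float)
        if self._diagonal:
            return arr * (self._m_diag if arr.ndim == 1 else self._m_diag[:, None])
        rotated = self._evecs.T @ arr
        rotated *= self._inv_sqrt if arr.ndim == 1 else self._inv_sqrt[:, None]
        return self._evecs @ rotated


def whiten(y: np.ndarray, spec: ModelSpec) -> WhitenedData:
    """Transform y and [X | Z] so the residual covariance is sigma_e^2 I."""
    y = np.asarray(y, dtype=float)
    wh = Whitener(spec.eta, spec.relatedness, spec.residual_weights)
    design = np.hstack([spec.covariates, spec.variants])
    return WhitenedData(
        transformed_response=wh.apply(y),
        transformed_design=wh.apply(design),
        log_jacobian=wh.log_jacobian,
        n_effective=spec.n,
    )


def _log_marginal_whitened(
    y_w: np.ndarray,
    design_w: np.ndarray,
    prior_ratios: np.ndarray,
    log_jacobian: float,
) -> float:
    """log P(D|M) on whitened data; prior_ratios holds phi/gamma per column.

    With W the whitened design and D = diag(prior_ratios),
    y_w ~ N(0, sigma^2 (I + W D W')) and integrating sigma^2 against the
    Jeffreys prior gives

      log P = logJ - n/2 log(pi) + lgamma(n/2) - 1/2 log|I + W D W'| - n/2 log Q

    with Q = y' (I + W D W')^{-1} y, evaluated via the Woodbury identity.
    """
    n = y_w.shape[0]
    q = design_w.shape[1]
    if n <= q:
        raise ValueError(f"need n > c + k ({n} <= {q})")
    yty = float(y_w @ y_w)
    if q == 0:
        logdet = 0.0
        quad = yty
    else:
        A = design_w.T @ design_w + np.diag(1.0 / prior_ratios)
        try:
            cho = linalg.cho_factor(A, lower=True)
        except np.linalg.LinAlgError as err:
            raise ConditioningError("model Gram matrix not positive definite") from err
        wy = design_w.T @ y_w
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0]))) + float(
            np.sum(np.log(prior_ratios))
        )
        quad = yty - float(wy @ linalg.cho_solve(cho, wy))
    if quad <= 0:
        raise ConditioningError("non-positive residual quadratic form")
    return (
        log_jacobian
        - 0.5 * n * math.log(math.pi)
        + special.gammaln(0.5 * n)
        - 0.5 * logdet
        - 0.5 * n * math.log(quad)
    )


def log_marginal_likelihood(y: np.ndarray, spec: ModelSpec) -> float:
    """Closed-form log P(D|M) for model spec (all effects integrated out).

    The additive constant depends only on n and the whitening, so
    differences between nested variant models on the same spec are exact
    log Bayes factors.
    """
    wd = whiten(y, spec)
    ratios = np.concatenate(
        [
            np.full(spec.n_covariates, spec.phi),
            np.full(spec.n_variants, spec.gamma),
        ]
    )
    return _log_marginal_whitened(
        wd.transformed_response, wd.transformed_design, ratios, wd.log_jacobian
    )


def log_bayes_factor(y: np.ndarray, spec: ModelSpec) -> float:
    """log BF of spec's variant model against the same spec with no variants."""
    if spec.n_variants == 0:
        return 0.0
    null = spec.with_variants(np.empty((spec.n, 0)))
    return log_marginal_likelihood(y, spec) - log_marginal_likelihood(y, null)


def scaled_log_bf(log_bf: float, gamma: float, k: int = 1) -> float:
    """Scale-normalised log Bayes factor with a finite large-gamma limit."""
    return log_bf + 0.5 * k * math.log(gamma)


def conditional_test(
    y: np.ndarray,
    spec: ModelSpec,
    new_variant: np.ndarray,
    current_leads: np.ndarray | None = None,
    backend: str = "ftest",
    n_null_draws: int = 100_000,
    rng: np.random.Generator | None = None,
) -> ModelFit:
    """Test a new variant conditional on variants already in the model.

    Returns the log Bayes factor of adding ``new_variant`` to the model
    holding ``current_leads`` and, with ``backend='ftest'``, the partial
    F-test (1 df) p-value on the whitened data — the exact frequentist limit
    of the Bayes factor as phi, gamma -> infinity.  ``backend='null-bf'``
    instead locates the observed scaled Bayes factor in a Monte-Carlo sample
    of null Bayes factors.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(new_variant, dtype=float).reshape(-1)
    if current_leads is None:
        leads = np.empty((spec.n, 0))
    else:
        leads = np.asarray(current_leads, dtype=float).reshape(spec.n, -1)

    wh = Whitener(spec.eta, spec.relatedness, spec.residual_weights)
    y_w = wh.apply(y)
    base_w = wh.apply(np.hstack([spec.covariates, leads]))
    v_w = wh.apply(v)

    # collinearity / degeneracy guard on the whitened scale
    q0, _ = np.linalg.qr(base_w)
    resid_v = v_w - q0 @ (q0.T @ v_w)
    vnorm = float(v_w @ v_w)
    rnorm = float(resid_v @ resid_v)
    if vnorm <= 0 or rnorm <= (1.0 - COLLINEARITY_R**2) * vnorm:
        raise DegenerateVariantError(
            "variant is constant or collinear with the model after whitening"
        )

    c = base_w.shape[1]
    n = y_w.shape[0]
    df_resid = n - c - 1
    if df_resid <= 0:
        raise ValueError("insufficient data for conditional test")

    ratios0 = np.concatenate(
        [np.full(spec.n_covariates, spec.phi), np.full(leads.shape[1], spec.gamma)]
    )
    lm0 = _log_marginal_whitened(y_w, base_w, ratios0, wh.log_jacobian)
    lm1 = _log_marginal_whitened(
        y_w,
        np.hstack([base_w, v_w[:, None]]),
        np.append(ratios0, spec.gamma),
        wh.log_jacobian,
    )
    lbf = lm1 - lm0
    slbf = scaled_log_bf(lbf, spec.gamma)

    # OLS on whitened data: partial F-test for the added column
    resid_y = y_w - q0 @ (q0.T @ y_w)
    rss0 = float(resid_y @ resid_y)
    coef = float(resid_v @ resid_y) / rnorm
    rss1 = rss0 - coef**2 * rnorm
    rss1 = max(rss1, 0.0)
    sigma2 = rss1 / df_resid
    se = math.sqrt(sigma2 / rnorm) if sigma2 > 0 else 0.0

    if backend == "ftest":
        if sigma2 <= 0:
            p = 0.0 if coef != 0 else 1.0
        else:
            fstat = (rss0 - rss1) / sigma2
            p = float(stats.f.sf(fstat, 1, df_resid))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
    elif backend == "null-bf":
        rng = np.random.default_rng(rng)
        null_slbf = sample_null_log_bf(
            base_w, v_w, spec, wh.log_jacobian, n_null_draws, rng
        )
        p = float((np.sum(null_slbf >= slbf) + 1) / (n_null_draws + 1))
    else:
        raise ValueError(f"unknown backend {backend!r}")

    return ModelFit(
        log_marginal=lm1,
        log_bf=lbf,
        scaled_log_bf=slbf,
        p_value=p,
        beta=coef,
        se=se,
    )


def sample_null_log_bf(
    base_w: np.ndarray,
    v_w: np.ndarray,
    spec: ModelSpec,
    log_jacobian: float,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo sample of scaled log Bayes factors under H0: a = 0.

    Null responses are drawn from the whitened null model (covariates and
    current leads with their Gaussian priors, sigma_e^2 = 1; the Bayes
    factor is scale-invariant so the unit variance is general).
    """
    n, c = base_w.shape
    ratios0 = np.concatenate(
        [np.full(spec.n_covariates, spec.phi), np.full(c - spec.n_covariates, spec.gamma)]
    )
    out = np.empty(n_draws)
    sd_effects = np.sqrt(ratios0)
    for i in range(n_draws):
        effects = rng.standard_normal(c) * sd_effects
        y0 = base_w @ effects + rng.standard_normal(n)
        lm0 = _log_marginal_whitened(y0, base_w, ratios0, log_jacobian)
        lm1 = _log_marginal_whitened(
            y0,
            np.hstack([base_w, v_w[:, None]]),
            np.append(ratios0, spec.gamma),
            log_jacobian,
        )
        out[i] = scaled_log_bf(lm1 - lm0, spec.gamma)
    return out


# ---------------------------------------------------------------------------
# Null-model REML for eta / heritability
# ---------------------------------------------------------------------------

def _reml_profile(eta, s, Xr, yr, weights_cache=None):
    """Restricted log-likelihood (up to a constant) at variance ratio eta."""
    w = 1.0 / (eta * s + 1.0)
    n, c = Xr.shape
    XtWX = Xr.T @ (w[:, None] * Xr)
    XtWy = Xr.T @ (w * yr)
    try:
        cho = linalg.cho_factor(XtWX)
    except np.linalg.LinAlgError:
        return -np.inf
    beta = linalg.cho_solve(cho, XtWy)
    resid = yr - Xr @ beta
    rss = float(resid @ (w * resid))
    if rss <= 0:
        return -np.inf
    logdet_v = -float(np.sum(np.log(w)))
    logdet_x = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    return -0.5 * (logdet_v + logdet_x + (n - c) * math.log(rss))


def fit_null_reml(
    y: np.ndarray,
    covariates: np.ndarray,
    relatedness,
    residual_weights: np.ndarray | float = 1.0,
    grid_size: int = 64,
    eta_bounds: tuple[float, float] = (1e-5, 1e5),
) -> dict:
    """Estimate eta = sigma_g^2/sigma_e^2 in the null model by profile REML.

    The model is y = X b + g + e with g ~ N(0, eta sigma_e^2 G) and
    e ~ N(0, sigma_e^2 R).  After scaling by R^(-1/2) and rotating into the
    eigenbasis of R^(-1/2) G R^(-1/2), the covariance is diagonal in eta and
    the restricted likelihood is maximised over a log-spaced grid (eta = 0
    included) followed by golden-section refinement.

    Returns a dict with eta, h2 = eta/(1+eta), sigma_e2, sigma_g2, loglik.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, c = X.shape
    w = np.broadcast_to(np.asarray(residual_weights, dtype=float), (n,))
    rsqi = 1.0 / np.sqrt(w)
    if relatedness is None:
        s = np.zeros(n)
        Xr, yr = rsqi[:, None] * X, rsqi * y
    else:
        if isinstance(relatedness, tuple):
            evals, evecs = relatedness
            G = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
        else:
            G = np.asarray(relatedness, dtype=float)
        K = rsqi[:, None] * G * rsqi[None, :]
        s, U = linalg.eigh(0.5 * (K + K.T))
        s = np.clip(s, 0.0, None)
        Xr = U.T @ (rsqi[:, None] * X)
        yr = U.T @ (rsqi * y)

    grid = np.concatenate(
        [[0.0], np.geomspace(eta_bounds[0], eta_bounds[1], grid_size)]
    )
    lls = np.array([_reml_profile(g, s, Xr, yr) for g in grid])
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if hi > lo:
        # golden-section on [lo, hi]
        invphi = (math.sqrt(5) - 1) / 2
        a, b = lo, hi
        x1 = b - invphi * (b - a)
        x2 = a + invphi * (b - a)
        f1 = _reml_profile(x1, s, Xr, yr)
        f2 = _reml_profile(x2, s, Xr, yr)
        for _ in range(60):
            if f1 < f2:
                a, x1, f1 = x1, x2, f2
                x2 = a + invphi * (b - a)
                f2 = _reml_profile(x2, s, Xr, yr)
            else:
                b, x2, f2 = x2, x1, f1
                x1 = b - invphi * (b - a)
                f1 = _reml_profile(x1, s, Xr, yr)
            if b - a < 1e-8 * (1 + b):
                break
        eta_hat = (a + b) / 2
        ll_hat = _reml_profile(eta_hat, s, Xr, yr)
        if lls[best] > ll_hat:
            eta_hat, ll_hat = grid[best], lls[best]
    else:
        eta_hat, ll_hat = grid[best], lls[best]

    wgt = 1.0 / (eta_hat * s + 1.0)
    XtWX = Xr.T @ (wgt[:, None] * Xr)
    beta = np.linalg.solve(XtWX, Xr.T @ (wgt * yr))
    resid = yr - Xr @ beta
    sigma_e2 = float(resid @ (wgt * resid)) / (n - c)
    return {
        "eta": float(eta_hat),
        "h2": eta_to_h2(float(eta_hat)),
        "sigma_e2": sigma_e2,
        "sigma_g2": float(eta_hat) * sigma_e2,
        "loglik": float(ll_hat),
    }
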
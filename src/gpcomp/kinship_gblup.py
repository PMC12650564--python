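"""Genomic relationship matrices, REML variance components, and GBLUP.

Two kinship flavors are supported: the allele-frequency-centered matrix
W W' / sum(2 p q) built from raw dosages, and X X' / n_columns built
from column-standardized compressed features.  Variance components come
from an eigendecomposition REML profile over the heritability of a
single genomic random effect; breeding values solve Henderson's
mixed-model equations with validation phenotypes masked.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from gpcomp.autoencoder import CompressedMatrix
from gpcomp.errors import ConsistencyError, EmptyDataError, InputError, NumericalError
from gpcomp.genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    """Symmetric n x n relationship matrix with provenance."""

    values: np.ndarray
    flavor: str  # "vanraden" | "compressed"
    n_features: int  # marker count or compressed dimension d

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ConsistencyError("kinship matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ConsistencyError("kinship matrix is not symmetric")
        self.values = (v + v.T) / 2.0  # kill rounding asymmetry

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def stabilized(self, tol: float = -1e-8, bump: float = 1e-6) -> np.ndarray:
        """Values with a small diagonal bump if the matrix is indefinite."""
        eigmin = float(np.linalg.eigvalsh(self.values)[0])
        if eigmin < tol:
            logger.info(
                "kinship smallest eigenvalue %.3g < 0; adding %.1g to diagonal",
                eigmin, bump,
            )
            return self.values + bump * np.eye(self.n)
        return self.values


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    log_likelihood: float

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_e2 <= 0:
            raise NumericalError("variance components out of range")

    @property
    def h2(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)

    @property
    def ratio(self) -> float:
        """lambda = sigma_e2 / sigma_a2 used in the MME."""
        return self.sigma_e2 / max(self.sigma_a2, 1e-12)


@dataclass
class GBLUPResult:
    fixed_effects: np.ndarray
    breeding_values: np.ndarray  # one GEBV per individual in kinship order

    @property
    def gebv(self) -> np.ndarray:
        return self.breeding_values


# ---------------------------------------------------------------------------
# kinship construction


def vanraden_g(g: GenotypeMatrix | np.ndarray) -> KinshipMatrix:
    """Allele-frequency-centered relationship matrix W W' / sum(2 p q).

    p_j is the alt-allele frequency computed from the supplied data
    (reference and candidates together); W subtracts 2 p_j per marker.
    """
    m = g.values if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    if (m == MISSING).any():
        raise InputError("kinship requires a complete dosage matrix")
    m = np.asarray(m, dtype=float)
    p = m.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise EmptyDataError("need at least 2 polymorphic markers")
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    w = m - 2.0 * p
    return KinshipMatrix(w @ w.T / denom, "vanraden", m.shape[1])


def compressed_g(
    x: CompressedMatrix | np.ndarray, ddof: int = 1
) -> KinshipMatrix:
    """Relationship matrix X X' / n_cols from standardized features.

    Columns are scaled to mean 0 and unit variance (sample variance by
    default, ``ddof=0`` for population variance); zero-variance columns
    are dropped with a logged count.
    """
    vals = x.values if isinstance(x, CompressedMatrix) else np.asarray(x, dtype=float)
    vals = np.asarray(vals, dtype=float)
    if vals.shape[1] < 2:
        raise EmptyDataError("need at least 2 feature columns")
    sd = vals.std(axis=0, ddof=ddof)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d zero-variance feature columns", n_dropped)
    if not keep.any():
        raise EmptyDataError("every feature column has zero variance")
    z = (vals[:, keep] - vals[:, keep].mean(axis=0)) / sd[keep]
    n_cols = int(keep.sum())
    return KinshipMatrix(z @ z.T / n_cols, "compressed", n_cols)


def compare_g(
    g1: KinshipMatrix | np.ndarray,
    g2: KinshipMatrix | np.ndarray,
    include_diagonal: bool = False,
) -> float:
    """Pearson correlation of (strictly, by default) upper-triangle entries."""
    a = g1.values if isinstance(g1, KinshipMatrix) else np.asarray(g1, dtype=float)
    b = g2.values if isinstance(g2, KinshipMatrix) else np.asarray(g2, dtype=float)
    if a.shape != b.shape:
        raise ConsistencyError(f"shape mismatch {a.shape} vs {b.shape}")
    iu = np.triu_indices(a.shape[0], k=0 if include_diagonal else 1)
    return float(np.corrcoef(a[iu], b[iu])[0, 1])


# ---------------------------------------------------------------------------
# REML via eigendecomposition of G


def _reml_profile(
    h2: float, lam_d: np.ndarray, ystar: np.ndarray, xstar: np.ndarray
) -> tuple[float, float, float]:
    """Profiled restricted log-likelihood at a given h2.

    With G = U diag(lam_d) U', V = sigma_a2 * D + sigma_e2 * I becomes
    diagonal in the rotated basis; the total variance profiles out
    analytically.  Returns (restricted ll, sigma_a2, sigma_e2).
    """
    n, p = xstar.shape
    v = h2 * lam_d + (1.0 - h2)  # V / sigma_p2 eigenvalues
    v = np.maximum(v, 1e-12)
    vinv = 1.0 / v
    xtvx = xstar.T @ (vinv[:, None] * xstar)
    xtvy = xstar.T @ (vinv * ystar)
    try:
        beta = np.linalg.solve(xtvx, xtvy)
    except np.linalg.LinAlgError:
        return -np.inf, 0.0, 1.0
    resid = ystar - xstar @ beta
    quad = float(resid @ (vinv * resid))
    sigma_p2 = quad / (n - p)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0 or sigma_p2 <= 0:
        return -np.inf, 0.0, 1.0
    ll = -0.5 * (
        (n - p) * np.log(sigma_p2)
        + np.log(v).sum()
        + logdet_xtvx
        + (n - p)
    )
    return float(ll), h2 * sigma_p2, (1.0 - h2) * sigma_p2


def reml_variance_components(
    y: np.ndarray,
    x: np.ndarray | None,
    g: KinshipMatrix,
    max_iter: int = 200,
) -> VarianceComponents:
    """REML estimates of (sigma_a2, sigma_e2) for y = X b + a + e.

    Single genomic random effect; 1-D bounded optimization of the
    profiled restricted likelihood over h2 after rotating into the
    eigenbasis of G.  ``x`` defaults to an intercept column.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise InputError("need at least 10 phenotyped individuals for REML")
    if np.isnan(y).any():
        raise InputError("REML received missing phenotypes; subset first")
    if g.n != n:
        raise ConsistencyError("kinship dimension does not match phenotypes")
    x = np.ones((n, 1)) if x is None else np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != n:
        raise ConsistencyError("design matrix rows do not match phenotypes")

    lam_d, u = np.linalg.eigh(g.stabilized())
    ystar = u.T @ y
    xstar = u.T @ x

    if np.ptp(lam_d) < 1e-10:
        warnings.warn(
            "kinship is (a multiple of) the identity: sigma_a2 and sigma_e2 "
            "are not separately identifiable; returning the boundary fit",
            stacklevel=2,
        )

    def neg_ll(h2: float) -> float:
        return -_reml_profile(h2, lam_d, ystar, xstar)[0]

    res = optimize.minimize_scalar(
        neg_ll, bounds=(1e-6, 1.0 - 1e-6), method="bounded",
        options={"maxiter": max_iter, "xatol": 1e-8},
    )
    if not res.success:
        raise NumericalError(f"REML did not converge: {res.message}")
    ll, sigma_a2, sigma_e2 = _reml_profile(float(res.x), lam_d, ystar, xstar)
    # also probe the h2 -> 0 boundary, where the profile can be flat
    ll0, sa0, se0 = _reml_profile(1e-9, lam_d, ystar, xstar)
    if ll0 >= ll:
        warnings.warn("sigma_a2 estimate pinned at the zero boundary", stacklevel=2)
        return VarianceComponents(max(sa0, 0.0), se0, ll0)
    return VarianceComponents(sigma_a2, sigma_e2, ll)


# ---------------------------------------------------------------------------
# mixed-model equations


def solve_mme(
    y: np.ndarray,
    x: np.ndarray | None,
    g: KinshipMatrix,
    vc: VarianceComponents,
    observed_mask: np.ndarray | None = None,
) -> GBLUPResult:
    """Henderson MME for y = X b + Z a + e with a ~ N(0, G sigma_a2).

    ``observed_mask`` selects individuals whose phenotypes enter the
    equations; everyone in G receives a breeding value through their
    genomic relationships.  Fixed effects default to the overall mean.

    Solved in the variance form ``a = sigma_a2 G Z' V^{-1} (y - X b)``
    with ``V = Z G Z' sigma_a2 + I sigma_e2`` rather than by inverting
    G, so singular kinships (rank-deficient centered marker matrices)
    are handled exactly; the solution coincides with Henderson's
    equations whenever G is invertible.
    """
    y = np.asarray(y, dtype=float)
    n_all = g.n
    observed_mask = (
        np.ones(n_all, dtype=bool)
        if observed_mask is None
        else np.asarray(observed_mask, dtype=bool)
    )
    if observed_mask.size != n_all:
        raise ConsistencyError("observed mask length does not match kinship")
    obs = np.flatnonzero(observed_mask)
    if obs.size == 0:
        raise EmptyDataError("no observed phenotypes")
    y_obs = y[obs] if y.size == n_all else y
    if y_obs.size != obs.size:
        raise ConsistencyError("phenotype vector does not match observed mask")
    if np.isnan(y_obs).any():
        raise InputError("observed phenotypes contain NaN")

    x_full = np.ones((n_all, 1)) if x is None else np.atleast_2d(np.asarray(x, float))
    x_obs = x_full[obs]
    p = x_obs.shape[1]
    if np.linalg.matrix_rank(x_obs) < p:
        raise NumericalError("fixed-effect design is rank deficient on observed rows")

    g_vals = g.values
    v = vc.sigma_a2 * g_vals[np.ix_(obs, obs)] + vc.sigma_e2 * np.eye(obs.size)
    try:
        v_chol = np.linalg.cholesky(v)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "singular phenotypic covariance; consider stabilizing the kinship "
            "diagonal"
        ) from exc

    def v_solve(b: np.ndarray) -> np.ndarray:
        return np.linalg.solve(v_chol.T, np.linalg.solve(v_chol, b))

    # GLS fixed effects, then BLUP of breeding values for everyone in G
    vinv_x = v_solve(x_obs)
    vinv_y = v_solve(y_obs)
    beta = np.linalg.solve(x_obs.T @ vinv_x, x_obs.T @ vinv_y)
    resid = v_solve(y_obs - x_obs @ beta)
    a_all = vc.sigma_a2 * g_vals[:, obs] @ resid
    return GBLUPResult(beta, a_all)


def gblup_predict(
    features: GenotypeMatrix | CompressedMatrix | np.ndarray,
    y: np.ndarray,
    observed_mask: np.ndarray | None = None,
    flavor: str | None = None,
) -> np.ndarray:
    """End-to-end GBLUP: build G, estimate variance components, solve MME.

    The kinship flavor follows the input type (dosages -> centered
    matrix, compressed features -> standardized matrix) unless forced
    with ``flavor``.  Variance components are estimated on observed
    individuals only; all individuals receive GEBVs.
    """
    if flavor is None:
        flavor = "vanraden" if isinstance(features, GenotypeMatrix) else "compressed"
    if isinstance(features, (GenotypeMatrix, CompressedMatrix)) or not isinstance(
        features, KinshipMatrix
    ):
        g = vanraden_g(features) if flavor == "vanraden" else compressed_g(features)
    else:
        g = features
    y = np.asarray(y, dtype=float)
    observed_mask = (
        ~np.isnan(y) if observed_mask is None else np.asarray(observed_mask, bool)
    )
    obs = np.flatnonzero(observed_mask)
    g_obs = KinshipMatrix(g.values[np.ix_(obs, obs)], g.flavor, g.n_features)
    vc = reml_variance_components(y[obs], None, g_obs)
    result = solve_mme(y[obs], None, g, vc, observed_mask)
    return result.breeding_values
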
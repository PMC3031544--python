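"""Data model and hidden multinomial-probit machinery.

The clustering model regresses latent cluster labels on per-individual
covariates through a multinomial probit: each individual carries K Gaussian
latent utilities

    y_ik = x_i' beta_k + eps_ik,      eps_ik iid N(0, 1),

and the label is the argmax over clusters.  One cluster (the *reference
cluster*) has its coefficient vector pinned at zero for identifiability, so
with all coefficients zero the membership distribution is uniform.

This module provides the containers (genotypes, design matrices, coefficient
sets, utilities, membership matrices), design-matrix construction with
trend-surface and effects-coded factor columns, the argmax label rule,
membership probabilities pi_k(x) by quadrature or Monte Carlo, the
truncated-normal utility refresh, and the conjugate coefficient update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import ndtr, ndtri

__all__ = [
    "GenotypeMatrix",
    "DesignMatrix",
    "CoefficientSet",
    "UtilityMatrix",
    "MembershipMatrix",
    "build_design",
    "utilities_to_label",
    "membership_probs",
    "sample_utilities",
    "update_beta",
    "latent_class_probs",
]

MISSING_CODE = -9

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Multilocus codominant genotypes for N diploid individuals at L loci.

    ``codes`` holds 0-based per-locus allele codes with shape (N, L, 2);
    positions flagged in ``missing_mask`` carry no information.
    ``allele_code_maps`` optionally records the original file codes per locus
    so that write-then-read round-trips are exact.
    """

    codes: np.ndarray
    missing_mask: np.ndarray
    n_alleles: np.ndarray
    individual_ids: list = field(default_factory=list)
    locus_ids: list = field(default_factory=list)
    populations: np.ndarray | None = None
    allele_code_maps: list | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.n_alleles = np.asarray(self.n_alleles, dtype=np.int64)
        if self.codes.ndim != 3 or self.codes.shape[2] != 2:
            raise ValueError("codes must have shape (N, L, 2)")
        if self.missing_mask.shape != self.codes.shape:
            raise ValueError("missing_mask shape must match codes")
        if self.n_alleles.shape != (self.codes.shape[1],):
            raise ValueError("n_alleles must have one entry per locus")
        if np.any(self.n_alleles < 1):
            raise ValueError("each locus needs at least one allele")
        ok = self.missing_mask | (
            (self.codes >= 0) & (self.codes < self.n_alleles[None, :, None])
        )
        if not ok.all():
            raise ValueError("allele codes out of range for their locus")
        if not self.individual_ids:
            self.individual_ids = [f"ind{i:04d}" for i in range(self.n_individuals)]
        if not self.locus_ids:
            self.locus_ids = [f"loc{j:04d}" for j in range(self.n_loci)]

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    def subset_loci(self, locus_idx) -> "GenotypeMatrix":
        locus_idx = np.asarray(locus_idx, dtype=int)
        return GenotypeMatrix(
            codes=self.codes[:, locus_idx, :].copy(),
            missing_mask=self.missing_mask[:, locus_idx, :].copy(),
            n_alleles=self.n_alleles[locus_idx].copy(),
            individual_ids=list(self.individual_ids),
            locus_ids=[self.locus_ids[j] for j in locus_idx],
            populations=None if self.populations is None else self.populations.copy(),
            allele_code_maps=None
            if self.allele_code_maps is None
            else [self.allele_code_maps[j] for j in locus_idx],
        )


@dataclass
class DesignMatrix:
    """N x p covariate design with an intercept first and tagged columns.

    ``column_meta[j]`` is one of ``("intercept",)``,
    ``("continuous", <name>)`` or ``("factor", <factor>, <level>)``.
    Factors are effects-coded (sum-to-zero contrast): a factor with m
    observed levels contributes m-1 columns and the last level's rows are -1
    across all of them.
    """

    values: np.ndarray
    column_meta: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("design values must be 2-D")
        if len(self.column_meta) != self.values.shape[1]:
            raise ValueError("one metadata entry per column required")
        if self.column_meta[0] != ("intercept",) or not np.all(self.values[:, 0] == 1.0):
            raise ValueError("first column must be a constant intercept")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("design values must be finite")

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> list:
        names = []
        for meta in self.column_meta:
            if meta[0] == "intercept":
                names.append("intercept")
            elif meta[0] == "continuous":
                names.append(meta[1])
            else:
                names.append(f"{meta[1]}[{meta[2]}]")
        return names


@dataclass
class CoefficientSet:
    """K x p regression coefficients with the reference row pinned at zero."""

    beta: np.ndarray
    reference_cluster: int = 0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 2:
            raise ValueError("beta must be K x p")
        if not 0 <= self.reference_cluster < self.beta.shape[0]:
            raise ValueError("reference_cluster out of range")
        if np.any(self.beta[self.reference_cluster] != 0.0):
            raise ValueError("reference cluster coefficients must be exactly zero")

    @property
    def n_clusters(self) -> int:
        return self.beta.shape[0]


@dataclass
class UtilityMatrix:
    """Augmented N x K latent utilities; row argmax equals the label."""

    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("utilities must be N x K")

    def check_consistent(self, labels: np.ndarray) -> None:
        if not np.array_equal(self.y.argmax(axis=1), labels):
            raise AssertionError("utility argmax inconsistent with labels")


@dataclass
class MembershipMatrix:
    """Row-stochastic N x K membership probabilities."""

    q: np.ndarray
    kind: str = "estimated"

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if self.kind not in ("estimated", "predicted"):
            raise ValueError("kind must be 'estimated' or 'predicted'")
        if self.q.ndim != 2:
            raise ValueError("membership matrix must be N x K")
        if np.any(self.q < -1e-12) or np.any(self.q > 1 + 1e-12):
            raise ValueError("membership entries must lie in [0, 1]")
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def _standardize(col: np.ndarray, name: str) -> np.ndarray:
    col = np.asarray(col, dtype=float)
    if not np.all(np.isfinite(col)):
        raise ValueError(f"covariate '{name}' contains non-finite values")
    sd = col.std()
    if sd == 0.0:
        raise ValueError(f"covariate '{name}' is constant")
    return (col - col.mean()) / sd


def build_design(
    covariates: pd.DataFrame,
    geo_trend: str = "linear",
    factors=(),
    continuous=(),
) -> DesignMatrix:
    """Build the regression design from a per-individual covariate table.

    Parameters
    ----------
    covariates
        One row per individual.  Geographic trends use the ``latitude`` and
        ``longitude`` columns (decimal degrees or any continuous scale).
    geo_trend
        ``"none"``, ``"linear"`` (lat, long) or ``"quadratic"`` (adds lat^2,
        long^2, lat*long).  Continuous columns are centered and scaled to
        unit standard deviation *before* the polynomial expansion.
    factors
        Names of categorical columns; each factor with m observed levels
        contributes m-1 effects-coded columns (last level row = -1).
    continuous
        Extra continuous covariate names appended standardized, without
        polynomial expansion (e.g. a candidate spurious covariate).
    """
    if geo_trend not in ("none", "linear", "quadratic"):
        raise ValueError("geo_trend must be one of none/linear/quadratic")
    n = len(covariates)
    cols = [np.ones(n)]
    meta: list = [("intercept",)]

    if geo_trend != "none":
        for name in ("latitude", "longitude"):
            if name not in covariates.columns:
                raise ValueError(f"geo_trend='{geo_trend}' requires column '{name}'")
        lat = _standardize(covariates["latitude"].to_numpy(), "latitude")
        lon = _standardize(covariates["longitude"].to_numpy(), "longitude")
        cols += [lat, lon]
        meta += [("continuous", "latitude"), ("continuous", "longitude")]
        if geo_trend == "quadratic":
            cols += [lat**2, lon**2, lat * lon]
            meta += [
                ("continuous", "latitude^2"),
                ("continuous", "longitude^2"),
                ("continuous", "latitude*longitude"),
            ]

    for name in continuous:
        cols.append(_standardize(covariates[name].to_numpy(), name))
        meta.append(("continuous", name))

    for fac in factors:
        levels = sorted(pd.unique(covariates[fac].astype(str)))
        if len(levels) < 2:
            raise ValueError(f"factor '{fac}' has a single observed level")
        codes = covariates[fac].astype(str).to_numpy()
        last = levels[-1]
        for lev in levels[:-1]:
            col = np.where(codes == lev, 1.0, 0.0)
            col[codes == last] = -1.0
            cols.append(col)
            meta.append(("factor", fac, lev))

    return DesignMatrix(values=np.column_stack(cols), column_meta=meta)


# ---------------------------------------------------------------------------
# Label rule and membership probabilities
# ---------------------------------------------------------------------------


def utilities_to_label(y_i: np.ndarray) -> int:
    """Argmax label rule; ties (a measure-zero event) break to the lowest index."""
    y_i = np.asarray(y_i, dtype=float)
    if np.any(np.isnan(y_i)):
        raise ValueError("utilities contain NaN")
    return int(np.argmax(y_i))


# Gauss-Hermite rule for E[f(T)], T ~ N(0,1); hermegauss uses weight e^{-t^2/2}.
_GH_CACHE: dict = {}


def _gh_rule(n_nodes: int):
    if n_nodes not in _GH_CACHE:
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
        _GH_CACHE[n_nodes] = (nodes, weights / weights.sum())
    return _GH_CACHE[n_nodes]


# Piecewise-linear table for the standard normal CDF on [-8, 8] (step 1/512;
# interpolation error < 2e-7, far below the Gauss-Hermite truncation error).
# Used only in the sampler's inner loop, where Phi is evaluated ~1e5 times
# per sweep and the libm-backed ndtr dominates the runtime.
_PHI_LO = -8.0
_PHI_STEP = 1.0 / 512.0
_PHI_N = int(16.0 / _PHI_STEP) + 1
_PHI_TAB = ndtr(_PHI_LO + _PHI_STEP * np.arange(_PHI_N)).astype(np.float32)
_PHI_DIFF = np.diff(_PHI_TAB, append=_PHI_TAB[-1]).astype(np.float32)
_PHI_INV_STEP = np.float32(1.0 / _PHI_STEP)


def _phi_table(x: np.ndarray) -> np.ndarray:
    """Fast vectorized Phi via table lookup with linear interpolation."""
    t = (x - np.float32(_PHI_LO)) * _PHI_INV_STEP
    np.clip(t, 0.0, _PHI_N - 1.001, out=t)
    idx = t.astype(np.int32)
    frac = t - idx
    return _PHI_TAB[idx] + frac * _PHI_DIFF[idx]


try:  # optional acceleration; the numpy path below is the reference
    from numba import njit as _njit

    @_njit(cache=True, fastmath=False)
    def _probs_kernel(m, nodes, weights, tab, dtab, lo, inv_step, tmax):  # pragma: no cover
        N, K = m.shape
        G = nodes.shape[0]
        out = np.empty((N, K), dtype=np.float32)
        for i in range(N):
            for k in range(K):
                acc = 0.0
                for g in range(G):
                    base = m[i, k] + nodes[g]
                    prod = weights[g]
                    for j in range(K):
                        if j != k:
                            t = (base - m[i, j] - lo) * inv_step
                            if t < 0.0:
                                t = 0.0
                            elif t > tmax:
                                t = tmax
                            it = int(t)
                            prod *= tab[it] + (t - it) * dtab[it]
                    acc += prod
                out[i, k] = acc
        return out

    @_njit(cache=True, fastmath=False)
    def _rows_kernel(m, labels, nodes, weights, tab, dtab, lo, inv_step, tmax):  # pragma: no cover
        N, K = m.shape
        G = nodes.shape[0]
        out = np.empty(N, dtype=np.float32)
        for i in range(N):
            k = labels[i]
            acc = 0.0
            for g in range(G):
                base = m[i, k] + nodes[g]
                prod = weights[g]
                for j in range(K):
                    if j != k:
                        t = (base - m[i, j] - lo) * inv_step
                        if t < 0.0:
                            t = 0.0
                        elif t > tmax:
                            t = tmax
                        it = int(t)
                        prod *= tab[it] + (t - it) * dtab[it]
                acc += prod
            out[i] = acc
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _latent_probs_fast(means: np.ndarray, n_nodes: int = 13) -> np.ndarray:
    """Table-lookup float32 variant of :func:`latent_class_probs` (N, K)."""
    m = np.ascontiguousarray(means, dtype=np.float32)
    nodes, weights = _gh_rule(n_nodes)
    if _HAVE_NUMBA:
        pi = _probs_kernel(
            m,
            nodes.astype(np.float32),
            weights.astype(np.float32),
            _PHI_TAB,
            _PHI_DIFF,
            np.float32(_PHI_LO),
            _PHI_INV_STEP,
            np.float32(_PHI_N - 1.001),
        )
        return pi.astype(np.float64)
    K = m.shape[1]
    diff = m[:, :, None] - m[:, None, :]
    arg = diff[..., None] + nodes.astype(np.float32)
    phi = _phi_table(arg)
    idx = np.arange(K)
    phi[:, idx, idx, :] = 1.0
    pi = phi.prod(axis=2) @ weights.astype(np.float32)
    return pi.astype(np.float64)


def _latent_logprob_rows(means: np.ndarray, labels: np.ndarray, n_nodes: int = 13):
    """log pi_{i, z_i}(beta) for each row, without the full N x K matrix.

    Needs only the z_i-th slice of the pairwise-difference tensor, so it is
    ~K times cheaper than :func:`_latent_probs_fast`; used by the collapsed
    Metropolis coefficient moves.
    """
    m = np.ascontiguousarray(means, dtype=np.float32)
    N, K = m.shape
    nodes, weights = _gh_rule(n_nodes)
    if _HAVE_NUMBA:
        pi = _rows_kernel(
            m,
            np.ascontiguousarray(labels, dtype=np.int64),
            nodes.astype(np.float32),
            weights.astype(np.float32),
            _PHI_TAB,
            _PHI_DIFF,
            np.float32(_PHI_LO),
            _PHI_INV_STEP,
            np.float32(_PHI_N - 1.001),
        )
        pi = np.maximum(pi.astype(np.float64), 1e-300)
        return np.log(pi), pi
    mz = m[np.arange(N), labels]
    diff = mz[:, None] - m  # (N, K): m_{i,z_i} - m_{i,j}
    arg = diff[..., None] + nodes.astype(np.float32)
    phi = _phi_table(arg)
    phi[np.arange(N), labels, :] = 1.0
    pi = phi.prod(axis=1) @ weights.astype(np.float32)
    pi = np.maximum(pi.astype(np.float64), 1e-300)
    return np.log(pi), pi


def latent_class_probs(
    means: np.ndarray, n_nodes: int = 21, dtype=np.float64
) -> np.ndarray:
    """Probit class probabilities for rows of utility means.

    Given an (N, K) array of means m_ik = x_i' beta_k, returns the (N, K)
    array pi_ik = P(argmax_j {m_ij + eps_j} = k) with eps iid N(0,1),
    computed with a fixed Gauss-Hermite rule

        pi_ik = E_T[ prod_{j != k} Phi(T + m_ik - m_ij) ],   T ~ N(0,1).

    This is the deterministic fast path used inside the Gibbs sampler;
    ``membership_probs`` exposes the adaptive-quadrature and Monte Carlo
    variants for a single covariate row.
    """
    m = np.asarray(means, dtype=dtype)
    if m.ndim == 1:
        m = m[None, :]
    nodes, weights = _gh_rule(n_nodes)
    nodes = nodes.astype(dtype)
    weights = weights.astype(dtype)
    K = m.shape[1]
    # diff[i, k, j] = m_ik - m_ij
    diff = m[:, :, None] - m[:, None, :]
    arg = diff[..., None] + nodes
    phi = ndtr(arg)
    idx = np.arange(K)
    phi[:, idx, idx, :] = 1.0
    pi = phi.prod(axis=2) @ weights
    return np.asarray(pi, dtype=np.float64)


def membership_probs(
    x_i: np.ndarray,
    beta: CoefficientSet | np.ndarray,
    method: str = "quadrature",
    n_mc: int = 100_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Membership probabilities pi_k(x_i) for one covariate row.

    ``method="quadrature"`` evaluates, for each cluster k, the 1-D integral

        pi_k = \\int phi(u - m_k) prod_{j != k} Phi(u - m_j) du

    by adaptive quadrature (m = beta @ x_i); the output sums to 1 within
    1e-8.  ``method="mc"`` estimates the probabilities as argmax frequencies
    over ``n_mc`` Gaussian utility draws (unbiased).
    """
    b = beta.beta if isinstance(beta, CoefficientSet) else np.asarray(beta, float)
    x_i = np.asarray(x_i, dtype=float)
    m = b @ x_i
    K = m.shape[0]
    if method == "quadrature":
        out = np.empty(K)
        for k in range(K):
            others = np.delete(m, k)

            def integrand(u, mk=m[k], mo=others):
                return (
                    math.exp(-0.5 * (u - mk) ** 2) / math.sqrt(2 * math.pi)
                ) * np.prod(ndtr(u - mo))

            lo = m.min() - 10.0
            hi = m.max() + 10.0
            out[k], _ = integrate.quad(integrand, lo, hi, limit=200)
        return out
    if method == "mc":
        if n_mc < 1:
            raise ValueError("n_mc must be >= 1")
        if rng is None:
            rng = np.random.default_rng()
        draws = m[None, :] + rng.standard_normal((int(n_mc), K))
        counts = np.bincount(draws.argmax(axis=1), minlength=K)
        return counts / float(n_mc)
    raise ValueError("method must be 'quadrature' or 'mc'")


# ---------------------------------------------------------------------------
# Truncated-normal utility updates
# ---------------------------------------------------------------------------

_TINY = 1e-300
_ONE_MINUS = 1.0 - 1e-16


def _truncnorm_below(mu, a, rng):
    """Draw from N(mu, 1) truncated below at a (vectorized, inverse CDF)."""
    mu = np.asarray(mu, dtype=float)
    a = np.asarray(a, dtype=float)
    p = ndtr(mu - a)  # P(Y > a)
    u = rng.random(np.broadcast(mu, a).shape)
    v = np.clip(u * p, _TINY, _ONE_MINUS)
    y = mu - ndtri(v)
    return np.maximum(y, a + 1e-12)


def _truncnorm_above(mu, b, rng):
    """Draw from N(mu, 1) truncated above at b (vectorized, inverse CDF)."""
    mu = np.asarray(mu, dtype=float)
    b = np.asarray(b, dtype=float)
    p = ndtr(b - mu)  # P(Y < b)
    u = rng.random(np.broadcast(mu, b).shape)
    v = np.clip(u * p, _TINY, _ONE_MINUS)
    y = mu + ndtri(v)
    return np.minimum(y, b - 1e-12)


def sample_utilities(
    x_i: np.ndarray,
    beta: CoefficientSet | np.ndarray,
    z_i: int,
    y_i: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Gibbs pass over the utility coordinates of one individual.

    The winning coordinate y[z_i] is drawn from N(x_i' beta_{z_i}, 1)
    truncated below at the maximum of the other coordinates; every other
    coordinate is then drawn truncated above at the new y[z_i].  The argmax
    consistency y.argmax() == z_i holds exactly on exit.  Started from a
    state consistent with ``z_i`` this kernel leaves the constrained
    Gaussian N(x_i' beta, I) | argmax = z_i invariant.
    """
    b = beta.beta if isinstance(beta, CoefficientSet) else np.asarray(beta, float)
    m = b @ np.asarray(x_i, dtype=float)
    K = m.shape[0]
    if y_i is None:
        y = m + rng.standard_normal(K)
    else:
        y = np.array(y_i, dtype=float, copy=True)
    others = np.delete(np.arange(K), z_i)
    bound = y[others].max() if K > 1 else -np.inf
    y[z_i] = _truncnorm_below(m[z_i], bound, rng)
    if K > 1:
        y[others] = _truncnorm_above(m[others], y[z_i], rng)
    assert int(y.argmax()) == int(z_i)
    return y


def _sample_constrained_single(m, k, rng, n_grid=4097):
    """Exact-to-grid draw of y ~ N(m, I) | argmax = k for one individual.

    The winning coordinate has marginal density proportional to
    phi(t - m_k) prod_{j != k} Phi(t - m_j); it is drawn by inverse CDF on a
    dense grid, after which the losing coordinates are independent normals
    truncated above at the winner.  Used as fallback when rejection sampling
    has a tiny acceptance probability.
    """
    from scipy.special import log_ndtr

    m = np.asarray(m, dtype=float)
    K = m.shape[0]
    lo = m[k] - 9.0
    hi = max(m.max(), m[k]) + 9.0
    t = np.linspace(lo, hi, n_grid)
    logf = -0.5 * (t - m[k]) ** 2
    for j in range(K):
        if j != k:
            logf = logf + log_ndtr(t - m[j])
    f = np.exp(logf - logf.max())
    cdf = np.concatenate([[0.0], np.cumsum((f[1:] + f[:-1]) * 0.5)])
    cdf /= cdf[-1]
    yk = np.interp(rng.random(), cdf, t)
    y = np.empty(K)
    y[k] = yk
    for j in range(K):
        if j != k:
            y[j] = _truncnorm_above(m[j], yk, rng)
    assert int(y.argmax()) == int(k)
    return y


def _sample_constrained_batch(means, labels, rng, n_grid=801):
    """Grid inverse-CDF draw of y ~ N(m, I) | argmax = z for a batch of rows."""
    from scipy.special import log_ndtr

    H, K = means.shape
    ar = np.arange(H)
    mz = means[ar, labels]
    lo = mz - 9.0
    hi = np.maximum(means.max(axis=1), mz) + 9.0
    step = (hi - lo) / (n_grid - 1)
    t = lo[:, None] + step[:, None] * np.arange(n_grid)  # (H, G)
    logf = -0.5 * (t - mz[:, None]) ** 2
    for j in range(K):
        contrib = log_ndtr(t - means[:, j][:, None])
        contrib[labels == j] = 0.0
        logf += contrib
    f = np.exp(logf - logf.max(axis=1, keepdims=True))
    cdf = np.cumsum((f[:, 1:] + f[:, :-1]) * 0.5, axis=1)
    u = rng.random(H) * cdf[:, -1]
    pos = (u[:, None] > cdf).sum(axis=1)
    yk = t[ar, np.minimum(pos + 1, n_grid - 1)]
    y = _truncnorm_above(means, yk[:, None], rng)
    y[ar, labels] = yk
    bad = y.argmax(axis=1) != labels
    for i in np.flatnonzero(bad):  # numerically degenerate rows, if any
        y[i] = _sample_constrained_single(means[i], labels[i], rng)
    return y


def sample_utilities_joint(
    means: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    accept_probs: np.ndarray | None = None,
    max_rounds: int = 64,
    fallback_threshold: float = 0.05,
) -> np.ndarray:
    """Exact redraw of all utilities given labels: N(means, I) | argmax = z.

    Vectorized rejection sampling (acceptance probability pi_{i,z_i});
    individuals with very small acceptance (``accept_probs`` holds the
    per-row pi_{i,z_i} when available) go through the grid inverse-CDF
    fallback instead of looping.
    """
    means = np.asarray(means, dtype=float)
    labels = np.asarray(labels, dtype=int)
    N, K = means.shape
    y = np.empty((N, K))
    pending = np.ones(N, dtype=bool)
    if accept_probs is not None:
        hard = np.asarray(accept_probs) < fallback_threshold
    else:
        hard = np.zeros(N, dtype=bool)
    active = pending & ~hard
    for _ in range(max_rounds):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        cand = means[idx] + rng.standard_normal((idx.size, K))
        ok = cand.argmax(axis=1) == labels[idx]
        acc = idx[ok]
        y[acc] = cand[ok]
        pending[acc] = False
        active[acc] = False
    rest = np.flatnonzero(pending)
    if rest.size:
        y[rest] = _sample_constrained_batch(means[rest], labels[rest], rng)
    return y


# ---------------------------------------------------------------------------
# Conjugate coefficient update
# ---------------------------------------------------------------------------


def _check_invertible(design: DesignMatrix, gram: np.ndarray) -> None:
    # name the collinear columns if the Gram matrix is singular
    rank = np.linalg.matrix_rank(gram)
    p = gram.shape[0]
    if rank < p:
        _, _, vh = np.linalg.svd(gram)
        null = np.abs(vh[rank:]).sum(axis=0)
        bad = [design.column_names[j] for j in np.flatnonzero(null > 1e-8)]
        raise np.linalg.LinAlgError(
            "singular design Gram matrix; collinear columns: " + ", ".join(bad)
        )


def update_beta(
    design: DesignMatrix,
    utilities: UtilityMatrix,
    reference: int,
    rng: np.random.Generator,
    prior_precision: float = 0.0,
) -> CoefficientSet:
    """Conjugate draw of the regression coefficients given the utilities.

    With unit error variance and a flat prior (``prior_precision=0``) each
    non-reference beta_k is drawn from Normal((D'D)^-1 D' y_k, (D'D)^-1);
    a positive ``prior_precision`` rho corresponds to the weakly informative
    Gaussian prior beta_k ~ N(0, I/rho), giving covariance (D'D + rho I)^-1.
    The reference row remains exactly zero.
    """
    D = design.values
    Y = utilities.y
    N, p = D.shape
    K = Y.shape[1]
    gram = D.T @ D
    if prior_precision == 0.0:
        _check_invertible(design, gram)
    else:
        gram = gram + prior_precision * np.eye(p)
    cov = np.linalg.inv(gram)
    chol = np.linalg.cholesky(cov)
    mean = cov @ (D.T @ Y)  # p x K
    draw = mean + chol @ rng.standard_normal((p, K))
    beta = draw.T
    beta[reference] = 0.0
    return CoefficientSet(beta=beta, reference_cluster=reference)
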
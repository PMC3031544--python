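"""Synthetic-data generators with ground truth attached.

Two designs are provided, matching the model's two standard benchmarks:

* a *hidden-regression* design — latent utilities are linear in the
  covariates, labels follow the argmax rule, and genotypes are drawn from
  cluster-specific allele frequencies (latitude-only truth by default,
  optionally with a language-style factor); and
* a *five-island* design — subpopulation allele frequencies drawn from the
  Balding-Nichols F-model around Dirichlet ancestral frequencies, with
  subpopulation centers arranged on a ring and Gaussian spatial scatter,
  plus an optional spurious covariate independent of the subpopulation.

Every generator returns the genotype matrix, the covariate table, and a
:class:`SimTruth` carrying the generating labels, coefficients, frequencies
and utilities, so each inference stage is testable without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import GenotypeMatrix, build_design

__all__ = [
    "SimTruth",
    "IslandConfig",
    "default_regression_beta",
    "simulate_regression_data",
    "simulate_island_data",
    "make_trend_covariates",
]


@dataclass
class SimTruth:
    """Ground truth attached to a simulated dataset."""

    true_labels: np.ndarray
    true_beta: np.ndarray | None
    true_freqs: np.ndarray  # (K, L, A)
    covariates: pd.DataFrame
    seed: int | None = None
    true_utilities: np.ndarray | None = None
    design_columns: list = field(default_factory=list)


@dataclass
class IslandConfig:
    """Five-island design: K subpopulations on a ring, F-model frequencies.

    ``fst`` is the Balding-Nichols differentiation parameter F: subpopulation
    frequency rows are Dirichlet with parameters p_ancestral * (1 - F) / F,
    so the expected multilocus F_ST is approximately F.  ``coord_sd`` is the
    isotropic Gaussian scatter of individuals around their subpopulation
    center; the default leaves adjacent subpopulations slightly overlapping.
    """

    n_subpop: int = 5
    n_per_subpop: int = 100
    n_loci: int = 10
    n_alleles_per_locus: int = 5
    fst: float = 0.03
    coord_sd: float = 0.25
    ring_radius: float = 1.0

    def validate(self):
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in (0, 1)")
        if min(self.n_subpop, self.n_per_subpop, self.n_loci, self.n_alleles_per_locus) < 1:
            raise ValueError("counts must be positive")


def default_regression_beta(K: int = 3, p: int = 3) -> np.ndarray:
    """Latitude-only generating coefficients over (intercept, lat, long).

    Cluster 0 is the reference (zero row); the remaining clusters carry
    increasing latitude slopes with intercepts placing the decision
    boundaries near the tertiles of a uniform latitude, so the three
    clusters come out roughly equal in size.
    """
    if K != 3 or p < 3:
        raise ValueError("the default generating coefficients assume K=3, p>=3")
    beta = np.zeros((K, p))
    beta[1, :3] = (1.8, 3.0, 0.0)
    beta[2, :3] = (0.0, 6.0, 0.0)
    return beta


def _default_freqs(K: int, n_loci: int) -> np.ndarray:
    """Biallelic cluster frequencies, identical across loci: the frequency
    of allele 1 is evenly spaced in [0.2, 0.8] across clusters."""
    p1 = np.linspace(0.2, 0.8, K)
    freqs = np.empty((K, n_loci, 2))
    freqs[:, :, 1] = p1[:, None]
    freqs[:, :, 0] = 1.0 - p1[:, None]
    return freqs


def _draw_genotypes(freqs: np.ndarray, labels: np.ndarray, rng) -> GenotypeMatrix:
    K, L, A = freqs.shape
    N = len(labels)
    cdf = freqs.cumsum(axis=2)
    u = rng.random((N, L, 2))
    codes = (u[..., None] > cdf[labels][:, :, None, :]).sum(axis=3)
    n_alleles = np.full(L, A, dtype=int)
    # per-locus alphabets may be smaller than A if a frequency row has
    # structural zeros; keep the declared alphabet size A for all loci
    return GenotypeMatrix(
        codes=codes,
        missing_mask=np.zeros((N, L, 2), dtype=bool),
        n_alleles=n_alleles,
    )


def simulate_regression_data(
    n_ind: int = 300,
    n_loci: int = 40,
    K: int = 3,
    true_beta: np.ndarray | None = None,
    covariate_spec: dict | None = None,
    freq_spec: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    geo_trend: str = "linear",
):
    """Simulate from the hidden-regression generative model.

    Covariates are drawn uniform over the ranges in ``covariate_spec``
    (default latitude and longitude on (-1, 1)); factor levels, when given,
    are assigned in equal blocks.  Utilities are X beta + standard Gaussian
    noise over the same standardized design the fitting pipeline builds,
    labels follow the argmax rule, and genotypes are drawn per locus from
    the cluster frequencies in ``freq_spec`` (shape (K, L, A); biallelic
    with an evenly spaced allele-frequency contrast by default).

    Returns ``(GenotypeMatrix, covariate table, SimTruth)``.
    """
    if rng is None:
        rng = np.random.default_rng()
    spec = covariate_spec or {}
    cont = spec.get("continuous", {"latitude": (-1.0, 1.0), "longitude": (-1.0, 1.0)})
    factors = spec.get("factors", {})

    table = {"id": [f"ind{i:04d}" for i in range(n_ind)]}
    for name, (lo, hi) in cont.items():
        table[name] = rng.uniform(lo, hi, size=n_ind)
    for name, levels in factors.items():
        reps = int(np.ceil(n_ind / len(levels)))
        table[name] = np.repeat(list(levels), reps)[:n_ind]
    covariates = pd.DataFrame(table)

    extra_cont = tuple(c for c in cont if c not in ("latitude", "longitude"))
    design = build_design(
        covariates,
        geo_trend=geo_trend,
        factors=tuple(factors),
        continuous=extra_cont,
    )
    if true_beta is None:
        true_beta = default_regression_beta(K, design.n_columns)
    true_beta = np.asarray(true_beta, dtype=float)
    if true_beta.shape != (K, design.n_columns):
        raise ValueError(
            f"true_beta must have shape (K={K}, p={design.n_columns}), "
            f"got {true_beta.shape}"
        )

    utilities = design.values @ true_beta.T + rng.standard_normal((n_ind, K))
    labels = utilities.argmax(axis=1)

    if freq_spec is None:
        freq_spec = _default_freqs(K, n_loci)
    freq_spec = np.asarray(freq_spec, dtype=float)
    if freq_spec.shape[0] != K or freq_spec.shape[1] != n_loci:
        raise ValueError("freq_spec inconsistent with K or n_loci")

    data = _draw_genotypes(freq_spec, labels, rng)
    truth = SimTruth(
        true_labels=labels,
        true_beta=true_beta,
        true_freqs=freq_spec,
        covariates=covariates,
        true_utilities=utilities,
        design_columns=design.column_names,
    )
    return data, covariates, truth


def simulate_island_data(
    config: IslandConfig | None = None,
    rng: np.random.Generator | None = None,
    spurious: bool = True,
):
    """Simulate the five-island design with the Balding-Nichols F-model.

    Ancestral allele frequencies per locus are Dirichlet(1, ..., 1) clipped
    away from 0 and 1; each subpopulation's frequency row is Dirichlet with
    parameters p_ancestral * (1 - F) / F.  Subpopulation centers sit equally
    spaced on a circle and individual coordinates add isotropic Gaussian
    noise.  When ``spurious`` is set, the covariate table carries an extra
    standard-normal column independent of the subpopulation of origin.

    Returns ``(GenotypeMatrix, covariate table, SimTruth)``.
    """
    if config is None:
        config = IslandConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng()
    K, n_per = config.n_subpop, config.n_per_subpop
    L, A = config.n_loci, config.n_alleles_per_locus
    N = K * n_per

    ancestral = rng.dirichlet(np.ones(A), size=L)  # (L, A)
    ancestral = np.clip(ancestral, 0.05, None)
    ancestral /= ancestral.sum(axis=1, keepdims=True)
    conc = (1.0 - config.fst) / config.fst
    freqs = np.empty((K, L, A))
    for k in range(K):
        for l in range(L):
            freqs[k, l] = rng.dirichlet(ancestral[l] * conc)

    labels = np.repeat(np.arange(K), n_per)
    theta = 2.0 * np.pi * np.arange(K) / K
    centers = config.ring_radius * np.column_stack([np.sin(theta), np.cos(theta)])
    coords = centers[labels] + rng.normal(0.0, config.coord_sd, size=(N, 2))

    covariates = pd.DataFrame(
        {
            "id": [f"ind{i:04d}" for i in range(N)],
            "latitude": coords[:, 0],
            "longitude": coords[:, 1],
            "population": [f"pop{k}" for k in labels],
        }
    )
    if spurious:
        covariates["spurious"] = rng.standard_normal(N)

    data = _draw_genotypes(freqs, labels, rng)
    data.populations = labels.copy()
    truth = SimTruth(
        true_labels=labels,
        true_beta=None,
        true_freqs=freqs,
        covariates=covariates,
    )
    return data, covariates, truth


def make_trend_covariates(coords: pd.DataFrame, geo_trend: str) -> pd.DataFrame:
    """Trend-surface covariate columns for a coordinate table.

    Convenience pass-through so simulated coordinates enter the same design
    pipeline as real ones: returns the standardized trend columns (linear:
    lat, long; quadratic: plus squares and the cross-product; none: no
    columns, leaving the downstream design intercept-only).
    """
    design = build_design(coords, geo_trend=geo_trend, factors=())
    cols = {}
    for j, meta in enumerate(design.column_meta):
        if meta[0] == "continuous":
            cols[meta[1]] = design.values[:, j]
    return pd.DataFrame(cols, index=coords.index)
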
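"""Gibbs sampler for the joint posterior of labels, frequencies and coefficients.

The target is

    p(Z, P, beta, Y | X, D)  ∝  p(X | Z, P) p(P) p(Z | beta, D) p(beta),

with the no-admixture genotype likelihood (each individual's alleles drawn
from its cluster's per-locus frequencies), independent Dirichlet(lambda)
priors on every cluster x locus frequency row, the multinomial-probit label
layer of :mod:`latentpop.model_core`, and a weakly informative Gaussian
prior on the free coefficient rows.

One sweep performs, in order:

1. allele frequencies  P | Z, X          (Dirichlet conjugacy)
2. labels              Z | beta, P, X    (utilities integrated out; the
                                          label prior pi_k(x_i) is computed
                                          deterministically by Gauss-Hermite
                                          quadrature)
3. utilities           Y | Z, beta       (exact constrained-Gaussian redraw,
                                          so that steps 2+3 form a valid
                                          blocked draw of (Z, Y))
4. coefficients        beta | Y, D       (conjugate normal; reference row 0)

All randomness flows through one seeded Generator; identical configs give
bit-identical chains.  Log-space normalization is used throughout so that
hundreds of loci do not underflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .model_core import (
    DesignMatrix,
    GenotypeMatrix,
    _latent_logprob_rows,
    _latent_probs_fast,
    sample_utilities_joint,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleFrequencies",
    "LabelVector",
    "PosteriorChain",
    "GibbsConfig",
    "genotype_loglik",
    "update_allele_freqs",
    "update_labels",
    "run_gibbs",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class AlleleFrequencies:
    """Per-locus K x n_alleles[l] frequency matrices, padded internally."""

    padded: np.ndarray  # (K, L, A_max)
    n_alleles: np.ndarray

    def __post_init__(self):
        self.padded = np.asarray(self.padded, dtype=float)
        self.n_alleles = np.asarray(self.n_alleles, dtype=np.int64)

    @property
    def p(self) -> list:
        """List of per-locus K x n_alleles[l] matrices (rows sum to 1)."""
        return [self.padded[:, l, : self.n_alleles[l]] for l in range(len(self.n_alleles))]

    @property
    def n_clusters(self) -> int:
        return self.padded.shape[0]


@dataclass
class LabelVector:
    """Cluster labels with a mask of individuals pinned to the reference."""

    z: np.ndarray
    pinned_mask: np.ndarray | None = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.int64)
        if self.pinned_mask is None:
            self.pinned_mask = np.zeros(self.z.shape, dtype=bool)
        self.pinned_mask = np.asarray(self.pinned_mask, dtype=bool)

    def check_pinned(self, reference: int) -> None:
        if np.any(self.z[self.pinned_mask] != reference):
            raise ValueError("pinned individuals must carry the reference label")


@dataclass
class PosteriorChain:
    """Stored post-burn-in samples of one Gibbs run."""

    label_samples: np.ndarray  # (S, N) int
    beta_samples: np.ndarray  # (S, K, p)
    loglik_trace: np.ndarray  # (sweeps,)
    config: dict
    freq_samples: np.ndarray | None = None  # optional thinned (S', K, L, A_max)
    n_alleles: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.label_samples.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.beta_samples.shape[1]

    @property
    def mean_loglik(self) -> float:
        """Mean post-burn-in data log-likelihood (used for run retention)."""
        burn = self.config["burn_in"]
        return float(self.loglik_trace[burn:].mean())


@dataclass
class GibbsConfig:
    """Sampler configuration; a seed is mandatory (no unseeded runs)."""

    K: int
    sweeps: int
    burn_in: int
    seed: int
    reference_cluster: int = 0
    pinned: np.ndarray | None = None
    lambda_: float = 1.0
    prior_sd: float = 10.0
    gh_nodes: int = 13
    scale_step: float = 0.4
    scale_moves: int = 1
    relabel_moves: bool = False
    init: str = "auto"  # auto | uniform | kmeans
    warmup: int = 50
    store_freqs: bool = False
    freq_thin: int = 10

    def validate(self, n_individuals: int) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if not self.sweeps > self.burn_in >= 0:
            raise ValueError("need sweeps > burn_in >= 0")
        if self.seed is None:
            raise ValueError("a seed is required")
        if not 0 <= self.reference_cluster < self.K:
            raise ValueError("reference_cluster out of range")
        if self.pinned is not None and np.asarray(self.pinned).shape != (n_individuals,):
            raise ValueError("pinned mask must have one entry per individual")

    def as_dict(self) -> dict:
        d = {
            "K": self.K,
            "sweeps": self.sweeps,
            "burn_in": self.burn_in,
            "seed": self.seed,
            "reference_cluster": self.reference_cluster,
            "lambda": self.lambda_,
            "prior_sd": self.prior_sd,
            "gh_nodes": self.gh_nodes,
        }
        return d


# ---------------------------------------------------------------------------
# Flat-index helpers (shared by likelihood, counts and the sampler)
# ---------------------------------------------------------------------------


def _flat_layout(data: GenotypeMatrix):
    """Flatten allele copies to indices into a (L*A_max + 1) code space.

    Missing copies map to the final slot, whose log-frequency is held at 0
    so they contribute nothing to likelihoods or counts.
    """
    N, L = data.n_individuals, data.n_loci
    A = int(data.n_alleles.max())
    C = L * A + 1
    offs = (np.arange(L) * A)[None, :, None]
    flat = data.codes + offs
    flat = np.where(data.missing_mask, C - 1, flat)
    return flat.reshape(N, 2 * L).astype(np.int64), A, C


def _valid_slot_mask(n_alleles: np.ndarray, A: int) -> np.ndarray:
    return np.arange(A)[None, :] < n_alleles[:, None]  # (L, A)


def _counts_from_labels(flat, z, K, C):
    idx = flat + (np.asarray(z, dtype=np.int64) * C)[:, None]
    cnt = np.bincount(idx.ravel(), minlength=K * C).reshape(K, C)
    return cnt[:, : C - 1]  # drop the missing slot


def _draw_freqs(counts, n_alleles, A, lam, rng):
    K = counts.shape[0]
    L = len(n_alleles)
    alpha = lam + counts.reshape(K, L, A).astype(float)
    alpha *= _valid_slot_mask(n_alleles, A)[None, :, :]
    g = rng.standard_gamma(alpha)
    total = g.sum(axis=2, keepdims=True)
    return g / total


def _log_freq_flat(padded, n_alleles, A, C):
    K, L, _ = padded.shape
    valid = _valid_slot_mask(n_alleles, A)[None, :, :]
    safe = np.where(valid & (padded > 0.0), padded, 1.0)
    logf = np.log(safe)
    flat = np.zeros((K, C))
    flat[:, : C - 1] = logf.reshape(K, L * A)
    return flat


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def genotype_loglik(genotype_row, mask_row, freqs_k) -> float:
    """No-admixture log-likelihood of one individual under one cluster.

    Sums log p_{k,l,allele} over loci and the two allele copies; masked
    (missing) copies contribute 0.  A zero frequency for an observed allele
    yields -inf (flagged in the log).
    """
    genotype_row = np.asarray(genotype_row)
    mask_row = np.asarray(mask_row, dtype=bool)
    total = 0.0
    for l, rows in enumerate(freqs_k):
        for c in range(2):
            if mask_row[l, c]:
                continue
            f = rows[genotype_row[l, c]]
            if f <= 0.0:
                logger.warning(
                    "observed allele with zero frequency at locus %d; loglik = -inf", l
                )
                return -np.inf
            total += np.log(f)
    return float(total)


def _loglik_matrix(flat, log_freq_flat) -> np.ndarray:
    """(N, K) log-likelihood of every individual under every cluster."""
    return log_freq_flat[:, flat].sum(axis=2).T


def update_allele_freqs(
    data: GenotypeMatrix,
    labels: LabelVector | np.ndarray,
    lam: float,
    rng: np.random.Generator,
    K: int | None = None,
) -> AlleleFrequencies:
    """Conjugate Dirichlet draw of all cluster x locus frequency rows.

    Each row is drawn from Dirichlet(lambda + allele counts among copies
    carried by individuals assigned to the cluster); missing copies are
    excluded.  Empty clusters draw from the Dirichlet(lambda, ...) prior.
    """
    z = labels.z if isinstance(labels, LabelVector) else np.asarray(labels)
    if K is None:
        K = int(z.max()) + 1
    flat, A, C = _flat_layout(data)
    counts = _counts_from_labels(flat, z, K, C)
    padded = _draw_freqs(counts, data.n_alleles, A, lam, rng)
    return AlleleFrequencies(padded=padded, n_alleles=data.n_alleles)


def update_labels(
    data: GenotypeMatrix,
    freqs: AlleleFrequencies,
    prior_probs: np.ndarray,
    pinned_mask: np.ndarray | None,
    rng: np.random.Generator,
    current: np.ndarray | None = None,
) -> LabelVector:
    """Sample labels from their full conditional (log-space normalized).

    For each unpinned individual, z_i is drawn with probability proportional
    to exp(genotype loglik under cluster k) * prior_probs[i, k]; pinned
    individuals keep their current (reference) label.
    """
    flat, A, C = _flat_layout(data)
    logf = _log_freq_flat(freqs.padded, freqs.n_alleles, A, C)
    ll = _loglik_matrix(flat, logf)
    z = _sample_labels(ll, np.asarray(prior_probs, float), pinned_mask, rng, current)
    return LabelVector(z=z, pinned_mask=pinned_mask)


def _sample_labels(ll, prior_probs, pinned_mask, rng, current):
    N, K = ll.shape
    w = np.exp(ll - ll.max(axis=1, keepdims=True))
    w *= np.maximum(prior_probs, 1e-300)
    total = w.sum(axis=1)
    if np.any(total == 0.0):
        raise ValueError("all posterior label weights are zero (degenerate frequencies)")
    cum = np.cumsum(w, axis=1)
    u = rng.random(N) * total
    z = (u[:, None] > cum).sum(axis=1).astype(np.int64)
    if pinned_mask is not None and pinned_mask.any():
        if current is None:
            raise ValueError("pinned individuals require current labels")
        z[pinned_mask] = current[pinned_mask]
    return z


def run_gibbs(
    data: GenotypeMatrix,
    design: DesignMatrix,
    config: GibbsConfig,
    init_labels: np.ndarray | None = None,
) -> PosteriorChain:
    """Run one Gibbs chain and return the post-burn-in posterior samples.

    Labels initialize uniformly at random (pinned individuals at the
    reference), beta at zero.  The per-sweep data log-likelihood
    sum_i loglik(i, z_i) is traced for every sweep.
    """
    config.validate(data.n_individuals)
    rng = np.random.default_rng(config.seed)
    N, L = data.n_individuals, data.n_loci
    K, p = config.K, design.n_columns
    ref = config.reference_cluster
    pinned = (
        np.zeros(N, dtype=bool) if config.pinned is None else np.asarray(config.pinned, bool)
    )

    flat, A, C = _flat_layout(data)
    D = design.values
    prec = 0.0 if config.prior_sd is None else 1.0 / config.prior_sd**2
    gram = D.T @ D + prec * np.eye(p)
    cov = np.linalg.inv(gram)
    chol = np.linalg.cholesky(cov)
    proj = cov @ D.T  # p x N

    if init_labels is not None:
        z = np.asarray(init_labels, dtype=np.int64).copy()
        if np.any(z[pinned] != ref):
            raise ValueError("pinned individual initialized with a non-reference label")
    else:
        mode = config.init
        if mode == "auto":
            mode = "kmeans" if p > 1 else "uniform"
        if mode == "kmeans":
            # spatially/covariate-coherent random start: k-means++ on the
            # standardized covariate columns (per-run randomness diversifies
            # the ensemble); the genotype likelihood then corrects the
            # partition during burn-in
            from scipy.cluster.vq import kmeans2

            with np.errstate(invalid="ignore"):
                _, z = kmeans2(design.values[:, 1:], K, minit="++", seed=rng, iter=20)
            z = z.astype(np.int64)
        else:
            z = rng.integers(K, size=N)
        z[pinned] = ref
    beta = np.zeros((K, p))

    d_free_ = (K - 1) * p
    for _ in range(config.warmup):
        # warm-up: adapt (Y, beta) to the initial partition with labels held
        # fixed, so the probit layer encodes the start before the first
        # label sweep; pure initialization, not part of the posterior sample
        means = D @ beta.T
        cur_rows, row_p = _latent_logprob_rows(means, z, n_nodes=config.gh_nodes)
        c = float(np.exp(rng.normal(0.0, config.scale_step)))
        prop_rows, _ = _latent_logprob_rows(c * means, z, n_nodes=config.gh_nodes)
        log_acc = (
            prop_rows.sum()
            - cur_rows.sum()
            - 0.5 * prec * (c * c - 1.0) * float((beta**2).sum())
            + d_free_ * np.log(c)
        )
        if np.log(rng.random()) < log_acc:
            beta *= c
            means = c * means
        Y = sample_utilities_joint(means, z, rng, accept_probs=row_p)
        beta = (proj @ Y + chol @ rng.standard_normal((p, K))).T
        beta[ref] = 0.0

    S = config.sweeps - config.burn_in
    label_samples = np.empty((S, N), dtype=np.int16)
    beta_samples = np.empty((S, K, p))
    loglik_trace = np.empty(config.sweeps)
    freq_store = [] if config.store_freqs else None

    arangeN = np.arange(N)
    d_free = (K - 1) * p
    for sweep in range(config.sweeps):
        # 1. allele frequencies | labels
        counts = _counts_from_labels(flat, z, K, C)
        padded = _draw_freqs(counts, data.n_alleles, A, config.lambda_, rng)
        logf = _log_freq_flat(padded, data.n_alleles, A, C)
        # 2. labels | beta, freqs (utilities marginalized)
        ll = _loglik_matrix(flat, logf)
        means = D @ beta.T
        pi = _latent_probs_fast(means, n_nodes=config.gh_nodes)
        z = _sample_labels(ll, pi, pinned, rng, z)
        loglik_trace[sweep] = ll[arangeN, z].sum()
        row_probs = np.maximum(pi[arangeN, z], 1e-300)
        # 2b. collapsed Metropolis scale move on the free coefficient block,
        # targeting p(beta | Z) with the utilities integrated out; this is
        # what lets |beta| equilibrate quickly (plain data augmentation
        # mixes the coefficient scale very slowly).
        cur_logpi = np.log(row_probs).sum()
        ssq = float((beta**2).sum())
        for _ in range(config.scale_moves):
            c = float(np.exp(rng.normal(0.0, config.scale_step)))
            prop_log_rows, prop_rows = _latent_logprob_rows(
                c * means, z, n_nodes=config.gh_nodes
            )
            log_acc = (
                prop_log_rows.sum()
                - cur_logpi
                - 0.5 * prec * (c * c - 1.0) * ssq
                + d_free * np.log(c)
            )
            if np.log(rng.random()) < log_acc:
                beta *= c
                means *= c
                ssq *= c * c
                cur_logpi = prop_log_rows.sum()
                row_probs = prop_rows
        # 2c. optional reference-swap relabeling move: transpose the
        # reference with another cluster (beta'_k = beta_{tau(k)} - beta_j,
        # labels and frequencies relabeled).  The probit label prior and the
        # genotype likelihood are exactly invariant under this map, so the
        # acceptance probability is just the coefficient prior ratio.  It
        # makes the chain traverse the label-permutation symmetry of the
        # posterior; off by default because deliberate within-chain label
        # switching scrambles membership estimates.
        if config.relabel_moves and not pinned.any():
            jj = int(rng.integers(K - 1))
            j = jj + 1 if jj >= ref else jj
            tau = np.arange(K)
            tau[ref], tau[j] = j, ref
            beta_prop = beta[tau] - beta[j]
            log_acc = -0.5 * prec * (float((beta_prop**2).sum()) - ssq)
            if np.log(rng.random()) < log_acc:
                beta = beta_prop
                ssq = float((beta**2).sum())
                z = tau[z]
                means = means[:, tau] - means[:, [j]]
        # 3. utilities | labels, beta (exact blocked redraw)
        Y = sample_utilities_joint(means, z, rng, accept_probs=row_probs)
        # 4. coefficients | utilities
        mean = proj @ Y  # p x K
        beta = (mean + chol @ rng.standard_normal((p, K))).T
        beta[ref] = 0.0

        s = sweep - config.burn_in
        if s >= 0:
            label_samples[s] = z
            beta_samples[s] = beta
            if freq_store is not None and s % config.freq_thin == 0:
                freq_store.append(padded.copy())

    chain = PosteriorChain(
        label_samples=label_samples,
        beta_samples=beta_samples,
        loglik_trace=loglik_trace,
        config=config.as_dict(),
        freq_samples=None if freq_store is None else np.array(freq_store),
        n_alleles=data.n_alleles.copy(),
    )
    if not np.all(np.isfinite(loglik_trace)):
        logger.warning("non-finite log-likelihood encountered in trace")
    return chain


def spawn_configs(config: GibbsConfig, n_runs: int) -> list:
    """Derive per-run configs with independent seeds from one base config."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_runs)
    return [
        replace(config, seed=int(c.generate_state(1)[0] % (2**31))) for c in children
    ]
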
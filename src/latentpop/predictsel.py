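"""Posterior-predictive membership and variable-selection criteria.

Two measures quantify how well a covariate subset predicts the genetic
structure:

* the Pearson correlation r between the matrix of membership coefficients
  predicted from covariates alone and the matrix estimated from genotypes
  (confidence intervals through Fisher's z-transform), and
* a 2-fold cross-validation predictive score: the loci are split into two
  complementary halves, chains are fitted on one half, and the posterior-
  averaged log-probability of the held-out half is computed under the
  Dirichlet-multinomial marginal given the sampled training labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .gibbs import (
    GibbsConfig,
    PosteriorChain,
    _counts_from_labels,
    _flat_layout,
    _valid_slot_mask,
)
from .model_core import (
    DesignMatrix,
    GenotypeMatrix,
    MembershipMatrix,
    latent_class_probs,
)
from .runs import align_runs, average_runs, run_ensemble, select_top_runs

__all__ = [
    "SelectionReport",
    "estimated_membership",
    "predicted_membership",
    "pearson_criterion",
    "fisher_interval",
    "split_loci",
    "predictive_score",
    "cross_validation_score",
    "ensemble_memberships",
]


@dataclass
class SelectionReport:
    """Selection measures for one candidate covariate subset."""

    model_label: str
    pearson_r: float | None
    cv_score: float
    cv_score_sd: float
    n_runs_used: int

    def __post_init__(self):
        if self.pearson_r is not None and not -1.0 <= self.pearson_r <= 1.0:
            raise ValueError("pearson_r must lie in [-1, 1]")

    def as_dict(self) -> dict:
        return {
            "model": self.model_label,
            "pearson_r": self.pearson_r,
            "cv_score": self.cv_score,
            "cv_score_sd": self.cv_score_sd,
            "n_runs_used": self.n_runs_used,
        }


# ---------------------------------------------------------------------------
# Membership matrices
# ---------------------------------------------------------------------------


def estimated_membership(chain: PosteriorChain) -> MembershipMatrix:
    """q[i, k] = fraction of post-burn-in samples with z_i = k."""
    if chain.n_samples == 0:
        raise ValueError("empty chain")
    S, N = chain.label_samples.shape
    K = chain.n_clusters
    q = np.zeros((N, K))
    for k in range(K):
        q[:, k] = (chain.label_samples == k).sum(axis=0)
    return MembershipMatrix(q=q / S, kind="estimated")


def predicted_membership(
    chain: PosteriorChain,
    design: DesignMatrix,
    n_draws: int,
    rng: np.random.Generator,
    method: str = "simulate",
) -> MembershipMatrix:
    """Posterior-predictive membership from covariates alone.

    For each draw, a stored coefficient sample is picked uniformly, latent
    utilities are simulated as X beta + eps, and the argmax label recorded;
    q[i, k] is the frequency of label k (``method="simulate"``).
    ``method="average"`` instead averages the deterministic probit
    probabilities over the sampled coefficients — the quadrature cross-check
    of the label-simulation estimate.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    D = design.values
    N = D.shape[0]
    K = chain.n_clusters
    picks = rng.integers(chain.n_samples, size=n_draws)
    if method == "simulate":
        counts = np.zeros((N, K))
        for s in picks:
            means = D @ chain.beta_samples[s].T
            labels = (means + rng.standard_normal((N, K))).argmax(axis=1)
            counts[np.arange(N), labels] += 1.0
        return MembershipMatrix(q=counts / n_draws, kind="predicted")
    if method == "average":
        q = np.zeros((N, K))
        for s in picks:
            q += latent_class_probs(D @ chain.beta_samples[s].T)
        q /= n_draws
        q /= q.sum(axis=1, keepdims=True)
        return MembershipMatrix(q=q, kind="predicted")
    raise ValueError("method must be 'simulate' or 'average'")


def pearson_criterion(q_pred: MembershipMatrix, q_est: MembershipMatrix) -> float:
    """Pearson correlation over all N*K entries of the two matrices."""
    a = (q_pred.q if isinstance(q_pred, MembershipMatrix) else np.asarray(q_pred)).ravel()
    b = (q_est.q if isinstance(q_est, MembershipMatrix) else np.asarray(q_est)).ravel()
    if a.shape != b.shape:
        raise ValueError("membership matrices differ in shape")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("zero variance in a membership matrix")
    return float(np.corrcoef(a, b)[0, 1])


def fisher_interval(r: float, n_entries: int, level: float = 0.95) -> tuple:
    """Confidence interval for r assuming Fisher's z-transform is Gaussian."""
    from scipy.stats import norm

    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    se = 1.0 / np.sqrt(max(n_entries - 3, 1))
    half = norm.ppf(0.5 + level / 2) * se
    return float(np.tanh(z - half)), float(np.tanh(z + half))


# ---------------------------------------------------------------------------
# Cross-validation machinery
# ---------------------------------------------------------------------------


def split_loci(data: GenotypeMatrix, rng: np.random.Generator):
    """Random partition of the loci into ceil(L/2) training and floor(L/2)
    validation loci (disjoint, exhaustive)."""
    L = data.n_loci
    if L < 2:
        raise ValueError("need at least two loci to split")
    perm = rng.permutation(L)
    half = (L + 1) // 2
    train_idx = np.sort(perm[:half])
    valid_idx = np.sort(perm[half:])
    return data.subset_loci(train_idx), data.subset_loci(valid_idx)


def predictive_score(
    chain_train: PosteriorChain,
    valid: GenotypeMatrix,
    lam: float,
    sample_thin: int = 1,
    method: str = "marginal",
) -> float:
    """Posterior-averaged log-probability of the validation loci.

    For each stored training label sample Z(s), the validation genotypes are
    scored by the Dirichlet-multinomial marginal per cluster x locus —
    integrating the (unseen) validation-locus frequencies against their
    Dirichlet(lambda) prior given the allele counts implied by Z(s) — and
    the log-probabilities are averaged over samples.  ``method="plugin"``
    instead plugs the posterior-mean frequencies into the likelihood, kept
    as a sensitivity variant.
    """
    if valid.n_loci == 0:
        return 0.0
    if method not in ("marginal", "plugin"):
        raise ValueError("method must be 'marginal' or 'plugin'")
    K = chain_train.n_clusters
    flat, A, C = _flat_layout(valid)
    valid_mask = _valid_slot_mask(valid.n_alleles, A)  # (L, A)
    a_l = valid.n_alleles.astype(float)  # alphabet size per locus
    # per-locus constant terms of the DM marginal
    const_top = gammaln(a_l * lam)  # log Gamma(A_l * lambda)
    scores = []
    samples = chain_train.label_samples[::sample_thin]
    for z in samples:
        counts = _counts_from_labels(flat, z, K, C).reshape(K, valid.n_loci, A)
        n_tot = counts.sum(axis=2)  # (K, L)
        if method == "marginal":
            term = gammaln(lam + counts) - gammaln(lam)
            term = np.where(valid_mask[None, :, :], term, 0.0)
            s = (
                const_top[None, :]
                - gammaln(a_l[None, :] * lam + n_tot)
                + term.sum(axis=2)
            ).sum()
        else:
            mean_f = (lam + counts) / (a_l[None, :, None] * lam + n_tot[:, :, None])
            logf = np.where(valid_mask[None, :, :], np.log(mean_f), 0.0)
            s = float((counts * logf).sum())
        scores.append(s)
    return float(np.mean(scores))


def cross_validation_score(
    data: GenotypeMatrix,
    design: DesignMatrix,
    config: GibbsConfig,
    n_runs: int,
    n_keep: int,
    rng: np.random.Generator,
    n_bootstrap: int = 1000,
    sample_thin: int = 1,
    model_label: str = "",
) -> SelectionReport:
    """2-fold locus-split cross-validation predictive score.

    ``n_runs`` chains are fitted on the training half; the ``n_keep`` with
    highest mean post-burn-in log-likelihood are each scored against the
    validation half; the folds are then exchanged.  The report carries the
    mean of the 2*n_keep scores and a nonparametric-bootstrap standard
    deviation of that mean.
    """
    if n_keep > n_runs:
        raise ValueError("n_keep must not exceed n_runs")
    train, valid = split_loci(data, rng)
    scores = []
    for half_a, half_b in ((train, valid), (valid, train)):
        cfg = GibbsConfig(
            **{**config.__dict__, "seed": int(rng.integers(2**31))}
        )
        ens = run_ensemble(half_a, design, cfg, n_runs)
        for idx in select_top_runs(ens, n_keep):
            scores.append(
                predictive_score(ens.chains[idx], half_b, config.lambda_, sample_thin)
            )
    scores = np.asarray(scores)
    boot = rng.integers(len(scores), size=(n_bootstrap, len(scores)))
    sd = float(scores[boot].mean(axis=1).std())
    return SelectionReport(
        model_label=model_label,
        pearson_r=None,
        cv_score=float(scores.mean()),
        cv_score_sd=sd,
        n_runs_used=len(scores),
    )


def ensemble_memberships(
    data: GenotypeMatrix,
    design: DesignMatrix,
    config: GibbsConfig,
    n_runs: int,
    n_keep: int,
    n_draws: int,
    rng: np.random.Generator,
):
    """Fit an ensemble and return aligned-averaged estimated and predicted
    membership matrices (plus the ensemble itself).

    The retained runs are aligned on their estimated memberships; the same
    column permutations are applied to the predicted memberships before
    averaging, so the two averages live in a common cluster numbering.
    """
    ens = run_ensemble(data, design, config, n_runs)
    kept = select_top_runs(ens, n_keep)
    ens.retained = kept
    q_est_list = [estimated_membership(ens.chains[i]) for i in kept]
    q_pred_list = [
        predicted_membership(ens.chains[i], design, n_draws, rng) for i in kept
    ]
    # the reference column is only identifiable across runs when individuals
    # are pinned to it; otherwise all columns are free to permute
    pinned = config.pinned
    fix_ref = pinned is not None and bool(np.asarray(pinned).any())
    perms, aligned_est = align_runs(
        q_est_list, config.reference_cluster if fix_ref else None
    )
    ens.alignment = perms
    aligned_pred = [m.q[:, perm] for m, perm in zip(q_pred_list, perms)]
    q_est = average_runs(aligned_est)
    q_pred = MembershipMatrix(q=np.mean(aligned_pred, axis=0), kind="predicted")
    return q_est, q_pred, ens
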
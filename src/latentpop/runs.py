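"""Multi-run orchestration: replicate chains, retention, alignment, scoring.

Independent Gibbs runs of a label-switching mixture land in arbitrary
cluster numberings.  This module runs replicate chains, keeps the runs with
the highest mean post-burn-in log-likelihood, aligns cluster columns across
runs by exact optimal assignment (with the reference column held fixed),
averages the aligned membership matrices, and scores misclassification
against ground-truth labels under the best label permutation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .gibbs import GibbsConfig, run_gibbs, spawn_configs
from .model_core import DesignMatrix, GenotypeMatrix, MembershipMatrix

__all__ = [
    "RunEnsemble",
    "run_ensemble",
    "select_top_runs",
    "align_runs",
    "average_runs",
    "misclassification_rate",
]


@dataclass
class RunEnsemble:
    """A collection of replicate chains plus retention/alignment metadata."""

    chains: list
    retained: list = field(default_factory=list)
    alignment: list = field(default_factory=list)  # per-retained-run permutation

    @property
    def n_runs(self) -> int:
        return len(self.chains)

    def manifest(self) -> list:
        out = []
        perms = {r: p for r, p in zip(self.retained, self.alignment)}
        for i, chain in enumerate(self.chains):
            out.append(
                {
                    "run": i,
                    "seed": chain.config["seed"],
                    "mean_loglik": chain.mean_loglik,
                    "retained": i in self.retained,
                    "permutation": None if i not in perms else [int(v) for v in perms[i]],
                }
            )
        return out

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1)


def run_ensemble(
    data: GenotypeMatrix,
    design: DesignMatrix,
    config: GibbsConfig,
    n_runs: int,
) -> RunEnsemble:
    """Run ``n_runs`` independent chains with seeds derived from the config seed."""
    chains = [run_gibbs(data, design, cfg) for cfg in spawn_configs(config, n_runs)]
    return RunEnsemble(chains=chains)


def select_top_runs(ensemble: RunEnsemble, n_keep: int) -> list:
    """Indices of the n_keep chains with highest mean post-burn-in log-likelihood.

    Returned in descending likelihood order; ties break by run index.
    """
    if ensemble.n_runs == 0:
        raise ValueError("empty ensemble")
    if n_keep > ensemble.n_runs:
        raise ValueError("n_keep exceeds the number of runs")
    scores = np.array([c.mean_loglik for c in ensemble.chains])
    order = np.lexsort((np.arange(len(scores)), -scores))
    return [int(i) for i in order[:n_keep]]


def _best_permutation(q_anchor: np.ndarray, q_other: np.ndarray, reference: int | None):
    """Permutation perm with aligned[:, k] = q_other[:, perm[k]] maximizing
    the column-similarity overlap with the anchor; the reference column maps
    to itself."""
    K = q_anchor.shape[1]
    sim = q_anchor.T @ q_other  # sim[k, j] = sum_i qa[i,k] qo[i,j]
    free = [k for k in range(K) if k != reference]
    perm = np.empty(K, dtype=int)
    if reference is not None:
        perm[reference] = reference
        sub = sim[np.ix_(free, free)]
        rows, cols = linear_sum_assignment(-sub)
        for r, c in zip(rows, cols):
            perm[free[r]] = free[c]
    else:
        rows, cols = linear_sum_assignment(-sim)
        perm[rows] = cols
    return perm


def align_runs(q_list, reference_cluster: int | None = None):
    """Align cluster columns of membership matrices to the first matrix.

    Each non-anchor matrix is column-permuted by the permutation maximizing
    sum_ik q_anchor[i,k] * q_perm[i,k], found exactly by optimal assignment
    on the K x K column-similarity matrix.  The reference column, when
    given, is held fixed.  Returns ``(permutations, aligned)`` where
    aligned[r][:, k] = q_list[r][:, permutations[r][k]].
    """
    mats = [m.q if isinstance(m, MembershipMatrix) else np.asarray(m, float) for m in q_list]
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValueError("membership matrices differ in shape")
    anchor = mats[0]
    perms, aligned = [], []
    for m in mats:
        perm = _best_permutation(anchor, m, reference_cluster)
        perms.append(perm)
        aligned.append(m[:, perm])
    return perms, aligned


def average_runs(aligned_q_list) -> MembershipMatrix:
    """Entrywise mean of aligned membership matrices (rows still sum to 1)."""
    mats = [
        m.q if isinstance(m, MembershipMatrix) else np.asarray(m, float)
        for m in aligned_q_list
    ]
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise ValueError("membership matrices differ in shape")
    return MembershipMatrix(q=np.mean(mats, axis=0), kind="estimated")


def misclassification_rate(
    q_or_labels,
    truth: np.ndarray,
    exclude_pinned: bool = False,
    pinned_mask: np.ndarray | None = None,
) -> float:
    """Fraction of individuals misassigned, after optimal label matching.

    Each individual is assigned its modal cluster (probability ties break to
    the lowest index); the number of mismatches is minimized over all
    permutations of the predicted cluster labels by an exact assignment
    solve, so the rate is invariant to any relabeling of either side.
    """
    truth = np.asarray(truth, dtype=int)
    K_true = int(truth.max()) + 1
    if isinstance(q_or_labels, MembershipMatrix):
        q = q_or_labels.q
        pred = q.argmax(axis=1)
        K_pred = q.shape[1]
    else:
        arr = np.asarray(q_or_labels)
        if arr.ndim == 2:
            pred = arr.argmax(axis=1)
            K_pred = arr.shape[1]
        else:
            pred = arr.astype(int)
            K_pred = int(pred.max()) + 1
    if len(pred) != len(truth):
        raise ValueError("prediction and truth differ in length")
    if K_pred < K_true:
        raise ValueError(
            f"cluster count mismatch: predictions have {K_pred}, truth has {K_true}"
        )
    K = max(K_pred, K_true)
    if exclude_pinned:
        if pinned_mask is None:
            raise ValueError("exclude_pinned requires a pinned mask")
        keep = ~np.asarray(pinned_mask, bool)
        pred, truth = pred[keep], truth[keep]
    n = len(truth)
    conf = np.zeros((K, K))
    np.add.at(conf, (pred, truth), 1.0)
    rows, cols = linear_sum_assignment(-conf)
    matched = conf[rows, cols].sum()
    return float(1.0 - matched / n)
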
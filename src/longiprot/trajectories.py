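"""Baseline-subtracted group trajectories, exact t-SNE, and affinity propagation.

Each significant protein is summarised by a 6-vector: the group-median
abundance change from baseline at T1/T4/T10, for responders and
non-responders.  Profiles are embedded with exact t-SNE (visualisation) and
clustered by affinity propagation on a Spearman-correlation similarity
matrix (the clustering operates on the profiles, not the embedding).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.manifold import TSNE

from .containers import AbundanceMatrix, NON_RESPONDER, RESPONDER, TIMEPOINTS

PROFILE_COLUMNS = [
    f"{g}_{tp}" for g in (RESPONDER, NON_RESPONDER) for tp in TIMEPOINTS[1:]
]


def compute_delta_profiles(matrix: AbundanceMatrix, labels, proteins=None) -> pd.DataFrame:
    """Per-protein 6-vector of baseline-subtracted group-median trajectories.

    Group medians are taken across patients of the per-sample (replicate
    median) values; the group's T0 median is subtracted from its T1/T4/T10
    medians.  Invariant to adding a constant to all values of a protein.
    """
    collapsed = matrix.collapse_replicates()
    proteins = list(proteins) if proteins is not None else collapsed.protein_ids
    vals = collapsed.values.loc[proteins]
    ann = collapsed.runs
    out = pd.DataFrame(index=pd.Index(proteins, name="protein_id"),
                       columns=PROFILE_COLUMNS, dtype=float)
    for grp, members in ((RESPONDER, labels.responders), (NON_RESPONDER, labels.non_responders)):
        medians = {}
        for tp in TIMEPOINTS:
            cols = ann.index[(ann.timepoint == tp) & ann.patient_id.isin(members)]
            if len(cols) == 0:
                raise ValueError(f"no samples for group {grp!r} at {tp}")
            med = vals[cols].median(axis=1)
            if med.isna().any():
                bad = med.index[med.isna()][:5].tolist()
                raise ValueError(f"protein(s) absent at {tp} in {grp}: {bad}")
            medians[tp] = med
        for tp in TIMEPOINTS[1:]:
            out[f"{grp}_{tp}"] = medians[tp] - medians["T0"]
    return out


def tsne_embed(profiles: pd.DataFrame, perplexity: float = 2.0, seed: int = 0,
               dims: int = 2) -> pd.DataFrame:
    """Exact (non-approximated) t-SNE embedding of the delta profiles.

    Deterministic given ``seed`` (PCA initialisation); coordinates are
    centred.  Requires ``perplexity < (n - 1) / 3``.
    """
    n = profiles.shape[0]
    if n < 4 or perplexity >= (n - 1) / 3:
        raise ValueError(f"perplexity {perplexity} infeasible for n={n}")
    emb = TSNE(n_components=dims, perplexity=perplexity, method="exact",
               init="pca", random_state=seed).fit_transform(
        profiles.to_numpy(dtype=float))
    emb = emb - emb.mean(axis=0)
    return pd.DataFrame(emb, index=profiles.index,
                        columns=[f"tsne_{i+1}" for i in range(dims)])


def spearman_similarity(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation between profile rows (midrank ties)."""
    arr = profiles.to_numpy(dtype=float)
    ranks = np.apply_along_axis(sps.rankdata, 1, arr)
    sim = np.corrcoef(ranks)
    return pd.DataFrame(sim, index=profiles.index, columns=profiles.index)


@dataclasses.dataclass
class ClusterAssignment:
    labels: pd.Series  # item -> cluster id (0..K-1)
    exemplars: list  # cluster id -> item id of the exemplar
    preference: float
    converged: bool
    n_iter: int
    embedding: pd.DataFrame | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)


def affinity_propagation(
    similarity: pd.DataFrame,
    preference: float | None = None,
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_iter: int = 100,
) -> ClusterAssignment:
    """Exemplar clustering by responsibility/availability message passing.

    ``preference`` (self-similarity of every point) defaults to the median
    of the off-diagonal similarities.  Messages are damped by ``damping``;
    the run stops once the exemplar set is stable for ``convergence_iter``
    sweeps.  Ties in the final assignment break towards the lowest item
    index.  On non-convergence the best (last) iterate is returned with
    ``converged = False``.
    """
    ids = list(similarity.index)
    S = np.array(similarity.to_numpy(dtype=float), copy=True)
    n = S.shape[0]
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    if n == 1:
        return ClusterAssignment(pd.Series([0], index=ids), [ids[0]],
                                 preference=float(preference or 0.0),
                                 converged=True, n_iter=0)
    if preference is None:
        off = S[~np.eye(n, dtype=bool)]
        preference = float(np.median(off))
    np.fill_diagonal(S, preference)
    # deterministic tie-breaking jitter: exactly equal similarities (common
    # with rank-based profiles) leave message passing in degenerate fixed
    # points otherwise
    span = float(S.max() - S.min()) or 1.0
    S = S + np.random.default_rng(0).normal(0.0, 1e-9 * span, (n, n))

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    last_exemplars = None
    stable = 0
    it = 0
    for it in range(1, max_iter + 1):
        # responsibilities
        AS = A + S
        first_idx = AS.argmax(axis=1)
        first = AS[np.arange(n), first_idx]
        AS[np.arange(n), first_idx] = -np.inf
        second = AS.max(axis=1)
        Rnew = S - first[:, None]
        Rnew[np.arange(n), first_idx] = S[np.arange(n), first_idx] - second
        R = damping * R + (1 - damping) * Rnew
        # availabilities
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, R.diagonal())
        col_sums = Rp.sum(axis=0)
        Anew = np.minimum(0.0, col_sums[None, :] - Rp)
        np.fill_diagonal(Anew, col_sums - R.diagonal())
        A = damping * A + (1 - damping) * Anew

        exemplars = np.where(np.diag(A + R) > 0)[0]
        if last_exemplars is not None and np.array_equal(exemplars, last_exemplars) \
                and len(exemplars) > 0:
            stable += 1
            if stable >= convergence_iter:
                break
        else:
            stable = 0
        last_exemplars = exemplars

    converged = stable >= convergence_iter
    exemplars = np.where(np.diag(A + R) > 0)[0]
    if len(exemplars) == 0:
        exemplars = np.array([int(np.argmax(S.sum(axis=0)))])
    # assign to the most similar exemplar; lowest index wins ties
    sim_to_ex = S[:, exemplars]
    best = sim_to_ex.argmax(axis=1)  # argmax returns the first (lowest) maximiser
    labels = best.copy()
    for k, e in enumerate(exemplars):
        labels[e] = k
    return ClusterAssignment(
        labels=pd.Series(labels, index=ids, name="cluster"),
        exemplars=[ids[e] for e in exemplars],
        preference=float(preference),
        converged=converged,
        n_iter=it,
    )


def cluster_trajectories(
    profiles: pd.DataFrame,
    preference: float | None = None,
    damping: float = 0.9,
    perplexity: float = 2.0,
    seed: int = 0,
) -> ClusterAssignment:
    """Affinity propagation on Spearman similarity of delta profiles, with a
    2-D exact t-SNE embedding attached for plotting."""
    sim = spearman_similarity(profiles)
    assignment = affinity_propagation(sim, preference=preference, damping=damping)
    if profiles.shape[0] >= 4 and perplexity < (profiles.shape[0] - 1) / 3:
        assignment.embedding = tsne_embed(profiles, perplexity=perplexity, seed=seed)
    return assignment
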
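"""Inter-subject connectome similarity (fingerprinting-style contrasts).

Similarity between two subjects is the cosine distance
d = 1 - u.v / (||u|| ||v||) between their edge vectors, restricted to a
feature subset; lower distance means higher similarity.  For a two-group
cohort the within-group and between-group mean distances are compared
with a two-sample t-test on the pooled pair distances (default) or a
subject-label permutation test.  Pair distances sharing a subject are not
independent, which the t-test ignores — the permutation alternative is
the honest option when that matters.

The panel runs the same contrast on four subsets of equal bookkeeping:
all edges, the mRMR-selected edges computed on the complete groups (no
train/test split), a random subset of the same size, and the same number
of lowest-relevance edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics.pairwise import cosine_distances

from .mrmr import DiscretizationRule, bottom_rank_features, miq_rank


@dataclass
class SimilarityResult:
    subset_id: str
    subset_size: int
    group_a: str
    group_b: str
    within_a: float
    within_b: float
    between: float
    p_a: float  # within-A vs between
    p_b: float  # within-B vs between
    n_pairs_within_a: int
    n_pairs_within_b: int
    n_pairs_between: int


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """d = 1 - cos(u, v); in [0, 2], symmetric, zero for identical
    directions.  Zero vectors are a hard error."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def _pair_masks(labels: np.ndarray, a, b):
    n = labels.size
    iu = np.triu_indices(n, k=1)
    la, lb = labels[iu[0]], labels[iu[1]]
    within_a = (la == a) & (lb == a)
    within_b = (la == b) & (lb == b)
    between = ((la == a) & (lb == b)) | ((la == b) & (lb == a))
    return iu, within_a, within_b, between


def group_similarity(
    x: np.ndarray,
    labels: Sequence,
    subset: Optional[np.ndarray] = None,
    test: str = "ttest",
    seed: int = 0,
    n_permutations: int = 5000,
    subset_id: str = "all",
) -> SimilarityResult:
    """Within- vs between-group mean cosine distances on a feature subset.

    Both groups are compared against the shared between-group pair pool;
    p-values are two-sided.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("exactly two groups are required")
    a, b = groups
    if np.sum(labels == a) < 2 or np.sum(labels == b) < 2:
        raise ValueError("need at least 2 subjects per group")
    if subset is None:
        subset = np.arange(x.shape[1])
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("feature subset must be nonempty")
    if subset.min() < 0 or subset.max() >= x.shape[1]:
        raise ValueError("feature subset indices out of range")

    d = cosine_distances(x[:, subset])
    iu, wa, wb, bt = _pair_masks(labels, a, b)
    pair_d = d[iu]
    da, db, dbt = pair_d[wa], pair_d[wb], pair_d[bt]

    if test == "ttest":
        p_a = float(stats.ttest_ind(da, dbt).pvalue)
        p_b = float(stats.ttest_ind(db, dbt).pvalue)
    elif test == "permutation":
        rng = np.random.default_rng(seed)
        p_a = _perm_pvalue(d, labels, a, b, "a", rng, n_permutations)
        p_b = _perm_pvalue(d, labels, a, b, "b", rng, n_permutations)
    else:
        raise ValueError("test must be 'ttest' or 'permutation'")

    return SimilarityResult(
        subset_id=subset_id, subset_size=int(subset.size),
        group_a=str(a), group_b=str(b),
        within_a=float(da.mean()), within_b=float(db.mean()),
        between=float(dbt.mean()), p_a=p_a, p_b=p_b,
        n_pairs_within_a=int(wa.sum()), n_pairs_within_b=int(wb.sum()),
        n_pairs_between=int(bt.sum()),
    )


def _perm_pvalue(d, labels, a, b, which, rng, n_perm):
    """Permutation p for (mean within - mean between) by shuffling subject
    labels; two-sided, with the +1 correction for the observed draw."""
    iu, wa, wb, bt = _pair_masks(labels, a, b)
    pair_d = d[iu]
    w = wa if which == "a" else wb
    obs = pair_d[w].mean() - pair_d[bt].mean()
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        _, pwa, pwb, pbt = _pair_masks(perm, a, b)
        pw = pwa if which == "a" else pwb
        stat = pair_d[pw].mean() - pair_d[pbt].mean()
        if abs(stat) >= abs(obs):
            hits += 1
    return (hits + 1) / (n_perm + 1)


def similarity_panel(
    x: np.ndarray,
    labels: Sequence,
    rule: DiscretizationRule = DiscretizationRule(),
    max_k: int = 50,
    redundancy: str = "mean",
    drop_ratio: Optional[float] = None,
    test: str = "ttest",
    seed: int = 0,
    n_permutations: int = 5000,
    selected: Optional[np.ndarray] = None,
) -> list[SimilarityResult]:
    """Similarity contrasts on {all, mrmr, random, low_score} subsets.

    The mRMR subset is computed once on the complete groups (no train/test
    split); the random and low-score subsets have exactly the same size.
    Pass ``selected`` to reuse an existing selection instead of re-running
    mRMR.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    y = (labels == np.unique(labels)[1]).astype(int)
    if selected is None:
        ranking = miq_rank(x, y, max_k=max_k, rule=rule,
                           redundancy=redundancy, drop_ratio=drop_ratio)
        selected = ranking.selected
    selected = np.asarray(selected, dtype=int)
    k = selected.size
    rng = np.random.default_rng(seed)
    random_subset = np.sort(rng.choice(x.shape[1], size=k, replace=False))
    low = bottom_rank_features(x, y, k, rule)
    subsets = {
        "all": np.arange(x.shape[1]),
        "mrmr": selected,
        "random": random_subset,
        "low_score": low,
    }
    return [
        group_similarity(x, labels, subset=s, test=test, seed=seed,
                         n_permutations=n_permutations, subset_id=name)
        for name, s in subsets.items()
    ]
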
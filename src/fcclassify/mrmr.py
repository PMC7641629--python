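"""Minimum-redundancy / maximum-relevance (mRMR) edge selection.

The ranking criterion is the mutual-information quotient (MIQ): at each
greedy step the candidate feature maximising

    score(f) = I(f; class) / redundancy(f, selected)

is appended, where redundancy is the mean (configurable: sum) of the
mutual information between the candidate and the already-selected
features.  The first feature is chosen by pure relevance I(f; class) and
its recorded score *is* that relevance (there is no redundancy term yet).
Mutual information is the plug-in estimate on discretised features; by
default a continuous edge feature is cut into three bins at mean +/- 0.5
standard deviations.

The number of features to keep is read off the score trajectory: the cut
falls immediately before the largest relative single-step drop in the
recorded scores ("elbow" rule), or, when ``drop_ratio`` is given, at the
first step whose score falls below ``drop_ratio`` times its predecessor.
Because the step-1 score lives on the relevance scale rather than the
quotient scale, drops are only compared from step 2 onward.

All tie-breaks are "lowest feature index", making the whole ranking
deterministic for a given input table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

_EPS_REDUNDANCY = 1e-12


@dataclass(frozen=True)
class DiscretizationRule:
    """How continuous features are binned before mutual information.

    ``three_bin_mean_sd`` cuts at mean +/- alpha*sd into three bins
    (-inf, mu-a*sd], (mu-a*sd, mu+a*sd], (mu+a*sd, inf); ``equal_frequency``
    uses ``n_bins`` quantile bins.
    """

    scheme: str = "three_bin_mean_sd"
    alpha: float = 0.5
    n_bins: int = 3

    def __post_init__(self) -> None:
        if self.scheme not in ("three_bin_mean_sd", "equal_frequency"):
            raise ValueError(f"unknown discretisation scheme {self.scheme!r}")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    @property
    def max_bins(self) -> int:
        return 3 if self.scheme == "three_bin_mean_sd" else self.n_bins


@dataclass
class MRMRRanking:
    """Greedy selection order, per-step importance scores and the
    drop-rule cut ``k_selected`` (1 <= k_selected <= len(order))."""

    order: np.ndarray
    scores: np.ndarray
    k_selected: int

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(np.unique(self.order)) != self.order.size:
            raise ValueError("ranking order contains duplicate features")
        if self.scores.size != self.order.size:
            raise ValueError("scores and order must have equal length")
        if not (1 <= self.k_selected <= self.order.size):
            raise ValueError("k_selected out of range")

    @property
    def selected(self) -> np.ndarray:
        return self.order[: self.k_selected]


def discretize(x: np.ndarray, rule: DiscretizationRule = DiscretizationRule()) -> np.ndarray:
    """Map a continuous feature to integer bin labels (deterministic).

    Constant inputs collapse to a single bin.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot discretise an empty array")
    if rule.scheme == "three_bin_mean_sd":
        mu, sd = x.mean(), x.std()
        if sd == 0:
            return np.zeros(x.shape, dtype=np.int8)
        lo, hi = mu - rule.alpha * sd, mu + rule.alpha * sd
        return ((x > lo).astype(np.int8) + (x > hi).astype(np.int8))
    cuts = np.quantile(x, np.linspace(0, 1, rule.n_bins + 1)[1:-1])
    return np.searchsorted(cuts, x, side="left").astype(np.int8)


def discretize_matrix(x: np.ndarray, rule: DiscretizationRule = DiscretizationRule()) -> np.ndarray:
    """Column-wise :func:`discretize` of an (n, E) feature table."""
    x = np.asarray(x, dtype=float)
    if rule.scheme == "three_bin_mean_sd":
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        const = sd == 0
        sd = np.where(const, 1.0, sd)
        lo = mu - rule.alpha * sd
        hi = mu + rule.alpha * sd
        d = (x > lo).astype(np.int8) + (x > hi).astype(np.int8)
        if np.any(const):  # constant column: single bin, matching discretize()
            d[:, const] = 0
        return d
    return np.column_stack([discretize(x[:, j], rule) for j in range(x.shape[1])])


def _as_codes(a: np.ndarray) -> np.ndarray:
    _, codes = np.unique(np.asarray(a), return_inverse=True)
    return codes.astype(np.int64)


def _mi_columns(f: np.ndarray, y: np.ndarray, nb_f: int, nb_y: int) -> np.ndarray:
    """Plug-in mutual information (nats) between every column of the
    discretised (n, E) matrix ``f`` and the label vector ``y``."""
    n, e = f.shape
    cell = f.astype(np.int64) * nb_y + y[:, None]
    cell += np.arange(e, dtype=np.int64)[None, :] * (nb_f * nb_y)
    counts = np.bincount(cell.ravel(), minlength=e * nb_f * nb_y).astype(float)
    pj = counts.reshape(e, nb_f, nb_y) / n
    pf = pj.sum(axis=2, keepdims=True)
    py = pj.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pj * (np.log(pj) - np.log(pf) - np.log(py))
    terms[~np.isfinite(terms)] = 0.0  # 0 log 0 := 0
    return np.maximum(terms.sum(axis=(1, 2)), 0.0)


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information I(a; b) in nats between two discrete
    label vectors (symmetric, non-negative)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.size == 0 or b.size == 0:
        raise ValueError("mutual information of empty inputs is undefined")
    if a.shape != b.shape:
        raise ValueError("inputs must have equal length")
    ca, cb = _as_codes(a), _as_codes(b)
    return float(_mi_columns(cb[:, None], ca, int(cb.max()) + 1, int(ca.max()) + 1)[0])


def relevance(x: np.ndarray, y: np.ndarray,
              rule: DiscretizationRule = DiscretizationRule()) -> np.ndarray:
    """I(feature; class) for every column of the continuous table ``x``."""
    d = discretize_matrix(x, rule)
    yc = _as_codes(y)
    return _mi_columns(d, yc, rule.max_bins, int(yc.max()) + 1)


def miq_rank(
    x: np.ndarray,
    y: np.ndarray,
    max_k: Optional[int] = None,
    rule: DiscretizationRule = DiscretizationRule(),
    redundancy: str = "mean",
    drop_ratio: Optional[float] = None,
) -> MRMRRanking:
    """Greedy mutual-information-quotient ranking of ``max_k`` features.

    Step 1 picks the feature with maximal relevance I(f; c); later steps
    pick the feature maximising I(f; c) divided by the mean (or sum) of
    its mutual information with the already-selected set.  The recorded
    score at each step is the winning quotient (pure relevance at step 1).
    Ties break to the lowest feature index.  ``k_selected`` is filled in by
    the drop rule (:func:`select_by_drop`).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.ndim != 2:
        raise ValueError("x must be (n_subjects, n_features)")
    n, e = x.shape
    if y.shape != (n,):
        raise ValueError("y must have one label per row of x")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("need at least 2 subjects in each of >= 2 classes")
    if redundancy not in ("mean", "sum"):
        raise ValueError("redundancy must be 'mean' or 'sum'")
    if max_k is None:
        max_k = min(e, 50)
    if max_k <= 0:
        raise ValueError("max_k must be >= 1")
    max_k = min(max_k, e)

    d = discretize_matrix(x, rule)
    yc = _as_codes(y)
    nb = rule.max_bins
    rel = _mi_columns(d, yc, nb, int(yc.max()) + 1)

    order = np.empty(max_k, dtype=int)
    scores = np.empty(max_k, dtype=float)
    taken = np.zeros(e, dtype=bool)
    red_sum = np.zeros(e, dtype=float)

    first = int(np.argmax(rel))  # argmax returns the lowest index on ties
    order[0], scores[0] = first, rel[first]
    taken[first] = True

    for t in range(1, max_k):
        red_sum += _mi_columns(d, d[:, order[t - 1]].astype(np.int64), nb, nb)
        denom = red_sum / t if redundancy == "mean" else red_sum
        quotient = rel / np.maximum(denom, _EPS_REDUNDANCY)
        quotient[taken] = -np.inf
        nxt = int(np.argmax(quotient))
        order[t], scores[t] = nxt, quotient[nxt]
        taken[nxt] = True

    k = select_by_drop(scores, drop_ratio=drop_ratio)
    return MRMRRanking(order=order, scores=scores, k_selected=k)


def select_by_drop(scores: np.ndarray | MRMRRanking,
                   drop_ratio: Optional[float] = None) -> int:
    """Feature count implied by the drop in the importance-score trajectory.

    Default (elbow) rule: k is the 1-based position immediately before the
    largest relative single-step decrease, comparing from step 2 onward
    because the step-1 score is on the relevance scale.  With
    ``drop_ratio`` set, k is instead the first position t >= 2 with
    score_{t+1} < drop_ratio * score_t.  Always returns 1 <= k <= len.
    """
    if isinstance(scores, MRMRRanking):
        scores = scores.scores
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty score trajectory")
    if s.size == 1:
        return 1
    if np.allclose(s, s[0]):
        warnings.warn("all importance scores equal; no drop found, keeping all",
                      stacklevel=2)
        return int(s.size)
    if drop_ratio is not None:
        for t in range(2, s.size):  # t is 1-based step index; s[t] is score_{t+1}
            if s[t - 1] > 0 and s[t] < drop_ratio * s[t - 1]:
                return t
        return int(s.size)
    if s.size < 3:
        return int(s.size)
    best_k, best_drop = int(s.size), -np.inf
    for t in range(2, s.size):
        if s[t - 1] <= 0:
            continue
        drop = (s[t - 1] - s[t]) / s[t - 1]
        if drop > best_drop:
            best_drop, best_k = drop, t
    return best_k


def bottom_rank_features(
    x: np.ndarray,
    y: np.ndarray,
    n: int,
    rule: DiscretizationRule = DiscretizationRule(),
) -> np.ndarray:
    """The ``n`` features with the *lowest* single-feature relevance
    I(f; class) — the low-importance control set.

    Single-feature relevance is used as a deterministic, linear-time stand-in
    for the tail of a full greedy ranking; ties break to the lowest index.
    """
    x = np.asarray(x, dtype=float)
    e = x.shape[1]
    if n > e:
        raise ValueError(f"requested {n} features but only {e} exist")
    if n == 0:
        warnings.warn("bottom_rank_features called with n=0; returning empty set",
                      stacklevel=2)
        return np.empty(0, dtype=int)
    rel = relevance(x, y, rule)
    return np.argsort(rel, kind="stable")[:n]
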
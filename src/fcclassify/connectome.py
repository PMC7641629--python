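"""Functional-connectivity matrices and edge-vector bookkeeping.

Region time series (T timepoints x P regions) are turned into Fisher-z
Pearson correlation matrices; the upper triangle is flattened into a
fixed-order edge vector which is the feature representation used by every
downstream stage.  An atlas table maps region ids onto named functional
networks so edges can be reported as (region, network) pairs.  A scalar
mean framewise-displacement (FD) covariate supports the head-motion
quality filter.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical eight functional-network labels used for annotation: medial
#: frontal, frontoparietal, default mode, subcortical/cerebellar, motor,
#: visual I, visual II and visual association.
DEFAULT_NETWORKS: tuple[str, ...] = (
    "MFN", "FPN", "DMN", "SC", "MON", "VisI", "VisII", "VA",
)

PATIENT = "patient"
CONTROL = "control"


@dataclass
class SubjectRecord:
    """One subject: region time series, group label and covariates.

    ``timeseries`` is a (T, P) float array; ``group`` is ``"patient"`` or
    ``"control"``; ``subtype`` distinguishes planted patient subgroups in
    synthetic cohorts (1 or 2).  Clinical covariates that do not apply
    (e.g. illness duration for controls) are NaN / None.
    """

    subject_id: str
    group: str
    timeseries: Optional[np.ndarray] = None
    subtype: Optional[int] = None
    age: float = math.nan
    sex: Optional[str] = None  # 'F' or 'M'
    duration: float = math.nan
    ymrs: float = math.nan
    madrs: float = math.nan
    med_antipsychotic: Optional[bool] = None
    med_antidepressant: Optional[bool] = None
    med_mood_stabilizer: Optional[bool] = None
    mean_fd: float = math.nan

    def __post_init__(self) -> None:
        if self.group not in (PATIENT, CONTROL):
            raise ValueError(
                f"subject {self.subject_id!r}: group must be "
                f"'{PATIENT}' or '{CONTROL}', got {self.group!r}"
            )
        if self.timeseries is not None:
            ts = np.asarray(self.timeseries, dtype=float)
            if ts.ndim != 2 or ts.shape[0] < 2:
                raise ValueError(
                    f"subject {self.subject_id!r}: timeseries must be a "
                    f"(T>=2, P) array, got shape {ts.shape}"
                )
            if not np.all(np.isfinite(ts)):
                raise ValueError(
                    f"subject {self.subject_id!r}: timeseries has non-finite entries"
                )
            self.timeseries = ts
        if not math.isnan(self.mean_fd) and self.mean_fd < 0:
            raise ValueError(f"subject {self.subject_id!r}: mean_fd must be >= 0")


@dataclass
class RegionAtlas:
    """Region lookup table: id (1..P), free-text name, network label.

    Region ids must be contiguous 1..P and each region belongs to exactly
    one network.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"region_id", "name", "network"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        ids = np.asarray(self.table["region_id"], dtype=int)
        p = len(ids)
        if not np.array_equal(np.sort(ids), np.arange(1, p + 1)):
            raise ValueError("atlas region ids must be contiguous 1..P")
        self.table = self.table.sort_values("region_id").reset_index(drop=True)

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> list[str]:
        return list(pd.unique(self.table["network"]))

    def name_of(self, region_id: int) -> str:
        return str(self.table.at[region_id - 1, "name"])

    def network_of(self, region_id: int) -> str:
        return str(self.table.at[region_id - 1, "network"])

    @classmethod
    def uniform(
        cls,
        n_regions: int,
        networks: Sequence[str] = DEFAULT_NETWORKS,
        sizes: Optional[Sequence[int]] = None,
    ) -> "RegionAtlas":
        """Build a synthetic atlas with near-equal network blocks."""
        if sizes is None:
            base = n_regions // len(networks)
            sizes = [base] * len(networks)
            for i in range(n_regions - base * len(networks)):
                sizes[i] += 1
        if sum(sizes) != n_regions:
            raise ValueError("network sizes must sum to n_regions")
        rows = []
        rid = 1
        for net, size in zip(networks, sizes):
            for _ in range(size):
                rows.append({"region_id": rid, "name": f"region_{rid:03d}", "network": net})
                rid += 1
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionAtlas":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# quality filter
# ---------------------------------------------------------------------------

def filter_by_fd(
    records: Sequence[SubjectRecord], threshold: float = 0.2
) -> list[SubjectRecord]:
    """Drop subjects whose mean framewise displacement exceeds ``threshold``.

    The boundary is kept: subjects with mean FD exactly equal to the
    threshold (default 0.2 mm) survive; only strictly larger values are
    discarded.  A missing mean FD is a hard error naming the subject.
    """
    for rec in records:
        if rec.mean_fd is None or math.isnan(rec.mean_fd):
            raise ValueError(f"subject {rec.subject_id!r} has no mean_fd value")
    kept = [rec for rec in records if rec.mean_fd <= threshold]
    discarded = [rec.subject_id for rec in records if rec.mean_fd > threshold]
    if discarded:
        logger.info("FD filter (> %.3g mm) discarded %d subject(s): %s",
                    threshold, len(discarded), ", ".join(discarded))
    return kept


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def compute_fc(timeseries: np.ndarray, clip: float = 0.999999) -> np.ndarray:
    """Pearson-correlate region time series and Fisher r-to-z transform.

    Returns a symmetric P x P matrix with ``z = atanh(r)`` off the diagonal
    and zeros on it.  Correlations are clamped to ``|r| <= clip`` before the
    transform so degenerate (perfectly correlated) region pairs stay finite.
    A constant column is a hard error naming the 1-based region.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError(f"timeseries must be (T>=2, P), got shape {ts.shape}")
    dead = np.flatnonzero(np.ptp(ts, axis=0) == 0)
    if dead.size:
        raise ValueError(
            f"constant time series in region(s) {[int(i) + 1 for i in dead]}; "
            "correlation undefined"
        )
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -clip, clip)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return z


def n_edges(n_regions: int) -> int:
    """Number of unordered region pairs, E = P(P-1)/2."""
    return n_regions * (n_regions - 1) // 2


def edge_pairs(n_regions: int) -> np.ndarray:
    """(E, 2) array of 0-based (i, j), i < j, in row-major upper-triangle
    order: (0,1), (0,2), ..., (0,P-1), (1,2), ..."""
    iu = np.triu_indices(n_regions, k=1)
    return np.column_stack(iu)


def edge_index(i: int, j: int, n_regions: int) -> int:
    """0-based edge-vector index of the 0-based region pair (i, j), i < j."""
    if not (0 <= i < j < n_regions):
        raise ValueError(f"need 0 <= i < j < P, got ({i}, {j}) with P={n_regions}")
    return i * (2 * n_regions - i - 1) // 2 + (j - i - 1)


def vectorize_upper(fc: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Flatten the strict upper triangle of a symmetric matrix.

    Asymmetry beyond ``tol`` is a hard error; the inverse operation
    :func:`devectorize_upper` reconstructs the matrix exactly (zero
    diagonal convention).
    """
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {fc.shape}")
    if np.max(np.abs(fc - fc.T)) > tol:
        raise ValueError("matrix is not symmetric within tolerance")
    iu = np.triu_indices(fc.shape[0], k=1)
    return fc[iu].copy()


def devectorize_upper(values: np.ndarray) -> np.ndarray:
    """Rebuild the symmetric zero-diagonal matrix from an edge vector."""
    values = np.asarray(values, dtype=float)
    e = values.size
    p = int(round((1 + math.sqrt(1 + 8 * e)) / 2))
    if n_edges(p) != e:
        raise ValueError(f"edge vector length {e} is not P(P-1)/2 for any integer P")
    out = np.zeros((p, p), dtype=float)
    iu = np.triu_indices(p, k=1)
    out[iu] = values
    out += out.T
    return out


def edge_annotation(k: int, atlas: RegionAtlas) -> dict:
    """Annotate edge ``k`` (0-based) with 1-based region ids, names and
    network labels.  The network pair is unordered for reporting."""
    e = n_edges(atlas.n_regions)
    if not 0 <= k < e:
        raise ValueError(f"edge index {k} out of range for E={e}")
    pairs = edge_pairs(atlas.n_regions)
    i, j = (int(x) + 1 for x in pairs[k])
    net_i, net_j = atlas.network_of(i), atlas.network_of(j)
    return {
        "edge": int(k),
        "region_i": i,
        "region_j": j,
        "name_i": atlas.name_of(i),
        "name_j": atlas.name_of(j),
        "network_i": net_i,
        "network_j": net_j,
        "network_pair": "-".join(sorted((net_i, net_j))),
        "within_network": net_i == net_j,
    }


def features_table(
    records: Sequence[SubjectRecord], clip: float = 0.999999
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack per-subject edge vectors into an (n_subjects, E) matrix.

    Returns ``(X, y, subject_ids)`` where ``y`` is 1 for patients and 0
    for controls.
    """
    rows, labels, ids = [], [], []
    for rec in records:
        if rec.timeseries is None:
            raise ValueError(f"subject {rec.subject_id!r} has no time series")
        rows.append(vectorize_upper(compute_fc(rec.timeseries, clip=clip)))
        labels.append(1 if rec.group == PATIENT else 0)
        ids.append(rec.subject_id)
    return np.asarray(rows), np.asarray(labels, dtype=int), ids


# ---------------------------------------------------------------------------
# plain-text IO
# ---------------------------------------------------------------------------

def write_timeseries(ts: np.ndarray, path: str | Path) -> None:
    p = ts.shape[1]
    header = "\t".join(f"r{j + 1}" for j in range(p))
    np.savetxt(path, ts, delimiter="\t", header=header, comments="", fmt="%.6f")


def read_timeseries(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", skiprows=1)


def write_features(
    x: np.ndarray, subject_ids: Sequence[str], path: str | Path,
    edge_map_path: Optional[str | Path] = None,
) -> None:
    """Write the subjects x E feature table as CSV, plus an optional JSON
    sidecar with the edge-index -> 1-based region-pair map."""
    e = x.shape[1]
    p = int(round((1 + math.sqrt(1 + 8 * e)) / 2))
    df = pd.DataFrame(x, index=pd.Index(subject_ids, name="subject_id"),
                      columns=[f"e{k}" for k in range(e)])
    df.to_csv(path, float_format="%.6f")
    if edge_map_path is not None:
        pairs = edge_pairs(p) + 1
        payload = {"n_regions": p, "edges": {str(k): [int(i), int(j)]
                                             for k, (i, j) in enumerate(pairs)}}
        Path(edge_map_path).write_text(json.dumps(payload))


def read_features(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(s) for s in df.index]
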
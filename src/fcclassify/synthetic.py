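"""Synthetic cohorts with planted group-discriminative connectivity.

The generator emulates a two-group resting-state study: each subject's
region time series are drawn i.i.d. Gaussian from a subject-specific
correlation matrix.  The latent correlation structure is block-diagonal
over functional networks (higher within-network than between-network
baseline correlation).  Patients carry two kinds of planted structure:

* a *shared signature* — a sparse set of edges whose latent correlation is
  shifted by +/- ``effect_size`` in every patient, the ground truth that
  feature selection and classification should recover; and
* optional *heterogeneity edges* — a disjoint edge set on which each
  patient carries an individual signed loading (sign fixed by subtype,
  magnitude drawn per subject), so the two patient subtypes deviate from
  the control baseline in opposite directions.  This makes the patient
  group internally dissimilar on the full edge set while remaining
  homogeneous on the shared signature, the configuration needed to study
  how feature selection changes inter-subject similarity.

Latent matrices perturbed away from positive definiteness are repaired by
eigenvalue clipping at a small floor followed by rescaling to unit
diagonal; the repair is deterministic and preserves the sign of small
planted shifts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .connectome import (
    CONTROL,
    PATIENT,
    RegionAtlas,
    SubjectRecord,
    edge_index,
    n_edges,
    write_timeseries,
)

PD_FLOOR = 1e-6


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic cohort (defaults mirror the target
    study design: 268 regions in 8 networks, 192 patients vs 173 controls,
    192 retained volumes per subject).

    ``planted_edges`` are 1-based region pairs; when None, ``n_planted``
    pairs are drawn at random from the seed.  ``effect_size`` is the shift
    applied to the latent correlation of every planted edge in patients
    (sign per edge, random unless ``planted_signs`` is given).
    ``subtype_fraction`` of patients form subtype 2; heterogeneity edges
    (``het_edges`` / ``n_het``) receive per-subject loadings of magnitude
    ~ ``het_effect`` whose sign follows the subtype.
    """

    n_regions: int = 268
    n_networks: int = 8
    network_sizes: Optional[tuple[int, ...]] = None
    n_controls: int = 173
    n_patients: int = 192
    n_timepoints: int = 192
    planted_edges: Optional[tuple[tuple[int, int], ...]] = None
    n_planted: int = 10
    planted_signs: Optional[tuple[int, ...]] = None
    effect_size: float = 0.4
    subject_sd: float = 0.05
    subtype_fraction: float = 0.0
    het_edges: Optional[tuple[tuple[int, int], ...]] = None
    n_het: int = 40
    het_effect: float = 0.3
    het_loading_sd: float = 0.4
    within_r: float = 0.3
    between_r: float = 0.1
    #: proportion of women per group; equal by default (no sex imbalance)
    female_frac_patients: float = 0.5
    female_frac_controls: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise ValueError("need at least 3 regions")
        sizes = self.network_sizes
        if sizes is not None and sum(sizes) != self.n_regions:
            raise ValueError("network_sizes must sum to n_regions")
        if not 0.0 <= self.subtype_fraction <= 1.0:
            raise ValueError("subtype_fraction must be in [0, 1]")
        if self.planted_edges is not None:
            for i, j in self.planted_edges:
                if i == j:
                    raise ValueError(f"planted edge ({i},{j}) must join distinct regions")
                if not (1 <= i <= self.n_regions and 1 <= j <= self.n_regions):
                    raise ValueError(f"planted edge ({i},{j}) outside 1..{self.n_regions}")
        hi = max(abs(self.within_r), abs(self.between_r)) + abs(self.effect_size)
        if hi >= 1.0:
            raise ValueError("effect_size pushes latent correlations outside (-1, 1)")

    def resolved_network_sizes(self) -> tuple[int, ...]:
        if self.network_sizes is not None:
            return tuple(self.network_sizes)
        base = self.n_regions // self.n_networks
        sizes = [base] * self.n_networks
        for i in range(self.n_regions - base * self.n_networks):
            sizes[i] += 1
        return tuple(sizes)


def demo_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Desk-scale cohort used by examples and the demo pipeline:
    60 regions, 40+40 subjects, 150 timepoints, 10 planted edges."""
    base = SyntheticSpec(
        n_regions=60, n_controls=40, n_patients=40, n_timepoints=150,
        n_planted=10, effect_size=0.4, subject_sd=0.05, seed=seed,
    )
    return replace(base, **overrides) if overrides else base


@dataclass
class GroundTruth:
    """What was planted: edges (1-based pairs and 0-based edge-vector
    indices), per-edge shift signs, heterogeneity edges, and per-subject
    subtype and heterogeneity loading.

    Per-subject latent matrices are not stored (they are large at full
    scale); rebuild one with :func:`subject_latent`.
    """

    planted_edges: list[tuple[int, int]]
    planted_signs: list[int]
    planted_indices: list[int]
    het_edges: list[tuple[int, int]]
    het_indices: list[int]
    subtype: dict[str, int]
    het_loading: dict[str, float]
    spec: SyntheticSpec

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_edges": [list(e) for e in self.planted_edges],
            "planted_signs": self.planted_signs,
            "planted_indices": self.planted_indices,
            "het_edges": [list(e) for e in self.het_edges],
            "het_indices": self.het_indices,
            "subtype": self.subtype,
            "het_loading": self.het_loading,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# latent structure
# ---------------------------------------------------------------------------

def repair_correlation(m: np.ndarray, floor: float = PD_FLOOR) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and rescale to unit diagonal so the
    result is a valid (strictly positive definite) correlation matrix."""
    m = (m + m.T) / 2.0
    vals, vecs = np.linalg.eigh(m)
    if vals.min() < floor:
        vals = np.clip(vals, floor, None)
        m = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    if np.linalg.eigvalsh(m).min() <= 0:
        raise ValueError("correlation matrix not positive definite after repair")
    return m


def _block_baseline(spec: SyntheticSpec) -> np.ndarray:
    sizes = spec.resolved_network_sizes()
    labels = np.repeat(np.arange(len(sizes)), sizes)
    same = labels[:, None] == labels[None, :]
    m = np.where(same, spec.within_r, spec.between_r).astype(float)
    np.fill_diagonal(m, 1.0)
    return m


def build_latent_covariance(
    spec: SyntheticSpec,
    group: str,
    subtype: int = 1,
    het_loading: float | None = None,
) -> np.ndarray:
    """Latent correlation matrix for one group (and patient subtype).

    Controls get the block baseline.  Patients additionally get the shared
    planted shifts, and — when heterogeneity is configured — the subtype's
    signed shift of size ``het_loading * het_effect`` on the heterogeneity
    edges (``het_loading`` defaults to 1).  The result is repaired to a
    strictly positive-definite unit-diagonal matrix.
    """
    if group not in (PATIENT, CONTROL):
        raise ValueError(f"group must be '{PATIENT}' or '{CONTROL}'")
    truth = plant_edges(spec)
    m = _block_baseline(spec)
    if group == PATIENT:
        for (i, j), s in zip(truth.planted_edges, truth.planted_signs):
            m[i - 1, j - 1] = m[j - 1, i - 1] = m[i - 1, j - 1] + s * spec.effect_size
        if truth.het_edges:
            w = 1.0 if het_loading is None else het_loading
            shift = (1 if subtype == 1 else -1) * w * spec.het_effect
            for i, j in truth.het_edges:
                v = np.clip(m[i - 1, j - 1] + shift, -0.95, 0.95)
                m[i - 1, j - 1] = m[j - 1, i - 1] = v
    return repair_correlation(m)


def plant_edges(spec: SyntheticSpec) -> GroundTruth:
    """Resolve the planted-edge sets (drawing random ones where the spec
    leaves them open) without generating any subjects."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xED6E]))
    p = spec.n_regions
    e = n_edges(p)

    def draw_pairs(n: int, excluded: set[int]) -> list[tuple[int, int]]:
        pairs: list[tuple[int, int]] = []
        seen = set(excluded)
        while len(pairs) < n:
            i, j = sorted(rng.choice(p, size=2, replace=False))
            k = edge_index(int(i), int(j), p)
            if k not in seen:
                seen.add(k)
                pairs.append((int(i) + 1, int(j) + 1))
        return pairs

    if spec.planted_edges is not None:
        planted = [tuple(int(v) for v in pair) for pair in spec.planted_edges]
    else:
        if spec.n_planted > e:
            raise ValueError("more planted edges requested than exist")
        planted = draw_pairs(spec.n_planted, set())
    planted_idx = [edge_index(i - 1, j - 1, p) for i, j in planted]

    if spec.planted_signs is not None:
        if len(spec.planted_signs) != len(planted):
            raise ValueError("planted_signs must match planted_edges in length")
        signs = [int(s) for s in spec.planted_signs]
    else:
        signs = [int(s) for s in rng.choice([-1, 1], size=len(planted))]

    het: list[tuple[int, int]] = []
    if spec.subtype_fraction > 0:
        if spec.het_edges is not None:
            het = [tuple(int(v) for v in pair) for pair in spec.het_edges]
        else:
            het = draw_pairs(spec.n_het, set(planted_idx))
    het_idx = [edge_index(i - 1, j - 1, p) for i, j in het]
    if set(het_idx) & set(planted_idx):
        raise ValueError("heterogeneity edges must be disjoint from planted edges")

    return GroundTruth(
        planted_edges=planted, planted_signs=signs, planted_indices=planted_idx,
        het_edges=het, het_indices=het_idx, subtype={}, het_loading={}, spec=spec,
    )


def subject_latent(truth: GroundTruth, subject_id: str) -> np.ndarray:
    """Rebuild the latent correlation matrix of one generated subject."""
    sub = truth.subtype.get(subject_id)
    if sub is None or sub == 0:
        return build_latent_covariance(truth.spec, CONTROL)
    return build_latent_covariance(
        truth.spec, PATIENT, subtype=sub,
        het_loading=abs(truth.het_loading.get(subject_id, 1.0)),
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_subject_timeseries(
    latent: np.ndarray,
    n_timepoints: int,
    subject_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one subject's (T, P) Gaussian time series.

    The latent correlation matrix is first jittered on its off-diagonals
    by N(0, subject_sd^2) and repaired; rows are then i.i.d. multivariate
    normal with that subject-specific correlation.
    """
    latent = np.asarray(latent, dtype=float)
    p = latent.shape[0]
    if np.linalg.eigvalsh(latent).min() <= 0:
        raise ValueError("latent matrix must be positive definite")
    if n_timepoints < p / 4:
        warnings.warn(
            f"T={n_timepoints} is small relative to P={p}; sample correlations "
            "will be unstable", stacklevel=2,
        )
    if subject_sd > 0:
        noise = rng.normal(0.0, subject_sd, size=(p, p))
        noise = (noise + noise.T) / 2.0
        np.fill_diagonal(noise, 0.0)
        subject_corr = repair_correlation(np.clip(latent + noise, -0.99, 0.99))
    else:
        subject_corr = latent
    chol = np.linalg.cholesky(subject_corr)
    z = rng.standard_normal((n_timepoints, p))
    return z @ chol.T


def generate_cohort(spec: SyntheticSpec) -> tuple[list[SubjectRecord], GroundTruth]:
    """Generate the full cohort: per-subject time series, group labels,
    synthetic covariates and the ground-truth record.

    Byte-reproducible: the same spec (including seed) always yields the
    same cohort.  Subtype 2 receives ``floor(subtype_fraction * n_patients)``
    patients.
    """
    truth = plant_edges(spec)
    root = np.random.SeedSequence([spec.seed, 0xC0807])
    cov_rng = np.random.default_rng(root.spawn(1)[0])

    n_sub2 = int(np.floor(spec.subtype_fraction * spec.n_patients)) if spec.subtype_fraction > 0 else 0
    control_latent = build_latent_covariance(spec, CONTROL)

    records: list[SubjectRecord] = []
    streams = root.spawn(spec.n_patients + spec.n_controls + 1)[1:]
    idx = 0
    for g, count in ((PATIENT, spec.n_patients), (CONTROL, spec.n_controls)):
        for k in range(count):
            rng = np.random.default_rng(streams[idx])
            idx += 1
            sid = f"sub-{('p' if g == PATIENT else 'c')}{k + 1:03d}"
            if g == PATIENT:
                sub = 2 if k >= spec.n_patients - n_sub2 else 1
                loading = 0.0
                if truth.het_edges:
                    loading = (1 if sub == 1 else -1) * abs(
                        rng.normal(1.0, spec.het_loading_sd))
                latent = build_latent_covariance(
                    spec, PATIENT, subtype=sub, het_loading=abs(loading))
                truth.subtype[sid] = sub
                truth.het_loading[sid] = float(loading)
            else:
                sub = None
                latent = control_latent
                truth.subtype[sid] = 0
                truth.het_loading[sid] = 0.0
            ts = sample_subject_timeseries(
                latent, spec.n_timepoints, spec.subject_sd, rng)
            records.append(_with_covariates(sid, g, sub, ts, cov_rng, spec))
    return records, truth


def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    return shape, mean / shape


def _with_covariates(sid, group, subtype, ts, rng, spec) -> SubjectRecord:
    # marginals chosen to match the reference cohort's demographics:
    # age ~ Normal, mean FD ~ Gamma, sex/medication ~ Bernoulli
    if group == PATIENT:
        age = float(np.clip(rng.normal(37.16, 12.197), 18, 75))
        female = rng.random() < spec.female_frac_patients
        shape, scale = _gamma_params(0.090, 0.0360)
        fd = float(rng.gamma(shape, scale))
        return SubjectRecord(
            subject_id=sid, group=group, subtype=subtype, timeseries=ts,
            age=age, sex="F" if female else "M",
            duration=float(max(rng.normal(12.45, 9.163), 0.0)),
            ymrs=float(max(rng.normal(3.41, 4.429), 0.0)),
            madrs=float(max(rng.normal(12.07, 10.830), 0.0)),
            med_antipsychotic=bool(rng.random() < 0.505),
            med_antidepressant=bool(rng.random() < 0.339),
            med_mood_stabilizer=bool(rng.random() < 0.625),
            mean_fd=fd,
        )
    age = float(np.clip(rng.normal(35.65, 8.934), 18, 75))
    female = rng.random() < spec.female_frac_controls
    shape, scale = _gamma_params(0.085, 0.0381)
    return SubjectRecord(
        subject_id=sid, group=group, timeseries=ts,
        age=age, sex="F" if female else "M",
        mean_fd=float(rng.gamma(shape, scale)),
    )


# ---------------------------------------------------------------------------
# on-disk cohort
# ---------------------------------------------------------------------------

def manifest_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id, "group": r.group,
            "subtype": r.subtype if r.subtype is not None else "",
            "age": r.age, "sex": r.sex, "duration": r.duration,
            "ymrs": r.ymrs, "madrs": r.madrs,
            "med_antipsychotic": r.med_antipsychotic,
            "med_antidepressant": r.med_antidepressant,
            "med_mood_stabilizer": r.med_mood_stabilizer,
            "mean_fd": r.mean_fd,
        })
    return pd.DataFrame(rows)


def write_cohort(records: Sequence[SubjectRecord], truth: GroundTruth,
                 out_dir: str | Path) -> None:
    """Write manifest CSV, per-subject time-series TSVs, the atlas derived
    from the spec's network blocks, and the ground-truth JSON."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    manifest_frame(records).to_csv(out / "manifest.csv", index=False)
    for r in records:
        write_timeseries(r.timeseries, out / "timeseries" / f"{r.subject_id}.tsv")
    spec = truth.spec
    RegionAtlas.uniform(spec.n_regions, sizes=spec.resolved_network_sizes()).to_csv(
        out / "atlas.csv")
    truth.to_json(out / "ground_truth.json")


def read_cohort(in_dir: str | Path) -> list[SubjectRecord]:
    """Load a cohort written by :func:`write_cohort` (or hand-assembled in
    the same layout) back into SubjectRecords."""
    from .connectome import read_timeseries

    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    records = []
    for _, row in manifest.iterrows():
        ts = read_timeseries(in_dir / "timeseries" / f"{row['subject_id']}.tsv")
        subtype = row.get("subtype")
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]), group=str(row["group"]),
            subtype=int(subtype) if pd.notna(subtype) and str(subtype) != "" else None,
            timeseries=ts,
            age=float(row.get("age", np.nan)),
            sex=str(row["sex"]) if pd.notna(row.get("sex")) else None,
            duration=float(row.get("duration", np.nan)) if pd.notna(row.get("duration")) else np.nan,
            ymrs=float(row.get("ymrs", np.nan)) if pd.notna(row.get("ymrs")) else np.nan,
            madrs=float(row.get("madrs", np.nan)) if pd.notna(row.get("madrs")) else np.nan,
            med_antipsychotic=bool(row["med_antipsychotic"]) if pd.notna(row.get("med_antipsychotic")) else None,
            med_antidepressant=bool(row["med_antidepressant"]) if pd.notna(row.get("med_antidepressant")) else None,
            med_mood_stabilizer=bool(row["med_mood_stabilizer"]) if pd.notna(row.get("med_mood_stabilizer")) else None,
            mean_fd=float(row["mean_fd"]),
        ))
    return records
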
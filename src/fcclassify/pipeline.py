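"""End-to-end orchestration: simulate -> connectivity -> nested-CV
classification -> similarity panel -> confound screen -> summary bundle.

A single YAML config drives every stage; every output directory gets a
``run_log.json`` recording the config hash, the global seed and package
versions, and the ``summary.json`` is deterministic (byte-identical under
a fixed config), so any stage can be re-run and checked against a stored
result.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import SVMConfig, control_experiment, major_features, repeat_partitions
from .confounds import confound_screen
from .connectome import (
    RegionAtlas,
    features_table,
    filter_by_fd,
    read_features,
    write_features,
)
from .mrmr import DiscretizationRule
from .similarity import similarity_panel
from .synthetic import (
    SyntheticSpec,
    generate_cohort,
    manifest_frame,
    read_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one analysis run needs.  ``simulation`` is a
    SyntheticSpec used when no real manifest/time-series inputs are given."""

    out_dir: str = "fcclassify_out"
    seed: int = 0
    fd_threshold: float = 0.2
    # inputs (ignored when simulation is set)
    input_dir: Optional[str] = None
    simulation: Optional[SyntheticSpec] = None
    # mRMR settings
    mrmr_scheme: str = "three_bin_mean_sd"
    mrmr_alpha: float = 0.5
    mrmr_redundancy: str = "mean"
    mrmr_max_k: int = 30
    mrmr_drop_ratio: Optional[float] = None
    # CV settings
    n_outer_folds: int = 10
    inner_folds: int = 10
    repetitions: int = 100
    c_grid: Optional[tuple[float, ...]] = None
    scale_factors: Optional[tuple[float, ...]] = None
    major_min_count: int = 9
    # controls
    run_low_score: bool = True
    run_random: bool = True
    # similarity
    similarity_test: str = "ttest"
    similarity_permutations: int = 5000

    def mrmr_rule(self) -> DiscretizationRule:
        return DiscretizationRule(scheme=self.mrmr_scheme, alpha=self.mrmr_alpha)

    def svm_config(self) -> SVMConfig:
        kwargs = {"inner_folds": self.inner_folds}
        if self.c_grid is not None:
            kwargs["c_grid"] = tuple(float(c) for c in self.c_grid)
        if self.scale_factors is not None:
            kwargs["scale_factors"] = tuple(float(s) for s in self.scale_factors)
        return SVMConfig(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SyntheticSpec(**{
                k: tuple(tuple(p) for p in v) if k in ("planted_edges", "het_edges") and v is not None
                else (tuple(v) if isinstance(v, list) else v)
                for k, v in sim.items()
            })
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; returns the summary dict and writes
    the full report bundle under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- stage: inputs -----------------------------------------------------
    if config.simulation is not None:
        records, truth = generate_cohort(config.simulation)
        write_cohort(records, truth, out / "cohort")
        atlas = RegionAtlas.uniform(
            config.simulation.n_regions,
            sizes=config.simulation.resolved_network_sizes())
        truth_info = {
            "planted_indices": truth.planted_indices,
            "het_indices": truth.het_indices,
        }
    elif config.input_dir is not None:
        in_dir = Path(config.input_dir)
        atlas_path = in_dir / "atlas.csv"
        if not atlas_path.exists():
            raise FileNotFoundError(f"atlas file not found: {atlas_path}")
        atlas = RegionAtlas.from_csv(atlas_path)
        records = read_cohort(in_dir)
        truth_info = None
    else:
        raise ValueError("config must provide either 'simulation' or 'input_dir'")

    # ---- stage: QC + features ---------------------------------------------
    n_before = len(records)
    records = filter_by_fd(records, config.fd_threshold)
    x, y, subject_ids = features_table(records)
    write_features(x, subject_ids, out / "features.csv", out / "edge_map.json")
    manifest = manifest_frame(records)

    # ---- stage: nested-CV classification -----------------------------------
    rule = config.mrmr_rule()
    svm = config.svm_config()
    repeated = repeat_partitions(
        x, y, n_repetitions=config.repetitions, base_seed=config.seed,
        svm_config=svm, mrmr_rule=rule, n_outer=config.n_outer_folds,
        max_k=config.mrmr_max_k, redundancy=config.mrmr_redundancy,
        drop_ratio=config.mrmr_drop_ratio,
    )
    repeated.summary.to_csv(out / "repetitions.csv", index=False)
    optimal = repeated.optimal
    _write_fold_detail(optimal, out / "optimal_folds.json")
    mf = major_features(optimal, x, y, atlas=atlas,
                        min_count=config.major_min_count)
    mf.to_csv(out / "major_features.csv", index=False)
    _write_roc_points(optimal, out / "roc_points.csv")

    # ---- stage: controls ----------------------------------------------------
    controls = {}
    n_sel = max(1, int(round(optimal.mean_k_selected())))
    if config.run_low_score:
        controls["low_score"] = control_experiment(
            x, y, "low_score", n_sel, seed=config.seed, svm_config=svm,
            mrmr_rule=rule, n_outer=config.n_outer_folds)
    if config.run_random:
        controls["random"] = control_experiment(
            x, y, "random", n_sel, seed=config.seed, svm_config=svm,
            n_outer=config.n_outer_folds)

    # ---- stage: similarity --------------------------------------------------
    labels = manifest["group"].to_numpy()
    panel = similarity_panel(
        x, labels, rule=rule, max_k=config.mrmr_max_k,
        redundancy=config.mrmr_redundancy, drop_ratio=config.mrmr_drop_ratio,
        test=config.similarity_test, seed=config.seed,
        n_permutations=config.similarity_permutations,
    )
    pd.DataFrame([dataclasses.asdict(r) for r in panel]).to_csv(
        out / "similarity_panel.csv", index=False)

    # ---- stage: confounds ---------------------------------------------------
    if len(mf):
        feat_cols = pd.DataFrame(
            {f"e{int(k)}": x[:, int(k)] for k in mf["edge"]},
            index=pd.Index(subject_ids, name="subject_id"))
    else:
        feat_cols = pd.DataFrame(index=pd.Index(subject_ids, name="subject_id"))
    report = confound_screen(feat_cols, manifest)
    report.table.to_csv(out / "confounds.csv", index=False)

    # ---- summary ------------------------------------------------------------
    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects_input": n_before,
        "n_subjects_after_fd_filter": len(records),
        "n_edges": int(x.shape[1]),
        "classification": {
            "repetitions": config.repetitions,
            "across_repetitions": repeated.aggregate(),
            "optimal": {k: round(v, 6) for k, v in optimal.summary.items()},
            "mean_features_selected": round(float(np.mean(
                [r.mean_k_selected() for r in repeated.repetitions])), 3),
        },
        "controls": {
            name: {k: round(v, 6) for k, v in cv.summary.items()}
            for name, cv in controls.items()
        },
        "major_features": mf.drop(
            columns=[c for c in ("name_i", "name_j") if c in mf.columns]
        ).to_dict(orient="records"),
        "similarity": [
            {k: (round(v, 6) if isinstance(v, float) else v)
             for k, v in dataclasses.asdict(r).items()}
            for r in panel
        ],
        "confounds": {
            "n_tests": int(len(report.table)),
            "n_significant_q05": int((report.table["q"] < 0.05).sum())
            if len(report.table) else 0,
            "fd_group_test": {k: round(v, 6) for k, v in
                              report.fd_group_test.items()},
        },
    }
    if truth_info is not None:
        summary["ground_truth"] = truth_info
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out / "run_log.json").write_text(json.dumps({
        "fcclassify_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
    }, indent=2, sort_keys=True, default=str) + "\n")
    return summary


def _write_fold_detail(cv, path: Path) -> None:
    detail = {
        "seed": cv.seed,
        "summary": cv.summary,
        "folds": [
            {
                "fold": f.fold,
                "selected_edges": [int(k) for k in f.selected],
                "k_selected": f.k_selected,
                "C": f.c,
                "kernel_scale": f.scale,
                "metrics": f.metrics,
            }
            for f in cv.folds
        ],
    }
    path.write_text(json.dumps(detail, indent=2, sort_keys=True))


def _write_roc_points(cv, path: Path) -> None:
    from sklearn.metrics import roc_curve

    y_true = np.concatenate([f.y_true for f in cv.folds])
    scores = np.concatenate([f.scores for f in cv.folds])
    fpr, tpr, thr = roc_curve(y_true, scores)
    pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).to_csv(
        path, index=False)


def demo_config(out_dir: str | Path, seed: int = 0) -> PipelineConfig:
    """The self-contained demonstration run: a 60-region, 40+40-subject
    heterogeneous cohort with 10 planted shared edges, 5 CV repetitions
    and a compact hyperparameter grid."""
    sim = SyntheticSpec(
        n_regions=60, n_controls=40, n_patients=40, n_timepoints=150,
        n_planted=10, effect_size=0.4, subject_sd=0.05,
        subtype_fraction=0.5, n_het=20, het_effect=0.25, seed=seed,
    )
    compact = SVMConfig.compact()
    return PipelineConfig(
        out_dir=str(out_dir), seed=seed, simulation=sim,
        repetitions=5, inner_folds=compact.inner_folds,
        c_grid=compact.c_grid, scale_factors=compact.scale_factors,
        mrmr_max_k=30,
    )


def make_demo_fixture(out_dir: str | Path, seed: int = 0) -> Path:
    """Write the demo dataset (manifest, time series, atlas, ground truth)
    and its pipeline config; returns the config path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = demo_config(out / "results", seed=seed)
    records, truth = generate_cohort(cfg.simulation)
    write_cohort(records, truth, out / "cohort")
    cfg_on_disk = dataclasses.replace(cfg, simulation=None,
                                      input_dir=str(out / "cohort"))
    cfg_path = out / "config.yaml"
    cfg_on_disk.to_yaml(cfg_path)
    return cfg_path
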
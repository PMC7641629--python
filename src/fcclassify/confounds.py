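"""Confound screening of consensus edges against clinical covariates.

Continuous covariates (illness duration, symptom scores, mean framewise
displacement) are screened with Pearson correlations; binary covariates
(medication flags, sex) with independent two-sample t-tests (pooled
variance by default, Welch optional).  Benjamini-Hochberg FDR correction
is applied per covariate family across features.  A pooled two-proportion
z-test compares classifier accuracies between analysis variants, and a
summary-statistics t-test mode lets published group mean/sd/n rows be
checked without raw data.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def pearson_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided p from t = r sqrt((n-2)/(1-r^2)) on
    n-2 degrees of freedom.  Constant input is a hard error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def independent_ttest(
    a: Optional[np.ndarray] = None,
    b: Optional[np.ndarray] = None,
    variant: str = "student",
    summary: Optional[tuple[tuple[float, float, int], tuple[float, float, int]]] = None,
) -> tuple[float, float, float]:
    """Two-sided independent-samples t-test; returns (t, df, p).

    ``variant`` selects the pooled-variance Student test (default) or
    Welch.  ``summary`` takes ((mean, sd, n), (mean, sd, n)) so published
    group rows can be tested without raw data.  Two zero-variance groups
    with equal means return t=0, p=1 by convention.
    """
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    equal_var = variant == "student"
    if summary is not None:
        (m1, s1, n1), (m2, s2, n2) = summary
        res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                         equal_var=equal_var)
        df = n1 + n2 - 2 if equal_var else _welch_df(s1, n1, s2, n2)
        return float(res.statistic), float(df), float(res.pvalue)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else _welch_df(
        np.std(a, ddof=1), a.size, np.std(b, ddof=1), b.size)
    return float(res.statistic), float(df), float(res.pvalue)


def _welch_df(s1: float, n1: int, s2: float, n2: int) -> float:
    v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
    return (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} m p_(j)/j,
    clipped at 1 (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test, two-sided.

    z = (p1 - p2) / sqrt(p (1-p) (1/n1 + 1/n2)) with p the pooled
    proportion.  A degenerate pooled proportion of exactly 0 or 1 returns
    p = 1 with a warning.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise ValueError("need 0 <= successes <= n with n >= 1")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("pooled proportion is degenerate (0 or 1); returning p=1",
                      stacklevel=2)
        return 0.0, 1.0
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


CONTINUOUS_COVARIATES = ("duration", "ymrs", "madrs", "mean_fd")
BINARY_COVARIATES = ("med_antipsychotic", "med_antidepressant",
                     "med_mood_stabilizer", "sex")


@dataclass
class ConfoundReport:
    """Per (feature, covariate) statistics with BH q-values computed per
    covariate family, plus the one-off patient-vs-control FD contrast."""

    table: pd.DataFrame
    fd_group_test: dict

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < q_threshold]


def confound_screen(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    continuous: Sequence[str] = CONTINUOUS_COVARIATES,
    binary: Sequence[str] = BINARY_COVARIATES,
    variant: str = "student",
) -> ConfoundReport:
    """Screen each consensus-feature column against every covariate.

    ``features`` is (subjects x major features) indexed by subject id;
    ``manifest`` carries covariates plus a ``group`` column.  Clinical
    covariates (duration, symptoms, medication) are screened within the
    patient group only; mean FD and sex across all subjects.  Covariates
    that are entirely missing or constant are skipped with a log entry.
    The patient-vs-control FD difference is tested once.
    """
    manifest = manifest.set_index("subject_id") if "subject_id" in manifest.columns else manifest
    manifest = manifest.loc[features.index]
    is_patient = (manifest["group"] == "patient").to_numpy()
    rows = []
    if features.shape[1] == 0:
        logger.info("empty major-feature set; confound report is empty")
    for cov in continuous:
        if cov not in manifest.columns:
            continue
        patient_only = cov != "mean_fd"
        mask = is_patient if patient_only else np.ones(len(manifest), bool)
        vals = pd.to_numeric(manifest[cov], errors="coerce").to_numpy()[mask]
        ok = np.isfinite(vals)
        if ok.sum() < 3 or np.std(vals[ok]) == 0:
            logger.info("skipping covariate %r (missing or constant)", cov)
            continue
        for feat in features.columns:
            fv = features[feat].to_numpy()[mask][ok]
            r, p = pearson_test(fv, vals[ok])
            rows.append({"feature": feat, "covariate": cov,
                         "kind": "continuous", "statistic": r, "p": p})
    for cov in binary:
        if cov not in manifest.columns:
            continue
        patient_only = cov != "sex"
        mask = is_patient if patient_only else np.ones(len(manifest), bool)
        raw = manifest[cov].to_numpy()[mask]
        lab = pd.Series(raw).astype(str).to_numpy()
        levels = np.unique(lab[lab != "nan"])
        if levels.size != 2:
            logger.info("skipping covariate %r (not binary in this cohort)", cov)
            continue
        g1, g2 = lab == levels[0], lab == levels[1]
        if g1.sum() < 2 or g2.sum() < 2:
            logger.info("skipping covariate %r (a level has < 2 members)", cov)
            continue
        for feat in features.columns:
            fv = features[feat].to_numpy()[mask]
            t, _, p = independent_ttest(fv[g1], fv[g2], variant=variant)
            rows.append({"feature": feat, "covariate": cov,
                         "kind": "binary", "statistic": t, "p": p})
    table = pd.DataFrame(rows, columns=["feature", "covariate", "kind",
                                        "statistic", "p"])
    if len(table):
        table["q"] = np.nan
        for cov, grp in table.groupby("covariate"):
            table.loc[grp.index, "q"] = bh_fdr(grp["p"].to_numpy())
    else:
        table["q"] = pd.Series(dtype=float)

    fd = pd.to_numeric(manifest["mean_fd"], errors="coerce").to_numpy()
    t, df, p = independent_ttest(fd[is_patient], fd[~is_patient], variant=variant)
    fd_group_test = {
        "patient_mean": float(np.nanmean(fd[is_patient])),
        "control_mean": float(np.nanmean(fd[~is_patient])),
        "t": t, "df": df, "p": p,
    }
    return ConfoundReport(table=table, fd_group_test=fd_group_test)
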
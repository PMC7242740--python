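"""Treatment-response statistics over single-cell endpoint tables.

Effect sizes are Glass's Delta, standardizing the control-vs-treated mean
difference by the control SD (individual-cell sample sizes are large enough
that conventional significance tests are always passed, so the effect size
carries the response magnitude).  The sign convention makes a treatment-
induced *decrease* positive, matching the response direction of the OMI
index.  The predicted-responder rule combines a Glass's Delta of the OMI
index at or above 0.75 with a treatment-induced decrease in the wH-index.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from . import heterogeneity as het

DELTA_THRESHOLD = 0.75


class Classification(str, Enum):
    RESPONDER = "predicted_responder"
    NON_RESPONDER = "predicted_non_responder"
    INDETERMINATE = "indeterminate"


def glass_delta(treated: np.ndarray, control: np.ndarray) -> float:
    """Glass's Delta = (mean(control) - mean(treated)) / SD(control, ddof=1).

    Positive when the treated mean decreased (the response direction for the
    OMI index).
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("need at least 2 observations per group")
    sd = control.std(ddof=1)
    if sd == 0:
        raise ValueError("control SD is zero: Glass's Delta undefined")
    return float((control.mean() - treated.mean()) / sd)


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have n <= 10 and no ties; otherwise the
    normal approximation with tie and continuity corrections.  Capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(a) <= 10 and len(b) <= 10 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    p = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True).pvalue
    return float(min(p, 1.0))


def classify_response(
    delta_omi: float,
    wh_control: float,
    wh_treated: float,
    threshold: float = DELTA_THRESHOLD,
) -> Classification:
    """Predicted-responder call from the OMI-index effect size and wH change.

    predicted_responder iff Glass's Delta >= threshold (inclusive) and the
    wH-index decreased with treatment; equal wH values are indeterminate;
    everything else is predicted_non_responder.
    """
    for v in (delta_omi, wh_control, wh_treated):
        if not np.isfinite(v):
            raise ValueError("classification inputs must be finite")
    delta_wh = wh_treated - wh_control
    if delta_wh == 0.0:
        return Classification.INDETERMINATE
    if delta_omi >= threshold and delta_wh < 0.0:
        return Classification.RESPONDER
    return Classification.NON_RESPONDER


def variance_explained(values: np.ndarray, groups: np.ndarray) -> float:
    """Percent of a scalar endpoint's variance explained by group membership.

    OLS of the endpoint on group-indicator variables; returns 100 x adjusted
    R-squared (which may be slightly negative under the null; reported raw).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 cells")
    dummies = np.eye(len(labels))[codes][:, 1:]  # first group absorbed in intercept
    model = sm.OLS(values, sm.add_constant(dummies)).fit()
    return float(100.0 * model.rsquared_adj)


def variance_partition(
    cells: pd.DataFrame,
    endpoints: list[str],
    level: str = "organoid",
) -> pd.DataFrame:
    """Hierarchical variance partitioning of untreated cells at first timepoint.

    ``level="organoid"``: per patient and endpoint, the percentage of that
    patient's cell-level variation explained by organoid membership.
    ``level="patient"``: per endpoint, across all patients' cells, the
    percentage explained by patient membership.  Only control cells from each
    patient's earliest timepoint enter, mirroring a baseline analysis.
    """
    if level not in ("organoid", "patient"):
        raise ValueError("level must be 'organoid' or 'patient'")
    controls = cells[cells["treatment"] == "control"]
    first = controls.groupby("patient_id")["timepoint_h"].transform("min")
    baseline = controls[controls["timepoint_h"] == first]
    rows = []
    if level == "organoid":
        for patient, sub in baseline.groupby("patient_id"):
            for ep in endpoints:
                ok = sub[ep].notna()
                try:
                    pct = variance_explained(sub.loc[ok, ep], sub.loc[ok, "organoid_id"])
                except ValueError:
                    continue
                rows.append({"patient_id": patient, "endpoint": ep,
                             "pct_explained": pct, "pct_explained_floored": max(pct, 0.0),
                             "n_cells": int(ok.sum()),
                             "n_groups": sub.loc[ok, "organoid_id"].nunique()})
    else:
        for ep in endpoints:
            ok = baseline[ep].notna()
            try:
                pct = variance_explained(baseline.loc[ok, ep], baseline.loc[ok, "patient_id"])
            except ValueError:
                continue
            rows.append({"endpoint": ep, "pct_explained": pct,
                         "pct_explained_floored": max(pct, 0.0),
                         "n_cells": int(ok.sum()),
                         "n_groups": baseline.loc[ok, "patient_id"].nunique()})
    return pd.DataFrame(rows)


def correlation_map(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise squared Pearson correlations between measurement columns.

    Returns the symmetric R-squared matrix (unit diagonal; constant columns
    reported as missing) and, per measurement, the count of *other*
    measurements with R-squared > 0.5.
    """
    numeric = table.select_dtypes(include=[np.number])
    if numeric.shape[1] < 2:
        raise ValueError("need at least two numeric measurement columns")
    r2 = numeric.corr(min_periods=3) ** 2
    off_diag = r2.where(~np.eye(len(r2), dtype=bool))
    partners = (off_diag > 0.5).sum(axis=1)
    return r2, partners


def multivariate_regression(dependent: np.ndarray, independents: pd.DataFrame) -> float:
    """Adjusted R-squared of an OLS fit with intercept.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    y = np.asarray(dependent, dtype=float)
    X = pd.DataFrame(independents)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > p + 1 observations")
    mat = X.to_numpy(dtype=float)
    full_rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), mat]))
    if full_rank < mat.shape[1] + 1:
        redundant = []
        for j, name in enumerate(X.columns):
            reduced = np.column_stack([np.ones(len(y)), np.delete(mat, j, axis=1)])
            if np.linalg.matrix_rank(reduced) == full_rank:
                redundant.append(str(name))
        raise ValueError(f"rank-deficient design; collinear columns: {redundant}")
    model = sm.OLS(y, sm.add_constant(mat)).fit()
    return float(model.rsquared_adj)


def cohort_summary(attempted: int, successful: int) -> dict:
    """Organoid-establishment success rate as an integer percent.

    Rounding is half away from zero, e.g. 14 of 22 -> 64%.
    """
    if attempted <= 0:
        raise ValueError("attempted must be positive")
    if not 0 <= successful <= attempted:
        raise ValueError("successful must lie in [0, attempted]")
    rate = successful / attempted * 100.0
    return {
        "attempted": attempted,
        "successful": successful,
        "failed": attempted - successful,
        "success_rate_pct": int(np.floor(rate + 0.5)),
        "success_rate_raw": rate,
    }


@dataclass
class GroupResponse:
    patient_id: str
    treatment: str
    timepoint_h: float
    glass_delta: float
    wilcoxon_p: float
    responds_flag: bool
    wh_control: float
    wh_treated: float
    delta_wh: float
    classification: Classification


def response_report(
    cells: pd.DataFrame,
    endpoint: str = "omi_index",
    threshold: float = DELTA_THRESHOLD,
    seed: int | None = 0,
    g_max: int = 3,
    adjust_p: bool = False,
) -> pd.DataFrame:
    """Per (patient, treatment, timepoint) response report on one endpoint.

    For every treated arm with a matching control stratum: Glass's Delta,
    Wilcoxon rank-sum p-value, the wH-index of the control and treated cell
    distributions, and the responder classification.  Raw p-values are
    reported by default; ``adjust_p`` applies Benjamini-Hochberg.
    """
    rows: list[GroupResponse] = []
    for (patient, timepoint), stratum in cells.groupby(["patient_id", "timepoint_h"]):
        control = stratum.loc[stratum["treatment"] == "control", endpoint].dropna().to_numpy()
        if len(control) < 2:
            continue
        wh_c = het.wh_index(het.select_model(control, g_max=g_max))
        for treatment, arm in stratum[stratum["treatment"] != "control"].groupby("treatment"):
            treated = arm[endpoint].dropna().to_numpy()
            if len(treated) < 5:
                continue
            wh_t = het.wh_index(het.select_model(treated, g_max=g_max))
            delta = glass_delta(treated, control)
            rows.append(GroupResponse(
                patient_id=patient, treatment=treatment, timepoint_h=timepoint,
                glass_delta=delta,
                wilcoxon_p=wilcoxon_rank_sum(treated, control),
                responds_flag=delta >= threshold,
                wh_control=wh_c, wh_treated=wh_t, delta_wh=wh_t - wh_c,
                classification=classify_response(delta, wh_c, wh_t, threshold),
            ))
    report = pd.DataFrame([vars(r) for r in rows])
    if adjust_p and not report.empty:
        report["wilcoxon_p_adj"] = multipletests(report["wilcoxon_p"], method="fdr_bh")[1]
    if not report.empty:
        report["classification"] = report["classification"].map(lambda c: c.value)
    return report
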
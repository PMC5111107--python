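"""Relapse-free-survival benchmarking of classifier outputs.

The benchmark statistic throughout is the two-group Cox proportional-hazards
hazard ratio (Efron handling of tied event times, Wald CIs and p-values).
Classifiers with more than two outputs are reduced to their best- and
worst-outcome cohorts (one-vs-rest log-hazard ranking) before the
comparison; intermediate and unclassified samples are excluded, as are
samples from a classifier's original training datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)


@dataclass
class SurvivalResult:
    comparison: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_group: dict[str, int]
    log_hr: float = float("nan")
    tie_handling: str = "efron"
    stage_filter: tuple[str, ...] | None = None
    covariates: pd.DataFrame | None = field(default=None, repr=False)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hazard_ratio <= self.ci_high):
            raise ValueError("CI must bracket the hazard ratio")


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite survival time")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    if not np.isin(e, (0.0, 1.0)).all():
        raise ValueError("events must be 0/1")
    return t, e


def cox_two_group(times, events, group, comparison: str = "group",
                  stage_filter=None) -> SurvivalResult:
    """Two-group Cox PH fit; HR is for group 1 relative to group 0."""
    t, e = _check_surv(times, events)
    g = np.asarray(group)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    # map to 0/1 keeping a natural order (0/1 or False/True stay as-is)
    try:
        order = np.sort(levels)
    except TypeError:
        order = levels
    ind = (g == order[1]).astype(float)
    for lvl, name in zip(order, ("reference", "comparison")):
        if e[g == lvl].sum() == 0:
            raise ValueError(f"group {lvl!r} has zero events")
    df = pd.DataFrame({"time": t, "event": e, "group": ind})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["group"])
    return SurvivalResult(
        comparison=comparison,
        hazard_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(cph.confidence_intervals_.iloc[0, 0])),
        ci_high=float(np.exp(cph.confidence_intervals_.iloc[0, 1])),
        p_value=float(cph.summary["p"].iloc[0]),
        n_group={str(order[0]): int((ind == 0).sum()),
                 str(order[1]): int((ind == 1).sum())},
        log_hr=coef,
        stage_filter=tuple(stage_filter) if stage_filter else None,
    )


def km_logrank(times, events, group) -> tuple[pd.DataFrame, float, float]:
    """Kaplan-Meier curve table per group plus the log-rank test.

    Returns (curve table with columns group/time/survival/at_risk/censored,
    log-rank chi-square, p).
    """
    t, e = _check_surv(times, events)
    g = pd.Series(group)
    curves = []
    for lvl in pd.unique(g):
        mask = (g == lvl).to_numpy()
        if e[mask].sum() == 0:
            raise ValueError(f"group {lvl!r} has zero events")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=str(lvl))
        tab = kmf.event_table.reset_index().rename(
            columns={"event_at": "time"})
        tab["survival"] = kmf.survival_function_.iloc[:, 0].to_numpy()
        tab["group"] = str(lvl)
        curves.append(tab[["group", "time", "survival", "at_risk",
                           "observed", "censored"]])
    if g.nunique() == 2:
        lv = pd.unique(g)
        m = (g == lv[0]).to_numpy()
        res = logrank_test(t[m], t[~m], e[m], e[~m])
        chi2, p = float(res.test_statistic), float(res.p_value)
    else:
        from lifelines.statistics import multivariate_logrank_test

        res = multivariate_logrank_test(t, g, e)
        chi2, p = float(res.test_statistic), float(res.p_value)
    return pd.concat(curves, ignore_index=True), chi2, p


def _join_calls_clinical(calls: pd.Series, clinical: pd.DataFrame,
                         stage_filter=None,
                         exclude_datasets=None,
                         dataset_of_origin: pd.Series | None = None
                         ) -> pd.DataFrame:
    df = pd.DataFrame({"label": calls}).join(clinical, how="inner")
    df = df.dropna(subset=["label", "rfs_time", "rfs_event"])
    if stage_filter:
        df = df[df["stage"].isin(list(stage_filter))]
    if exclude_datasets and dataset_of_origin is not None:
        excluded = dataset_of_origin.reindex(df.index).isin(
            list(exclude_datasets))
        n_ex = int(excluded.sum())
        if n_ex:
            logger.info("excluding %d training-set sample(s)", n_ex)
        df = df[~excluded]
    return df


def rank_labels_by_hazard(df: pd.DataFrame) -> pd.Series:
    """One-vs-rest log hazard per label (higher = worse outcome)."""
    out = {}
    for lbl in df["label"].unique():
        ind = (df["label"] == lbl).astype(float)
        sub = pd.DataFrame({"time": df["rfs_time"], "event": df["rfs_event"],
                            "x": ind})
        cph = CoxPHFitter()
        cph.fit(sub, duration_col="time", event_col="event")
        out[lbl] = float(cph.params_["x"])
    return pd.Series(out).sort_values()


def extreme_cohort_hr(
    calls: pd.Series,
    clinical: pd.DataFrame,
    stage_filter=None,
    exclude_datasets=None,
    dataset_of_origin: pd.Series | None = None,
    comparison: str | None = None,
) -> SurvivalResult:
    """Best-vs-worst-cohort hazard ratio for one classifier.

    Labels are ranked by one-vs-rest log hazard; the lowest (best outcome)
    and highest (worst outcome) labels go into a two-group Cox fit, with
    intermediate and unclassified samples excluded. For a two-label
    classifier this is exactly the plain two-group fit.
    """
    df = _join_calls_clinical(calls, clinical, stage_filter,
                              exclude_datasets, dataset_of_origin)
    if df.empty or df["label"].nunique() < 2:
        raise ValueError("need >= 2 labels with samples after exclusions")
    labels_with_events = [
        lbl for lbl in df["label"].unique()
        if df.loc[df["label"] == lbl, "rfs_event"].sum() > 0]
    if len(labels_with_events) < 2:
        raise ValueError("need >= 2 labels with >= 1 event each")
    df = df[df["label"].isin(labels_with_events)]
    ranked = rank_labels_by_hazard(df)
    best, worst = ranked.index[0], ranked.index[-1]
    sub = df[df["label"].isin([best, worst])]
    res = cox_two_group(
        sub["rfs_time"], sub["rfs_event"],
        (sub["label"] == worst).astype(int),
        comparison=comparison or f"{worst}_vs_{best}",
        stage_filter=stage_filter)
    res.n_group = {str(best): int((sub["label"] == best).sum()),
                   str(worst): int((sub["label"] == worst).sum())}
    return res


def univariate_gene_screen(
    matrix,
    clinical: pd.DataFrame,
    genes: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Median-split survival screen of individual genes.

    Each gene's cohort-median expression defines two groups (ties to the low
    group); a two-group Cox fit gives the gene's HR and p. Constant genes
    come back NA and are excluded from the significant-proportion
    denominators. Returns (per-gene table, {prop_p_lt_05, prop_p_lt_01}).
    """
    if genes is None:
        genes = list(matrix.values.index)
    shared = clinical.index.intersection(matrix.values.columns)
    clin = clinical.loc[shared].dropna(subset=["rfs_time", "rfs_event"])
    rows = []
    for g in genes:
        if g not in matrix.values.index:
            rows.append({"gene": g, "hazard_ratio": np.nan, "p_value": np.nan,
                         "status": "missing"})
            continue
        expr = matrix.values.loc[g, clin.index]
        med = expr.median(skipna=True)
        grp = (expr > med).astype(int)
        if grp.nunique() < 2:
            rows.append({"gene": g, "hazard_ratio": np.nan, "p_value": np.nan,
                         "status": "constant"})
            continue
        try:
            res = cox_two_group(clin["rfs_time"], clin["rfs_event"], grp,
                                comparison=g)
        except Exception as exc:  # zero events in a group, convergence, ...
            rows.append({"gene": g, "hazard_ratio": np.nan, "p_value": np.nan,
                         "status": f"failed: {type(exc).__name__}"})
            continue
        rows.append({"gene": g, "hazard_ratio": res.hazard_ratio,
                     "p_value": res.p_value, "status": "ok"})
    table = pd.DataFrame(rows)
    ok = table["p_value"].dropna()
    denom = max(len(ok), 1)
    props = {"prop_p_lt_05": float((ok < 0.05).sum()) / denom,
             "prop_p_lt_01": float((ok < 0.01).sum()) / denom}
    return table, props


def proportion_vs_hr_correlation(per_signature: pd.DataFrame
                                 ) -> tuple[float, float]:
    """Spearman rank correlation between per-signature proportion of
    significant genes and the per-signature hazard ratio.

    Expects columns ``prop_significant`` and ``hazard_ratio``.
    """
    rho, p = spearmanr(per_signature["prop_significant"],
                       per_signature["hazard_ratio"])
    return float(rho), float(p)


def multivariate_cox(
    calls: pd.Series,
    clinical: pd.DataFrame,
    covariates: list[str],
    comparison: str = "classifier",
    stage_filter=None,
) -> SurvivalResult:
    """Cox fit of the (binary) classifier indicator adjusted for covariates.

    Categorical covariates (msi, gender) are coded 0/1; expression
    covariates (e.g. mki67_expr, cdx2_expr) pass through numerically.
    Incomplete rows are listwise-deleted (count reported); covariates must
    remain available for at least half of the classified samples, and an
    (almost) collinear covariate pair aborts with the pair named.
    """
    df = _join_calls_clinical(calls, clinical, stage_filter)
    labels = df["label"].unique()
    if len(labels) != 2:
        raise ValueError("multivariate fit expects a binary classifier "
                         f"indicator, got labels {sorted(map(str, labels))}")
    order = np.sort(labels.astype(str))
    X = pd.DataFrame({"time": df["rfs_time"], "event": df["rfs_event"],
                      "classifier": (df["label"].astype(str) == order[1])
                      .astype(float)})
    for cov in covariates:
        if cov not in df.columns:
            raise KeyError(f"covariate {cov!r} missing from clinical table")
        col = df[cov]
        if col.dtype == object:
            lv = sorted(col.dropna().unique())
            if len(lv) > 2:
                raise ValueError(f"covariate {cov!r} has > 2 levels")
            X[cov] = col.map({lv[0]: 0.0, lv[-1]: 1.0}) if lv else np.nan
        else:
            X[cov] = pd.to_numeric(col, errors="coerce")
    n_before = len(X)
    X = X.dropna()
    n_dropped = n_before - len(X)
    if n_dropped:
        logger.info("multivariate_cox: dropped %d incomplete row(s)",
                    n_dropped)
    if len(X) < 0.5 * n_before:
        raise ValueError("covariates available for < 50% of classified "
                         "samples")
    cols = ["classifier"] + covariates
    corr = X[cols].corr().abs()
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if corr.loc[a, b] > 0.999:
                raise ValueError(f"collinear covariates: {a!r} and {b!r}")
    cph = CoxPHFitter()
    cph.fit(X, duration_col="time", event_col="event")
    coef = float(cph.params_["classifier"])
    ci = cph.confidence_intervals_.loc["classifier"]
    return SurvivalResult(
        comparison=comparison,
        hazard_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(ci.iloc[0])),
        ci_high=float(np.exp(ci.iloc[1])),
        p_value=float(cph.summary.loc["classifier", "p"]),
        n_group={str(order[0]): int((X["classifier"] == 0).sum()),
                 str(order[1]): int((X["classifier"] == 1).sum())},
        log_hr=coef,
        covariates=cph.summary.loc[covariates,
                                   ["coef", "exp(coef)", "p"]].copy(),
        n_dropped=n_dropped,
        stage_filter=tuple(stage_filter) if stage_filter else None,
    )
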
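"""Execution of formula-specified classifiers.

Every rule classifier decomposes into a scoring step (weighted sum,
product-ratio, signature mean, per-gene tally, group-mean comparison)
followed by a cutoff step (fixed thresholds, cohort median, tertiles,
dual-median). All rules are deterministic, and ties at cohort-relative
cutoffs fall to the lower (non-risk) group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .signatures import Signature, RuleSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubtypeCall:
    sample_id: str
    label: str | None
    classifier_name: str
    score: float | None = None
    confidence: float | None = None


def calls_to_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": c.sample_id, "classifier": c.classifier_name,
          "label": c.label, "score": c.score, "confidence": c.confidence}
         for c in calls])


def calls_to_series(calls: list[SubtypeCall]) -> pd.Series:
    """Label per sample (NaN for unclassified), indexed by sample id."""
    return pd.Series({c.sample_id: c.label for c in calls}, dtype=object)


# ---------------------------------------------------------------------------
# scoring primitives


def delta_ct_transform(
    matrix: ExpressionMatrix,
    housekeeping: list[str],
    constant: float = -15.0,
    mean_mode: str = "arithmetic",
) -> ExpressionMatrix:
    """Emulate RT-PCR delta-Ct values from array data.

    Per sample, each gene value becomes
    ``constant - (log2(mean(housekeeping)) - log2(gene))``. On a log2-scale
    matrix the arithmetic housekeeping mean is taken on the linear scale
    (mean of 2**x, then log2); ``mean_mode="geometric"`` averages the log2
    values directly. A gene whose expression equals the housekeeping mean
    maps exactly to ``constant``.
    """
    missing = [g for g in housekeeping if g not in matrix.values.index]
    if missing:
        raise KeyError(f"housekeeping gene(s) missing from matrix: {missing}")
    vals = matrix.values
    hk = vals.loc[housekeeping]
    if matrix.log2_scale:
        if mean_mode == "arithmetic":
            log2_mean = np.log2(np.exp2(hk).mean(axis=0))
        elif mean_mode == "geometric":
            log2_mean = hk.mean(axis=0)
        else:
            raise ValueError(f"unknown mean_mode {mean_mode!r}")
        log2_gene = vals
    else:
        if (vals <= 0).any().any():
            raise ValueError("nonpositive linear-scale value under log")
        if mean_mode == "arithmetic":
            log2_mean = np.log2(hk.mean(axis=0))
        elif mean_mode == "geometric":
            log2_mean = np.log2(hk).mean(axis=0)
        else:
            raise ValueError(f"unknown mean_mode {mean_mode!r}")
        log2_gene = np.log2(vals)
    out = constant - (log2_mean - log2_gene)
    return ExpressionMatrix(out, matrix.dataset_of_origin, matrix.platform)


def _covered(matrix: ExpressionMatrix, symbols: list[str],
             name: str) -> list[str]:
    present = [g for g in symbols if g in matrix.values.index]
    if not present:
        raise KeyError(f"{name}: no signature gene present in matrix")
    if len(present) < len(symbols):
        logger.warning("%s: %d of %d genes missing, scoring on shared subset",
                       name, len(symbols) - len(present), len(symbols))
    return present


def score_linear(matrix: ExpressionMatrix, sig: Signature) -> pd.Series:
    """Weighted gene sum: ``intercept + sum_g w_g * expr_g`` per sample."""
    weights = {g.symbol: g.weight for g in sig.genes}
    genes = _covered(matrix, list(weights), sig.name)
    w = pd.Series({g: weights[g] for g in genes})
    intercept = float(sig.rule.params.get("intercept", 0.0))
    return matrix.values.loc[genes].mul(w, axis=0).sum(axis=0) + intercept


def score_signature_mean(matrix: ExpressionMatrix, sig: Signature) -> pd.Series:
    """Unweighted mean of the signature genes (uniform weights, intercept 0)."""
    genes = _covered(matrix, sig.gene_symbols, sig.name)
    return matrix.values.loc[genes].mean(axis=0)


def score_product_ratio(matrix: ExpressionMatrix, sig: Signature) -> pd.Series:
    """Sum of signed absolute product-ratio terms on housekeeping-adjusted
    values (each gene minus the per-sample housekeeping mean).

    Samples with a zero denominator in any term get an undefined score (NaN)
    and are logged; they are called NA downstream.
    """
    needed = set(sig.gene_symbols) | set(sig.housekeeping)
    missing = [g for g in needed if g not in matrix.values.index]
    if missing:
        raise KeyError(f"{sig.name}: missing gene(s) {sorted(missing)}")
    vals = matrix.values
    if sig.housekeeping:
        adjusted = vals.loc[sig.gene_symbols].sub(
            vals.loc[sig.housekeeping].mean(axis=0), axis=1)
    else:
        adjusted = vals.loc[sig.gene_symbols]
    score = pd.Series(0.0, index=vals.columns)
    undefined = pd.Series(False, index=vals.columns)
    for term in sig.rule.params["terms"]:
        num = adjusted.loc[term["numerator"]].prod(axis=0)
        den = adjusted.loc[term["denominator"]].prod(axis=0)
        zero = den == 0
        undefined |= zero
        with np.errstate(divide="ignore", invalid="ignore"):
            score = score + term["sign"] * (num / den).abs()
    if undefined.any():
        logger.warning("%s: %d sample(s) with zero denominator -> NA",
                       sig.name, int(undefined.sum()))
        score[undefined] = np.nan
    return score


# ---------------------------------------------------------------------------
# cutoff primitives


def _call(sample, label, sig, score=None):
    return SubtypeCall(sample, label, sig.name,
                       None if score is None or not np.isfinite(score)
                       else float(score))


def classify_by_cutoff(
    scores: pd.Series | pd.DataFrame,
    rule: RuleSpec,
    sig: Signature,
) -> list[SubtypeCall]:
    """Turn per-sample scores into labels under the rule's cutoff mode.

    - ``fixed``: one cutoff c maps score <= c to the lower label and > c to
      the upper; two cutoffs c1 < c2 map < c1 / [c1, c2] / > c2 to the three
      labels in order (boundary values go to the middle group).
    - ``cohort_median``: split at the cohort median, ties to the lower group.
    - ``tertile``: three equal-quantile groups, ties to the lower group.
    - ``dual_median`` (DataFrame of two score columns): upper label only when
      both sub-scores strictly exceed their own cohort medians.

    Undefined (NaN) scores yield NA calls. Cohort-relative modes with fewer
    than 2 distinct scores yield all-NA with a warning.
    """
    params = rule.params
    mode = params.get("cutoff_mode", "fixed")
    if rule.kind == "dual_median":
        assert isinstance(scores, pd.DataFrame) and scores.shape[1] == 2
        med = scores.median(axis=0, skipna=True)
        both = (scores.iloc[:, 0] > med.iloc[0]) & (scores.iloc[:, 1] > med.iloc[1])
        hi, lo = params["label_both_high"], params["label_else"]
        total = scores.sum(axis=1)
        return [
            _call(s, None if scores.loc[s].isna().any()
                  else (hi if both[s] else lo), sig, total[s])
            for s in scores.index
        ]

    assert isinstance(scores, pd.Series)
    labels = params["labels"]
    defined = scores.dropna()
    if mode == "fixed":
        cutoffs = params["cutoffs"]
        def assign(v):
            if len(cutoffs) == 1:
                return labels[1] if v > cutoffs[0] else labels[0]
            if v < cutoffs[0]:
                return labels[0]
            if v > cutoffs[1]:
                return labels[2]
            return labels[1]
    elif mode in ("cohort_median", "tertile", "percentile"):
        if defined.nunique() < 2:
            logger.warning("%s: fewer than 2 distinct scores, all NA",
                           sig.name)
            return [_call(s, None, sig) for s in scores.index]
        if mode == "cohort_median":
            med = defined.median()
            def assign(v):
                return labels[1] if v > med else labels[0]
        elif mode == "tertile":
            q1, q2 = defined.quantile([1 / 3, 2 / 3])
            def assign(v):
                if v <= q1:
                    return labels[0]
                if v <= q2:
                    return labels[1]
                return labels[2]
        else:
            hi = np.percentile(defined, params.get("hi", 80))
            lo = np.percentile(defined, params.get("lo", 20))
            def assign(v):
                if v > hi:
                    return labels[-1]
                if v < lo:
                    return labels[0]
                return labels[1] if len(labels) == 3 else labels[0]
    else:
        raise ValueError(f"unknown cutoff mode {mode!r}")
    return [
        _call(s, assign(scores[s]) if s in defined.index else None,
              sig, scores[s])
        for s in scores.index
    ]


def classify_by_tally(matrix: ExpressionMatrix,
                      sig: Signature) -> list[SubtypeCall]:
    """Count, per sample, the signature genes at risk-associated levels.

    A gene scores positive when the sample lies strictly beyond that gene's
    cohort reference level in the risk direction: above the per-gene median
    (or the high percentile) for up_is_risk genes, below the median (or the
    low percentile) for down_is_risk genes. With ``label_by_count`` the tally
    itself is the label (Yuen3's 0..3); otherwise reaching ``threshold``
    assigns the risk label. Constant genes never score positive.
    """
    p = sig.rule.params
    genes = _covered(matrix, sig.gene_symbols, sig.name)
    dir_of = {g.symbol: g.direction for g in sig.genes}
    vals = matrix.values.loc[genes]
    tally = pd.Series(0, index=vals.columns)
    for g in genes:
        row = vals.loc[g]
        if row.nunique(dropna=True) <= 1:
            logger.warning("%s: constant gene %s never scores positive",
                           sig.name, g)
            continue
        direction = dir_of[g]
        if p["reference"] == "median":
            hi_ref = lo_ref = row.median(skipna=True)
        else:
            hi_ref = np.nanpercentile(row, p["hi"])
            lo_ref = np.nanpercentile(row, p["lo"])
        if direction == "down_is_risk":
            tally += (row < lo_ref).astype(int)
        else:
            tally += (row > hi_ref).astype(int)
    if p.get("label_by_count"):
        label_of = dict(zip(range(len(sig.rule.params["labels"])),
                            sig.rule.params["labels"]))
        return [_call(s, label_of[int(tally[s])], sig, float(tally[s]))
                for s in vals.columns]
    thr = p["threshold"]
    hi_label, lo_label = p["label_if_tally_ge"], p["label_else"]
    return [_call(s, hi_label if tally[s] >= thr else lo_label, sig,
                  float(tally[s]))
            for s in vals.columns]


def classify_by_group_means(matrix: ExpressionMatrix,
                            sig: Signature) -> list[SubtypeCall]:
    """Per sample, compare the mean expression of two gene partitions.

    mean(G1) < mean(G2) yields the G1-low label (BRAF-mutant-like in the
    published rule); ties and the reverse yield the other label. A partition
    with no covered genes makes the sample NA.
    """
    p = sig.rule.params
    g1 = [g for g in p["g1"] if g in matrix.values.index]
    g2 = [g for g in p["g2"] if g in matrix.values.index]
    if not g1 or not g2:
        logger.warning("%s: a partition has no covered genes, all calls NA",
                       sig.name)
        return [_call(s, None, sig) for s in matrix.values.columns]
    m1 = matrix.values.loc[g1].mean(axis=0)
    m2 = matrix.values.loc[g2].mean(axis=0)
    diff = m1 - m2
    return [
        _call(s, None if pd.isna(diff[s]) else
              (p["label_g1_less"] if m1[s] < m2[s] else p["label_otherwise"]),
              sig, diff[s])
        for s in matrix.values.columns
    ]


# ---------------------------------------------------------------------------
# dispatcher


def apply_rule_classifier(matrix: ExpressionMatrix,
                          sig: Signature) -> list[SubtypeCall]:
    """Run any formula-specified signature on a matrix.

    Routes on the rule kind; ``trained_model`` signatures need a fitted
    engine and are handled by the trainable-engine module instead.
    """
    kind = sig.rule.kind
    work = matrix
    dct = sig.rule.params.get("delta_ct")
    if dct is not None:
        work = delta_ct_transform(matrix, sig.housekeeping,
                                  dct.get("constant", -15.0),
                                  dct.get("mean_mode", "arithmetic"))
    if kind == "linear_cutoff":
        return classify_by_cutoff(score_linear(work, sig), sig.rule, sig)
    if kind == "signature_mean_split":
        return classify_by_cutoff(score_signature_mean(work, sig),
                                  sig.rule, sig)
    if kind == "product_ratio":
        return classify_by_cutoff(score_product_ratio(work, sig),
                                  sig.rule, sig)
    if kind == "tally":
        return classify_by_tally(work, sig)
    if kind == "group_mean_compare":
        return classify_by_group_means(work, sig)
    if kind == "dual_median":
        p = sig.rule.params
        frames = {}
        for key in ("model_a", "model_b"):
            wmap = p[key]
            genes = [g for g in wmap if g in work.values.index]
            if not genes:
                raise KeyError(f"{sig.name}: sub-model {key} has no genes")
            w = pd.Series({g: wmap[g] for g in genes})
            frames[key] = work.values.loc[genes].mul(w, axis=0).sum(axis=0)
        scores = pd.DataFrame(frames)
        return classify_by_cutoff(scores, sig.rule, sig)
    raise ValueError(
        f"{sig.name}: rule kind {kind!r} is not a formula rule "
        f"(trained models are executed by the engine module)")
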
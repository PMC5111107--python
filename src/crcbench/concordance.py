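"""Agreement between classifier outputs and between signature gene lists.

Classifier agreement is Cramer's V on the contingency table of paired calls
(uncorrected chi-square), with samples left unclassified by either side
excluded pairwise. Gene-list relatedness is a row-normalized overlap
percentage matrix, and individual genes are ranked by a score rewarding
membership in many, small signatures.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .signatures import Signature

logger = logging.getLogger(__name__)


def cramers_v(labels_a, labels_b) -> float:
    """Cramer's V between two categorical labelings.

    ``V = sqrt(chi2 / (n * (min(r, c) - 1)))`` from the r x c contingency
    table, chi-square without continuity correction. Pairs where either
    label is missing are dropped; if either vector is single-level after
    that, the statistic is undefined and NaN is returned with a warning.
    """
    a = pd.Series(list(labels_a), dtype=object)
    b = pd.Series(list(labels_b), dtype=object)
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    keep = a.notna() & b.notna()
    a, b = a[keep], b[keep]
    if a.nunique() < 2 or b.nunique() < 2:
        warnings.warn("Cramer's V undefined: a labeling has < 2 levels "
                      "after NA removal", stacklevel=2)
        return float("nan")
    table = pd.crosstab(a, b)
    chi2 = chi2_contingency(table.to_numpy(), correction=False)[0]
    n = int(table.to_numpy().sum())
    k = min(table.shape) - 1
    return float(np.sqrt(chi2 / (n * k)))


def prognosis_label_concordance(
    calls_a: pd.Series,
    calls_b: pd.Series,
    label_a: str,
    label_b: str,
) -> float:
    """Agreement in flagging samples with one named label per classifier.

    The two call vectors are reduced to indicators (sample carries the named
    label or not) over the samples classified by both, then compared with
    Cramer's V. A negative association (observed co-occurrence below the
    independence expectation) is clamped to 0; a label missing from a call
    set, or a degenerate single-level indicator, yields NaN.
    """
    shared = calls_a.dropna().index.intersection(calls_b.dropna().index)
    a = calls_a[shared]
    b = calls_b[shared]
    if label_a not in set(a) or label_b not in set(b):
        return float("nan")
    ind_a = (a == label_a)
    ind_b = (b == label_b)
    v = cramers_v(ind_a, ind_b)
    if np.isnan(v):
        return v
    n = len(shared)
    observed = float((ind_a & ind_b).sum())
    expected = ind_a.sum() * ind_b.sum() / n
    return 0.0 if observed < expected else v


def concordance_matrix(calls_by_classifier: dict[str, pd.Series]
                       ) -> pd.DataFrame:
    """Symmetric Cramer's V matrix over all classifier pairs."""
    names = list(calls_by_classifier)
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for name in names:
        calls = calls_by_classifier[name].dropna()
        out.loc[name, name] = 1.0 if calls.nunique() >= 2 else np.nan
    for a, b in itertools.combinations(names, 2):
        ca, cb = calls_by_classifier[a], calls_by_classifier[b]
        shared = ca.dropna().index.intersection(cb.dropna().index)
        v = cramers_v(ca[shared], cb[shared]) if len(shared) else np.nan
        out.loc[a, b] = out.loc[b, a] = v
    return out


def signature_overlap_matrix(signatures: list[Signature]) -> pd.DataFrame:
    """Row-normalized gene-overlap percentages.

    entry(i, j) = 100 * |genes_i intersect genes_j| / |genes_i|; asymmetric
    (a small signature fully inside a large one reads 100 one way and the
    size ratio the other), diagonal 100.
    """
    if len(signatures) < 2:
        raise ValueError("need >= 2 signatures")
    names = [s.name for s in signatures]
    sets = {s.name: set(s.gene_symbols) for s in signatures}
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i in names:
        for j in names:
            out.loc[i, j] = 100.0 * len(sets[i] & sets[j]) / len(sets[i])
    return out


@dataclass(frozen=True)
class GeneScore:
    gene: str
    n_classifiers: int
    score: float


def gene_score_ranking(signatures: list[Signature]) -> pd.DataFrame:
    """Rank genes by cross-classifier centrality.

    A gene's proportion in a signature is 1/|signature|; its score is
    ``[number of signatures containing it] * [sum of its proportions]``.
    Returned descending by score, ties broken alphabetically.
    """
    if not signatures:
        raise ValueError("need >= 1 signature")
    rows: dict[str, dict] = {}
    for sig in signatures:
        size = len(set(sig.gene_symbols))
        for g in set(sig.gene_symbols):
            r = rows.setdefault(g, {"gene": g, "n_classifiers": 0,
                                    "proportion_sum": 0.0})
            r["n_classifiers"] += 1
            r["proportion_sum"] += 1.0 / size
    df = pd.DataFrame(rows.values())
    df["score"] = df["n_classifiers"] * df["proportion_sum"]
    df = df.sort_values(["score", "gene"],
                        ascending=[False, True]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df[["rank", "gene", "n_classifiers", "score"]]
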
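"""Synthetic cohorts with planted subtypes, signature effects, and survival.

The generator emulates the statistical structure of a pooled, normalized
microarray cohort: log2 expression as Gaussian background (mean 7, SD 1 —
typical of MAS5/RMA-normalized chips), subtype-specific mean shifts on
signature genes, exponential relapse times with multiplicative per-subtype
hazards (exactly proportional hazards, so Cox recovery is a clean oracle),
and independent uniform censoring calibrated to a requested rate. All
generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .expression import ExpressionMatrix
from .signatures import Signature

BACKGROUND_MEAN = 7.0


@dataclass
class SyntheticTruth:
    subtype: pd.Series                      # per-sample planted subtype
    hazard_map: dict[str, float]            # per-subtype hazard multiplier
    effect_size: float                      # log2 shift on planted genes
    noise_sd: float
    censor_rate: float
    seed: int
    planted_genes: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.subtype.index,
                           "subtype": self.subtype.values})
        df["hazard"] = df["subtype"].map(self.hazard_map)
        return df


def _censor_horizon(rates: np.ndarray, props: np.ndarray,
                    censor_rate: float) -> float:
    """Horizon H with marginal P(U(0,H) < Exp(rate)) = censor_rate.

    For exponential T with rate r, P(C < T) with C ~ U(0, H) is
    (1 - exp(-r H)) / (r H); averaged over the subtype mixture and solved
    for H by bisection.
    """
    def frac(H):
        return float(np.sum(props * (1 - np.exp(-rates * H)) / (rates * H)))
    # frac is decreasing in H from 1 (H -> 0) toward 0
    lo, hi = 1e-9, 1.0
    while frac(hi) > censor_rate:
        hi *= 2
        if hi > 1e12:
            raise ValueError("cannot reach requested censoring rate")
    return brentq(lambda H: frac(H) - censor_rate, lo, hi)


def simulate_cohort(
    n: int,
    genes: int,
    subtype_props: Mapping[str, float],
    signatures_to_plant: Sequence[Signature] = (),
    effect_size: float = 2.0,
    hazard_map: Mapping[str, float] | None = None,
    baseline_rate: float = 0.02,
    censor_rate: float = 0.2,
    seed: int = 0,
    noise_sd: float = 1.0,
    heavy_tails: bool = False,
    round_months: bool = False,
    dataset: str = "synthetic",
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate an expression matrix, clinical table, and planted truth.

    Samples are assigned subtypes by multinomial draw on ``subtype_props``
    (which must sum to 1). Signature genes are shifted by +-``effect_size``
    in the samples of risk subtypes (those with the largest hazard
    multiplier; everything when no hazard map is given): up_is_risk genes
    up, down_is_risk genes down. Relapse times are exponential with rate
    ``baseline_rate * hazard_map[subtype]`` (per month); censoring is
    independent uniform on [0, horizon] with the horizon solved to hit
    ``censor_rate`` marginally.
    """
    props = dict(subtype_props)
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"subtype proportions sum to {total}, not 1")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    rng = np.random.default_rng(seed)
    subtype_names = list(props)
    hazard_map = dict(hazard_map) if hazard_map else {s: 1.0
                                                      for s in subtype_names}
    sample_ids = [f"S{i:04d}" for i in range(n)]
    subtype = pd.Series(
        rng.choice(subtype_names, size=n, p=[props[s] for s in subtype_names]),
        index=sample_ids)

    sig_genes: list[str] = []
    for sig in signatures_to_plant:
        sig_genes.extend(g for g in sig.gene_symbols if g not in sig_genes)
        sig_genes.extend(g for g in sig.housekeeping if g not in sig_genes)
    n_background = max(genes - len(sig_genes), 0)
    gene_ids = sig_genes + [f"G{i:05d}" for i in range(n_background)]

    if heavy_tails:
        noise = rng.standard_t(df=5, size=(len(gene_ids), n)) * noise_sd
    else:
        noise = rng.normal(0.0, noise_sd, size=(len(gene_ids), n))
    values = pd.DataFrame(BACKGROUND_MEAN + noise, index=gene_ids,
                          columns=sample_ids)
    matrix = ExpressionMatrix(values,
                              pd.Series(dataset, index=sample_ids),
                              pd.Series("synthetic", index=sample_ids))

    max_hazard = max(hazard_map.values())
    risk_subtypes = [s for s, h in hazard_map.items() if h == max_hazard] \
        if max_hazard > min(hazard_map.values()) else subtype_names
    risk_samples = list(subtype.index[subtype.isin(risk_subtypes)])
    planted: dict[str, list[str]] = {}
    for sig in signatures_to_plant:
        matrix = plant_signature(matrix, sig, risk_samples, effect_size)
        planted[sig.name] = list(sig.gene_symbols)

    rates = np.array([baseline_rate * hazard_map[s] for s in subtype])
    event_times = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        horizon = _censor_horizon(
            np.array([baseline_rate * hazard_map[s] for s in subtype_names]),
            np.array([props[s] for s in subtype_names]), censor_rate)
        censor_times = rng.uniform(0.0, horizon, size=n)
        observed = np.minimum(event_times, censor_times)
        events = (event_times <= censor_times).astype(int)
    else:
        observed = event_times
        events = np.ones(n, dtype=int)
    if round_months:
        observed = np.maximum(np.round(observed), 1.0)

    stages = rng.choice(["I", "II", "III", "IV"], size=n,
                        p=[0.12, 0.38, 0.36, 0.14])
    clinical = pd.DataFrame({
        "rfs_time": observed,
        "rfs_event": events,
        "stage": stages,
        "msi": rng.choice(["MSI", "MSS"], size=n, p=[0.15, 0.85]),
        "gender": rng.choice(["male", "female"], size=n, p=[0.574, 0.426]),
        "age": np.clip(rng.normal(69, 10, size=n), 30, 95).round(1),
    }, index=pd.Index(sample_ids, name="sample_id"))

    truth = SyntheticTruth(subtype, hazard_map, effect_size, noise_sd,
                           censor_rate, seed, planted)
    return matrix, clinical, truth


def plant_signature(
    matrix: ExpressionMatrix,
    sig: Signature,
    target_samples: Sequence[str],
    effect_size: float,
) -> ExpressionMatrix:
    """Shift signature genes in the target samples only.

    up_is_risk genes move +effect_size, down_is_risk genes -effect_size;
    unsigned genes move up. Untouched columns are bit-identical to the
    input. An empty target set is a warned no-op.
    """
    import logging

    if not list(target_samples):
        logging.getLogger(__name__).warning(
            "plant_signature(%s): empty target set, no-op", sig.name)
        return matrix
    missing = [g for g in sig.gene_symbols if g not in matrix.values.index]
    if missing:
        raise KeyError(f"{sig.name}: gene(s) not in matrix: {missing}")
    values = matrix.values.copy()
    cols = [s for s in target_samples if s in values.columns]
    for g in sig.genes:
        shift = -effect_size if g.direction == "down_is_risk" else effect_size
        values.loc[g.symbol, cols] += shift
    return ExpressionMatrix(values, matrix.dataset_of_origin, matrix.platform,
                            matrix.log2_scale)


def simulate_cellline_replicates(
    n_lines: int,
    replicates_per_line: int,
    agreement: float,
    seed: int = 0,
    labels: Sequence[str] = ("A", "B", "C"),
    classifier: str = "sim",
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-array call fixtures for the replicate-consensus rule.

    Each line gets a planted label; every replicate reproduces it with
    probability ``agreement`` and otherwise draws uniformly from the other
    labels. Returns (long calls table, planted labels per line).
    """
    if not 0.0 <= agreement <= 1.0:
        raise ValueError("agreement must be in [0, 1]")
    if replicates_per_line < 1:
        raise ValueError("need >= 1 replicate per line")
    rng = np.random.default_rng(seed)
    labels = list(labels)
    rows = []
    planted = {}
    for i in range(n_lines):
        line = f"CL{i:04d}"
        true = labels[rng.integers(len(labels))]
        planted[line] = true
        others = [l for l in labels if l != true]
        for r in range(replicates_per_line):
            if rng.random() < agreement or not others:
                lab = true
            else:
                lab = others[rng.integers(len(others))]
            rows.append({"cell_line": line, "array_id": f"{line}_r{r}",
                         "classifier": classifier, "label": lab})
    return pd.DataFrame(rows), pd.Series(planted)
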
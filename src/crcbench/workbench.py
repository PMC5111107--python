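"""End-to-end benchmark orchestration.

``run_benchmark`` executes the full pipeline — pool matrices, classify with
every evaluable signature, concordance, gene scores, best-vs-worst survival,
univariate gene screen, optional cell-line assignment — and writes one TSV
per report into the output directory, stamped with a config hash and seed.
The bundle is a pure function of (inputs, config, seed): any stage failure
aborts with the stage named and partial outputs removed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import concordance as conc
from . import survival as surv
from .celllines import annotate_mutations, assign_panels, panels_to_frame, \
    subtype_prevalence_vs_models
from .engines import predict, train_shrunken_centroid
from .expression import ExpressionMatrix, load_clinical, load_matrix, \
    merge_and_dedup
from .rules import apply_rule_classifier, calls_to_frame, calls_to_series
from .signatures import Signature, load_signature_config, builtin_signatures, \
    validate_signature

logger = logging.getLogger(__name__)


class BenchmarkError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class BenchmarkConfig:
    matrix_paths: list[str]
    clinical_path: str
    output_dir: str
    signature_config: str | None = None
    include_builtin_signatures: bool = True
    stage_filter: tuple[str, ...] | None = ("II", "III")
    apply_training_exclusion: bool = True
    training_exclusion_exceptions: tuple[str, ...] = ("CMS",)
    training_labels_path: str | None = None   # sample_id<TAB>label for
    shrinkage: float = 1.0                    # trained_model signatures
    coverage_floor: float = 0.8
    duplicate_threshold: float = 0.99
    cellline_calls_path: str | None = None    # long per-array call table
    mutation_table_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage_filter is not None:
            bad = set(self.stage_filter) - {"I", "II", "III", "IV"}
            if bad:
                raise ValueError(f"invalid stage filter values {sorted(bad)}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "stage_filter" in doc and doc["stage_filter"] is not None:
            doc["stage_filter"] = tuple(doc["stage_filter"])
        if "training_exclusion_exceptions" in doc:
            doc["training_exclusion_exceptions"] = tuple(
                doc["training_exclusion_exceptions"])
        return cls(**doc)


def classify_all(
    matrix: ExpressionMatrix,
    signatures: list[Signature],
    coverage_floor: float = 0.8,
    training_labels: pd.Series | None = None,
    shrinkage: float = 1.0,
) -> dict[str, pd.Series]:
    """Run every evaluable signature on the matrix; label series per name.

    Formula rules run directly. ``trained_model`` signatures are trained as
    nearest shrunken centroid models on the supplied training labels (on
    the signature's genes) and skipped with a log line when no labels are
    available.
    """
    out: dict[str, pd.Series] = {}
    for sig in signatures:
        report = validate_signature(sig, matrix, coverage_floor)
        if not report.evaluable:
            logger.warning("%s: coverage %.3f below floor, not evaluable",
                           sig.name, report.coverage)
            continue
        if sig.rule.kind == "trained_model":
            if training_labels is None:
                logger.warning("%s: trained-model rule without training "
                               "labels, skipped", sig.name)
                continue
            genes = [g for g in sig.gene_symbols if g in matrix.values.index]
            sub = ExpressionMatrix(matrix.values.loc[genes],
                                   matrix.dataset_of_origin, matrix.platform)
            model = train_shrunken_centroid(
                sub, training_labels, shrinkage=shrinkage, name=sig.name,
                confidence_floor=sig.rule.params.get("confidence_floor", 0.0))
            calls = predict(model, sub)
        else:
            calls = apply_rule_classifier(matrix, sig)
        out[sig.name] = calls_to_series(calls)
    return out


def per_label_concordance_table(
    calls: dict[str, pd.Series],
    signatures: dict[str, Signature],
) -> pd.DataFrame:
    """Good/bad-prognosis concordance for every classifier pair."""
    rows = []
    names = [n for n in calls if n in signatures]
    for prognosis in ("bad", "good"):
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                for la in signatures[a].labels_with_prognosis(prognosis):
                    for lb in signatures[b].labels_with_prognosis(prognosis):
                        v = conc.prognosis_label_concordance(
                            calls[a], calls[b], la, lb)
                        rows.append({"prognosis": prognosis,
                                     "classifier_a": a, "label_a": la,
                                     "classifier_b": b, "label_b": lb,
                                     "concordance": v})
    return pd.DataFrame(rows)


def forest_table(
    calls: dict[str, pd.Series],
    signatures: dict[str, Signature],
    clinical: pd.DataFrame,
    stage_filter=None,
    dataset_of_origin: pd.Series | None = None,
    apply_training_exclusion: bool = True,
    exclusion_exceptions: tuple[str, ...] = ("CMS",),
) -> pd.DataFrame:
    """Best-vs-worst hazard ratio per classifier (forest-plot table)."""
    rows = []
    for name, series in calls.items():
        sig = signatures.get(name)
        exclude = None
        if (apply_training_exclusion and sig is not None
                and name not in exclusion_exceptions):
            exclude = sig.training_set_ids or None
        try:
            res = surv.extreme_cohort_hr(
                series, clinical, stage_filter=stage_filter,
                exclude_datasets=exclude,
                dataset_of_origin=dataset_of_origin, comparison=name)
            ngroups = list(res.n_group.items())
            rows.append({"classifier": name, "comparison": res.comparison,
                         "hazard_ratio": res.hazard_ratio,
                         "ci_low": res.ci_low, "ci_high": res.ci_high,
                         "p_value": res.p_value,
                         "n_best": ngroups[0][1], "n_worst": ngroups[1][1],
                         "status": "ok"})
        except Exception as exc:
            logger.warning("forest: %s failed: %s", name, exc)
            rows.append({"classifier": name, "comparison": "",
                         "hazard_ratio": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p_value": np.nan,
                         "n_best": 0, "n_worst": 0,
                         "status": f"failed: {exc}"})
    return pd.DataFrame(rows)


def univariate_summary_table(
    matrix: ExpressionMatrix,
    clinical: pd.DataFrame,
    signatures: dict[str, Signature],
) -> pd.DataFrame:
    """Per-signature proportion of individually prognostic member genes."""
    rows = []
    for name, sig in signatures.items():
        table, props = surv.univariate_gene_screen(matrix, clinical,
                                                   sig.gene_symbols)
        rows.append({"classifier": name,
                     "n_genes": len(sig.genes),
                     "n_screened": int(table["p_value"].notna().sum()),
                     "prop_p_lt_05": props["prop_p_lt_05"],
                     "prop_p_lt_01": props["prop_p_lt_01"]})
    return pd.DataFrame(rows)


def run_benchmark(config: BenchmarkConfig) -> dict[str, Path]:
    """Execute the full benchmark; returns the emitted artifact paths."""
    out_dir = Path(config.output_dir)
    tmp_dir = Path(tempfile.mkdtemp(prefix="crcbench_",
                                    dir=out_dir.parent
                                    if out_dir.parent.exists() else None))
    artifacts: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame, index=False) -> None:
        path = tmp_dir / name
        df.to_csv(path, sep="\t", index=index, na_rep="NA")
        artifacts[name] = out_dir / name

    stage = "load"
    try:
        matrices = [load_matrix(p) for p in config.matrix_paths]
        matrix, dup_report = merge_and_dedup(matrices,
                                             config.duplicate_threshold)
        clinical = load_clinical(config.clinical_path)

        stage = "signatures"
        if config.signature_config:
            sigs = load_signature_config(
                config.signature_config,
                include_builtins=config.include_builtin_signatures)
        elif config.include_builtin_signatures:
            sigs = list(builtin_signatures().values())
        else:
            raise ValueError("no signatures configured")
        sig_by_name = {s.name: s for s in sigs}

        stage = "classify"
        training_labels = None
        if config.training_labels_path:
            training_labels = pd.read_csv(
                config.training_labels_path, sep="\t", index_col=0,
                dtype=str).iloc[:, 0]
        calls = classify_all(matrix, sigs, config.coverage_floor,
                             training_labels, config.shrinkage)
        if not calls:
            raise ValueError("no signature was evaluable on this matrix")
        all_calls = pd.concat(
            [pd.DataFrame({"sample_id": s.index, "classifier": name,
                           "label": s.values})
             for name, s in calls.items()], ignore_index=True)
        emit("calls.tsv", all_calls)
        emit("duplicates.tsv", dup_report.removed)

        stage = "concordance"
        if len(calls) >= 2:
            emit("cramers_v.tsv", conc.concordance_matrix(calls), index=True)
            emit("per_label_concordance.tsv",
                 per_label_concordance_table(calls, sig_by_name))
            emit("overlap.tsv", conc.signature_overlap_matrix(sigs),
                 index=True)
        emit("gene_scores.tsv", conc.gene_score_ranking(sigs))

        stage = "survival"
        emit("forest.tsv", forest_table(
            calls, sig_by_name, clinical,
            stage_filter=config.stage_filter,
            dataset_of_origin=matrix.dataset_of_origin,
            apply_training_exclusion=config.apply_training_exclusion,
            exclusion_exceptions=config.training_exclusion_exceptions))

        stage = "gene_screen"
        evaluable = {n: sig_by_name[n] for n in calls if n in sig_by_name}
        emit("univariate_summary.tsv",
             univariate_summary_table(matrix, clinical, evaluable))

        stage = "celllines"
        if config.cellline_calls_path:
            per_array = pd.read_csv(config.cellline_calls_path, sep="\t",
                                    dtype=str)
            panels = assign_panels(per_array)
            if config.mutation_table_path:
                panels = annotate_mutations(panels,
                                            config.mutation_table_path)
            emit("celllines.tsv", panels_to_frame(panels))
            prev = [subtype_prevalence_vs_models(calls[c], panels, c)
                    for c in per_array["classifier"].unique() if c in calls]
            if prev:
                emit("prevalence_vs_models.tsv",
                     pd.concat(prev, ignore_index=True))

        stage = "finalize"
        info = {"config_hash": config.config_hash(), "seed": config.seed,
                "n_samples": matrix.shape[1], "n_genes": matrix.shape[0],
                "n_duplicates_removed": len(dup_report.removed),
                "classifiers": sorted(calls)}
        (tmp_dir / "run_info.json").write_text(json.dumps(info, indent=1))
        artifacts["run_info.json"] = out_dir / "run_info.json"

        out_dir.mkdir(parents=True, exist_ok=True)
        for name in artifacts:
            shutil.move(str(tmp_dir / name), str(out_dir / name))
    except Exception as exc:
        shutil.rmtree(tmp_dir, ignore_errors=True)
        if isinstance(exc, BenchmarkError):
            raise
        raise BenchmarkError(stage, exc) from exc
    shutil.rmtree(tmp_dir, ignore_errors=True)
    return artifacts
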
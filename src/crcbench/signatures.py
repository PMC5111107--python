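"""Declarative classifier definitions: gene lists, per-gene parameters, rules.

A :class:`Signature` fully determines a classifier's sample-level output:
its genes (with direction and optional weight), a :class:`RuleSpec` naming
the scoring/cutoff recipe, and the output labels with their prognosis
annotation. Gene lists published only in supplementary material are
config-supplied; classifiers whose constants appear verbatim in the primary
literature (CCHS, Yuen3, Oncodefender, ColoGuidePro) ship as built-ins, and
the remaining rule skeletons (ODXcolon, V7RHS, ColoGuideEx, ...) ship as
defaults a config can extend with its gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

DIRECTIONS = ("up_is_risk", "down_is_risk", "unsigned")
PROGNOSES = ("good", "bad", "intermediate", "unannotated")
RULE_KINDS = (
    "linear_cutoff",
    "product_ratio",
    "tally",
    "signature_mean_split",
    "group_mean_compare",
    "dual_median",
    "trained_model",
)
#: rule kinds whose score is an explicit weighted combination
WEIGHTED_KINDS = ("linear_cutoff", "dual_median")


class SignatureValidationError(ValueError):
    """Raised when a signature or rule definition is internally inconsistent."""


@dataclass(frozen=True)
class SignatureGene:
    symbol: str
    direction: str = "unsigned"
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise SignatureValidationError(
                f"{self.symbol}: unknown direction {self.direction!r}")


@dataclass
class RuleSpec:
    """Classification rule: a kind plus the parameters that kind requires.

    Supported kinds and their key parameters:

    - ``linear_cutoff``: ``intercept``, ``cutoff_mode`` in {fixed,
      cohort_median, tertile}; fixed mode needs ``cutoffs`` (1 or 2 values);
      optional ``delta_ct`` {constant, mean_mode} pre-transform.
    - ``product_ratio``: ``terms`` (list of {sign, numerator, denominator}
      taken as |prod(num)/prod(den)| each), ``cutoff_mode``.
    - ``tally``: ``reference`` in {median, percentile} (percentile needs
      ``hi``/``lo`` in (0,100)); either ``threshold`` (risk label when the
      tally reaches it) or ``label_by_count`` (Yuen3-style 0..n labels).
    - ``signature_mean_split``: unweighted signature-mean score split by
      ``cutoff_mode`` in {cohort_median, tertile, percentile}.
    - ``group_mean_compare``: gene partitions ``g1``/``g2``; label
      ``label_g1_less`` when mean(G1) < mean(G2), else ``label_otherwise``.
    - ``dual_median``: two weighted sub-scores (``model_a``/``model_b`` gene
      weight maps); ``label_both_high`` only when both exceed their own
      cohort medians.
    - ``trained_model``: ``engine`` plus engine parameters; executed by the
      trainable-engine module, optionally with a ``confidence_floor``.
    """

    kind: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise SignatureValidationError(f"unknown rule kind {self.kind!r}")
        p = self.params
        if self.kind == "linear_cutoff":
            mode = p.setdefault("cutoff_mode", "fixed")
            p.setdefault("intercept", 0.0)
            if mode == "fixed":
                cutoffs = p.get("cutoffs")
                if not cutoffs or len(cutoffs) not in (1, 2):
                    raise SignatureValidationError(
                        "linear_cutoff fixed mode needs 1 or 2 cutoffs")
                if sorted(cutoffs) != list(cutoffs):
                    raise SignatureValidationError("cutoffs must be ascending")
        elif self.kind == "product_ratio":
            if not p.get("terms"):
                raise SignatureValidationError("product_ratio needs terms")
            p.setdefault("cutoff_mode", "cohort_median")
        elif self.kind == "tally":
            ref = p.setdefault("reference", "median")
            if ref == "percentile":
                hi, lo = p.get("hi"), p.get("lo")
                if hi is None or lo is None or not (0 < lo < 100) \
                        or not (0 < hi < 100):
                    raise SignatureValidationError(
                        "percentile reference needs hi/lo in (0, 100)")
            elif ref != "median":
                raise SignatureValidationError(f"unknown reference {ref!r}")
            if not p.get("label_by_count") and "threshold" not in p:
                raise SignatureValidationError(
                    "tally rule needs a threshold or label_by_count")
        elif self.kind == "signature_mean_split":
            p.setdefault("cutoff_mode", "cohort_median")
        elif self.kind == "group_mean_compare":
            if not p.get("g1") or not p.get("g2"):
                raise SignatureValidationError(
                    "group_mean_compare needs non-empty g1 and g2")
        elif self.kind == "dual_median":
            if not p.get("model_a") or not p.get("model_b"):
                raise SignatureValidationError(
                    "dual_median needs model_a and model_b weight maps")
        elif self.kind == "trained_model":
            if "engine" not in p:
                raise SignatureValidationError("trained_model needs an engine")
            floor = p.setdefault("confidence_floor", 0.0)
            if not 0.0 <= floor <= 1.0:
                raise SignatureValidationError(
                    "confidence_floor must be in [0, 1]")

    def referenced_labels(self) -> list[str]:
        p = self.params
        out: list[str] = []
        for key in ("labels", "label_if_tally_ge", "label_else",
                    "label_g1_less", "label_otherwise", "label_both_high"):
            v = p.get(key)
            if isinstance(v, str):
                out.append(v)
            elif isinstance(v, (list, tuple)):
                out.extend(v)
        return out


@dataclass
class Signature:
    name: str
    genes: list[SignatureGene]
    rule: RuleSpec
    labels: list[tuple[str, str]]  # (label, prognosis)
    housekeeping: list[str] = field(default_factory=list)
    training_set_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise SignatureValidationError(f"{self.name}: empty gene list")
        label_names = [l for l, _ in self.labels]
        if len(set(label_names)) != len(label_names):
            raise SignatureValidationError(f"{self.name}: duplicate labels")
        for _, prog in self.labels:
            if prog not in PROGNOSES:
                raise SignatureValidationError(
                    f"{self.name}: unknown prognosis {prog!r}")
        for ref in self.rule.referenced_labels():
            if ref not in label_names:
                raise SignatureValidationError(
                    f"{self.name}: rule references unknown label {ref!r}")
        needs_weights = self.rule.kind in WEIGHTED_KINDS
        if self.rule.kind == "linear_cutoff":
            missing = [g.symbol for g in self.genes if g.weight is None]
            if missing:
                raise SignatureValidationError(
                    f"{self.name}: linear rule needs weights for {missing}")
        elif not needs_weights:
            weighted = [g.symbol for g in self.genes if g.weight is not None]
            if weighted:
                raise SignatureValidationError(
                    f"{self.name}: rule kind {self.rule.kind!r} takes no "
                    f"gene weights (found on {weighted})")
        if self.rule.kind == "tally":
            thr = self.rule.params.get("threshold")
            if thr is not None and thr > len(self.genes):
                raise SignatureValidationError(
                    f"{self.name}: tally threshold {thr} exceeds gene count "
                    f"{len(self.genes)}")

    @property
    def gene_symbols(self) -> list[str]:
        return [g.symbol for g in self.genes]

    @property
    def label_names(self) -> list[str]:
        return [l for l, _ in self.labels]

    def prognosis_of(self, label: str) -> str:
        for l, p in self.labels:
            if l == label:
                return p
        return "unannotated"

    def labels_with_prognosis(self, prognosis: str) -> list[str]:
        return [l for l, p in self.labels if p == prognosis]


@dataclass
class CoverageReport:
    signature: str
    coverage: float
    missing_genes: list[str]
    evaluable: bool


def validate_signature(
    sig: Signature,
    matrix,
    coverage_floor: float = 0.8,
) -> CoverageReport:
    """Report the fraction of signature genes measured in a matrix.

    A signature is evaluable when coverage reaches the floor (default 0.8);
    classification then proceeds on the shared-gene subset, mirroring the
    graceful degradation used for reduced-probe platforms.
    """
    present = set(matrix.values.index)
    missing = [g for g in sig.gene_symbols if g not in present]
    coverage = 1.0 - len(missing) / len(sig.genes)
    return CoverageReport(sig.name, coverage, missing,
                          coverage >= coverage_floor)


# ---------------------------------------------------------------------------
# built-ins


def _sig(name, genes, rule, labels, housekeeping=(), training=()):
    return Signature(
        name=name,
        genes=[SignatureGene(*g) if isinstance(g, tuple) else SignatureGene(g)
               for g in genes],
        rule=rule,
        labels=list(labels),
        housekeeping=list(housekeeping),
        training_set_ids=list(training),
    )


def builtin_signatures() -> dict[str, Signature]:
    """Classifiers whose constants are published in full in the literature.

    - CCHS: five-term hypoxia score with intercept 1.301, risk cutoff 4.526.
    - Yuen3: per-gene median tally over TAZ/AXL/CTGF, labels 0..3.
    - Oncodefender: |BMI1*VEGFA/H3F3B| - |ETV6*H3F3B/RPS10| on
      housekeeping-adjusted values, median risk split.
    - ColoGuidePro: 7-gene per-gene tally, poor prognosis at >= 3 risk genes.
    """
    sigs = {}
    sigs["CCHS"] = _sig(
        "CCHS",
        [("BCCIP", "up_is_risk", 0.543), ("BNIP3L", "down_is_risk", -0.416),
         ("GADD45B", "up_is_risk", 0.596), ("INSIG2", "up_is_risk", 0.538),
         ("TP53", "down_is_risk", -0.177)],
        RuleSpec("linear_cutoff", {
            "intercept": 1.301, "cutoff_mode": "fixed", "cutoffs": [4.526],
            "labels": ["low", "high"]}),
        [("low", "good"), ("high", "bad")],
    )
    sigs["Yuen3"] = _sig(
        "Yuen3",
        [("TAZ", "up_is_risk"), ("AXL", "up_is_risk"), ("CTGF", "up_is_risk")],
        RuleSpec("tally", {"reference": "median", "label_by_count": True,
                           "labels": ["0", "1", "2", "3"]}),
        [("0", "good"), ("1", "intermediate"), ("2", "intermediate"),
         ("3", "bad")],
    )
    sigs["Oncodefender"] = _sig(
        "Oncodefender",
        ["BMI1", "VEGFA", "H3F3B", "ETV6", "RPS10"],
        RuleSpec("product_ratio", {
            "terms": [
                {"sign": 1, "numerator": ["BMI1", "VEGFA"],
                 "denominator": ["H3F3B"]},
                {"sign": -1, "numerator": ["ETV6", "H3F3B"],
                 "denominator": ["RPS10"]},
            ],
            "cutoff_mode": "cohort_median", "labels": ["low", "high"]}),
        [("low", "good"), ("high", "bad")],
        housekeeping=["B2M", "GUSB", "POLR2L", "PSMB6", "UBC"],
    )
    sigs["ColoGuidePro"] = _sig(
        "ColoGuidePro",
        [("DMBT1", "up_is_risk"), ("NT5E", "up_is_risk"),
         ("SEMA3A", "up_is_risk"), ("WNT11", "up_is_risk"),
         ("CXCL9", "down_is_risk"), ("OLFM4", "down_is_risk"),
         ("UGT2B17", "down_is_risk")],
        RuleSpec("tally", {"reference": "median", "threshold": 3,
                           "label_if_tally_ge": "poor", "label_else": "good",
                           "labels": ["good", "poor"]}),
        [("good", "good"), ("poor", "bad")],
    )
    return sigs


def builtin_rule_defaults() -> dict[str, dict[str, Any]]:
    """Rule skeletons for classifiers whose gene lists are config-supplied.

    A config entry can name one of these via ``extends`` and add its gene
    list (and weights where the rule needs them); the rule parameters here
    carry the published constants (ODXcolon cutoffs 30/40 and delta-Ct
    constant -15, ColoGuideEx 80th/20th percentile tally of >= 5, V7RHS
    cutoff 0, Meta163 confidence floor 0.90, ...).
    """
    return {
        "ODXcolon": {
            "rule": {"kind": "linear_cutoff", "params": {
                "cutoff_mode": "fixed", "cutoffs": [30, 40],
                "labels": ["low", "intermediate", "high"],
                "delta_ct": {"constant": -15, "mean_mode": "arithmetic"}}},
            "labels": [["low", "good"], ["intermediate", "intermediate"],
                       ["high", "bad"]],
        },
        "V7RHS": {
            "rule": {"kind": "linear_cutoff", "params": {
                "cutoff_mode": "fixed", "cutoffs": [0],
                "labels": ["low", "high"],
                "delta_ct": {"constant": -15, "mean_mode": "arithmetic"}}},
            "labels": [["low", "good"], ["high", "bad"]],
            "housekeeping": ["ACTB", "HMBS", "RPL13A"],
        },
        "ColoGuideEx": {
            "rule": {"kind": "tally", "params": {
                "reference": "percentile", "hi": 80, "lo": 20, "threshold": 5,
                "label_if_tally_ge": "high", "label_else": "low",
                "labels": ["low", "high"]}},
            "labels": [["low", "good"], ["high", "bad"]],
        },
        "CIN25": {
            "rule": {"kind": "signature_mean_split", "params": {
                "cutoff_mode": "cohort_median",
                "labels": ["CIN-low", "CIN-high"]}},
            "labels": [["CIN-low", "good"], ["CIN-high", "bad"]],
        },
        "Chang95": {
            "rule": {"kind": "signature_mean_split", "params": {
                "cutoff_mode": "tertile",
                "labels": ["low", "intermediate", "high"]}},
            "labels": [["low", "good"], ["intermediate", "intermediate"],
                       ["high", "bad"]],
        },
        "TCA19": {
            "rule": {"kind": "linear_cutoff", "params": {
                "cutoff_mode": "cohort_median", "labels": ["low", "high"]}},
            "labels": [["low", "good"], ["high", "bad"]],
        },
        "Schetter": {
            "rule": {"kind": "dual_median", "params": {
                "label_both_high": "high", "label_else": "low",
                "labels": ["low", "high"]}},
            "labels": [["low", "good"], ["high", "bad"]],
        },
        "Popovici": {
            "rule": {"kind": "group_mean_compare", "params": {
                "label_g1_less": "BRAF-mutant-like",
                "label_otherwise": "wild-type-like"}},
            "labels": [["BRAF-mutant-like", "bad"],
                       ["wild-type-like", "good"]],
        },
        "Meta163": {
            "rule": {"kind": "trained_model", "params": {
                "engine": "shrunken_centroid", "confidence_floor": 0.90,
                "labels": ["good", "poor"]}},
            "labels": [["good", "good"], ["poor", "bad"]],
        },
    }


# ---------------------------------------------------------------------------
# config I/O


def _gene_to_dict(g: SignatureGene) -> dict[str, Any]:
    d: dict[str, Any] = {"symbol": g.symbol, "direction": g.direction}
    if g.weight is not None:
        d["weight"] = g.weight
    return d


def signature_to_dict(sig: Signature) -> dict[str, Any]:
    return {
        "name": sig.name,
        "genes": [_gene_to_dict(g) for g in sig.genes],
        "rule": {"kind": sig.rule.kind, "params": sig.rule.params},
        "labels": [[l, p] for l, p in sig.labels],
        "housekeeping": list(sig.housekeeping),
        "training_set_ids": list(sig.training_set_ids),
    }


def signature_from_dict(d: Mapping[str, Any]) -> Signature:
    entry = dict(d)
    base = entry.pop("extends", None)
    if base is not None:
        defaults = builtin_rule_defaults()
        if base not in defaults:
            raise SignatureValidationError(f"unknown extends target {base!r}")
        merged = {k: v for k, v in defaults[base].items()}
        merged.update(entry)
        merged.setdefault("name", base)
        entry = merged
    genes = []
    for g in entry["genes"]:
        if isinstance(g, str):
            genes.append(SignatureGene(g))
        else:
            genes.append(SignatureGene(g["symbol"],
                                       g.get("direction", "unsigned"),
                                       g.get("weight")))
    rule_d = entry["rule"]
    rule = RuleSpec(rule_d["kind"], dict(rule_d.get("params", {})))
    labels = [tuple(l) for l in entry["labels"]]
    return Signature(entry["name"], genes, rule, labels,
                     list(entry.get("housekeeping", [])),
                     list(entry.get("training_set_ids", [])))


def load_signature_config(path: str | Path,
                          include_builtins: bool = False) -> list[Signature]:
    """Load signatures from a YAML bundle (``signatures:`` list of entries).

    Each entry either defines a signature in full or ``extends`` a built-in
    rule skeleton, supplying the gene list. With ``include_builtins`` the
    fully-specified built-in classifiers are appended (config entries of the
    same name take precedence).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc.get("signatures", []) if isinstance(doc, dict) else doc
    sigs = [signature_from_dict(e) for e in entries]
    if include_builtins:
        have = {s.name for s in sigs}
        sigs.extend(s for n, s in builtin_signatures().items()
                    if n not in have)
    return sigs


def save_signature_config(sigs: Sequence[Signature], path: str | Path) -> None:
    doc = {"signatures": [signature_to_dict(s) for s in sigs]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
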
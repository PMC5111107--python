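"""Assignment of cell lines to molecular subtypes from replicate arrays.

A cell line measured on several arrays gets a final label per classifier
only when the modal per-array label reaches 60% of the arrays; otherwise
the classifier is NA for that line. Mutation annotations (KRAS, BRAF,
PIK3CA, PTEN, TP53, APC) are joined from a user-supplied table.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

MUTATION_GENES = ("KRAS", "BRAF", "PIK3CA", "PTEN", "TP53", "APC")
MUTATION_CODES = ("M", "WT", "NA")


@dataclass
class CellLinePanel:
    cell_line: str
    array_ids: list[str]
    per_array_labels: dict[str, list]  # classifier -> label per array
    final_labels: dict[str, str | None] = field(default_factory=dict)
    mutations: dict[str, str] = field(default_factory=dict)
    msi_status: str = "NA"


def tally_assign(per_array_labels: list) -> str | None:
    """Consensus label across replicate arrays.

    The modal label wins iff its frequency is at least 60% of all arrays
    (an inclusive threshold: 3-of-5 at exactly 60% passes, a 50/50 split
    does not). NA array calls count in the denominator but never win.
    """
    if not per_array_labels:
        raise ValueError("no arrays for cell line")
    n = len(per_array_labels)
    counts = Counter(l for l in per_array_labels if l is not None
                     and not pd.isna(l))
    if not counts:
        return None
    label, top = counts.most_common(1)[0]
    return label if top / n >= 0.60 else None


def assign_panels(per_array_calls: pd.DataFrame) -> list[CellLinePanel]:
    """Build per-line panels from a long table of per-array calls.

    Expects columns cell_line, array_id, classifier, label.
    """
    panels = []
    for line, block in per_array_calls.groupby("cell_line", sort=True):
        arrays = sorted(block["array_id"].unique())
        per_cls: dict[str, list] = {}
        finals: dict[str, str | None] = {}
        for cls, sub in block.groupby("classifier"):
            by_array = sub.set_index("array_id")["label"]
            labels = [by_array.get(a) for a in arrays if a in by_array.index]
            per_cls[cls] = labels
            finals[cls] = tally_assign(labels)
        panels.append(CellLinePanel(str(line), arrays, per_cls, finals))
    return panels


def annotate_mutations(panels: list[CellLinePanel],
                       mutation_table: str | Path | pd.DataFrame
                       ) -> list[CellLinePanel]:
    """Join mutation statuses onto panels from a cell_line/gene/status table.

    Conflicting duplicate rows for a line+gene raise; lines absent from the
    table get NA for every gene, with a warning.
    """
    if not isinstance(mutation_table, pd.DataFrame):
        mutation_table = pd.read_csv(mutation_table, sep="\t", dtype=str)
    required = {"cell_line", "gene", "status"}
    if not required.issubset(mutation_table.columns):
        raise ValueError(f"mutation table needs columns {sorted(required)}")
    bad = ~mutation_table["status"].isin(MUTATION_CODES)
    if bad.any():
        raise ValueError(
            f"invalid mutation code(s): "
            f"{sorted(mutation_table.loc[bad, 'status'].unique())}")
    dup = mutation_table.groupby(["cell_line", "gene"])["status"].nunique()
    conflicts = dup[dup > 1]
    if len(conflicts):
        raise ValueError(
            f"conflicting duplicate mutation rows for {list(conflicts.index)}")
    table = mutation_table.drop_duplicates().set_index(["cell_line", "gene"])
    for panel in panels:
        known = panel.cell_line in mutation_table["cell_line"].values
        if not known:
            logger.warning("cell line %s absent from mutation table, all NA",
                           panel.cell_line)
        panel.mutations = {
            g: (str(table.loc[(panel.cell_line, g), "status"])
                if known and (panel.cell_line, g) in table.index else "NA")
            for g in MUTATION_GENES}
    return panels


def panels_to_frame(panels: list[CellLinePanel]) -> pd.DataFrame:
    """Flatten panels into the benchmark's cell-line output table."""
    rows = []
    for p in panels:
        row: dict = {"cell_line": p.cell_line, "n_arrays": len(p.array_ids),
                     "msi_status": p.msi_status}
        for cls, label in sorted(p.final_labels.items()):
            row[cls] = label if label is not None else "NA"
        for g in MUTATION_GENES:
            row[g] = p.mutations.get(g, "NA")
        rows.append(row)
    return pd.DataFrame(rows)


def subtype_prevalence_vs_models(
    patient_calls: pd.Series,
    panels: list[CellLinePanel],
    classifier: str,
) -> pd.DataFrame:
    """Patient subtype prevalences next to available cell-line model counts.

    NA is shown as its own category on the patient side; labels with zero
    cell-line models are flagged unmodeled. Percentages sum to 100.
    """
    labels = patient_calls.fillna("NA").astype(str)
    prev = labels.value_counts(normalize=True) * 100.0
    model_counts = Counter(
        p.final_labels.get(classifier) for p in panels
        if p.final_labels.get(classifier) is not None)
    cats = sorted(set(prev.index) | set(map(str, model_counts)))
    rows = []
    for cat in cats:
        n_models = int(model_counts.get(cat, 0))
        rows.append({
            "classifier": classifier, "label": cat,
            "patient_pct": float(prev.get(cat, 0.0)),
            "n_models": n_models,
            "unmodeled": cat != "NA" and n_models == 0})
    return pd.DataFrame(rows)
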
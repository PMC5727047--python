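"""Cohort table I/O, per-tissue feature matrices and standardization.

Two variable sets are assembled per tissue:

* ``ann_markers`` — the classifier inputs: the 15 lineage/memory frequency
  markers for PB, BM, SPL, PLN_MLN and MLN (CD34 replacing CD14 in BM), or
  the 8 thymus markers (developmental compartments, TCRab+ fraction of CD3
  and the CD4:CD8 single-positive ratio);
* ``pca_variables`` — the PCA inputs: percentages and counts jointly for BM
  and SPL (30 variables), percentages only for PB, PLN_MLN and MLN (15),
  and for the thymus the 8 marker values plus the 6 absolute compartment
  counts (14 variables; the TCRab fraction and the CD4:CD8 ratio are
  derived quantities without a count twin).

Columns are named with the flow-cytometry convention ``marker%`` for
frequencies and ``marker#`` for counts.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from immunosig.errors import (
    DegenerateVariableError,
    EmptyTissueError,
    SchemaError,
)
from immunosig.synthetic import (
    CohortDataset,
    MouseRecord,
    SUBSET_STAGES,
    TISSUES,
    TissueMeasurement,
    lineage_markers,
)

log = logging.getLogger(__name__)

VALUE_TYPES = ("frequency_percent", "count", "concentration")
CSV_HEADER = ["mouse_id", "sex", "group", "cb_unit", "tissue", "marker", "value_type", "value"]

THY_COUNT_MARKERS = ("huCD45", "CD3", "DN", "DP", "CD4SP", "CD8SP")


def ann_marker_panel(tissue: str) -> list[str]:
    """Classifier input columns for a tissue (15 markers; 8 for thymus)."""
    if tissue == "THY":
        return ["huCD45%", "CD3%", "CD4SP%", "CD8SP%", "DN%", "DP%",
                "TCRab_CD3%", "CD4_CD8_ratio"]
    names = ["huCD45", *lineage_markers(tissue), "CD4", "CD8"]
    names += [f"CD4_{s}" for s in SUBSET_STAGES]
    names += [f"CD8_{s}" for s in SUBSET_STAGES]
    return [f"{n}%" for n in names]


def pca_variable_panel(tissue: str) -> list[str]:
    """PCA input columns: 30 for BM/SPL, 15 for PB/PLN_MLN/MLN, 14 for THY."""
    if tissue == "THY":
        return (["huCD45%", "CD3%", "CD4SP%", "CD8SP%", "DN%", "DP%", "TCRab_CD3%",
                 "CD4_CD8_ratio"] + [f"{n}#" for n in THY_COUNT_MARKERS])
    pct = ann_marker_panel(tissue)
    if tissue in ("BM", "SPL"):
        return pct + [v[:-1] + "#" for v in pct]
    return pct


@dataclass
class FeatureMatrix:
    """Mice × variables numeric table for one tissue and one variable set."""

    tissue: str
    variable_set: str  # "ann_markers" | "pca_variables"
    variables: list[str]
    rows: list[str]  # mouse_ids, roster order
    values: np.ndarray  # shape (len(rows), len(variables))
    labels: np.ndarray  # 0 = control, 1 = immunized
    sex: np.ndarray  # "F"/"M" per row

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask, dtype=bool)
        return FeatureMatrix(
            tissue=self.tissue,
            variable_set=self.variable_set,
            variables=list(self.variables),
            rows=[r for r, keep in zip(self.rows, mask) if keep],
            values=self.values[mask],
            labels=self.labels[mask],
            sex=self.sex[mask],
        )


@dataclass
class StandardizedMatrix(FeatureMatrix):
    """A FeatureMatrix after column-wise z-scoring (sample SD, n-1)."""

    means: np.ndarray = field(default_factory=lambda: np.empty(0))
    sds: np.ndarray = field(default_factory=lambda: np.empty(0))


def write_cohort(dataset: CohortDataset, path) -> None:
    """Write the long-format CSV; a `censored` column is added only if needed."""
    any_censored = any(m.censored for m in dataset.measurements)
    header = CSV_HEADER + (["censored"] if any_censored else [])
    lookup = {m.mouse_id: m for m in dataset.mice}
    with open(path, "w", newline="") as fh:
        if dataset.provenance:
            fh.write(f"# {dataset.provenance}\n")
        writer = csv.writer(fh)
        writer.writerow(header)
        for meas in dataset.measurements:
            mouse = lookup[meas.mouse_id]
            row = [meas.mouse_id, mouse.sex, mouse.group, mouse.cb_unit,
                   meas.tissue, meas.marker, meas.value_type, repr(meas.value)]
            if any_censored:
                row.append(int(meas.censored))
            writer.writerow(row)


def read_cohort(path) -> CohortDataset:
    """Read and validate a long-format cohort CSV.

    Rejects unknown tissue codes, out-of-range frequencies, negative
    counts, duplicate (mouse, tissue, marker, value_type) keys and
    inconsistent per-mouse metadata, naming the offending row.
    """
    provenance = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            provenance = first.lstrip("#").strip()
        else:
            fh.seek(0)
        df = pd.read_csv(fh, float_precision="round_trip")

    missing = [c for c in CSV_HEADER if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    mice: dict[str, MouseRecord] = {}
    measurements: list[TissueMeasurement] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 2 = first data line
        if row.tissue not in TISSUES and row.tissue != "PLASMA":
            raise SchemaError(f"row {i}: unknown tissue code {row.tissue!r}")
        if row.value_type not in VALUE_TYPES:
            raise SchemaError(f"row {i}: unknown value_type {row.value_type!r}")
        value = float(row.value)
        if row.value_type == "frequency_percent" and not 0.0 <= value <= 100.0:
            raise SchemaError(f"row {i}: frequency_percent out of [0, 100]: {value}")
        if row.value_type == "count" and value < 0:
            raise SchemaError(f"row {i}: negative count: {value}")
        key = (row.mouse_id, row.tissue, row.marker, row.value_type)
        if key in seen:
            raise SchemaError(f"row {i}: duplicate measurement key {key}")
        seen.add(key)
        record = MouseRecord(str(row.mouse_id), str(row.sex), str(row.group), str(row.cb_unit))
        prior = mice.setdefault(record.mouse_id, record)
        if (prior.sex, prior.group, prior.cb_unit) != (record.sex, record.group, record.cb_unit):
            raise SchemaError(f"row {i}: inconsistent metadata for mouse {record.mouse_id!r}")
        censored = bool(getattr(row, "censored", False))
        measurements.append(TissueMeasurement(record.mouse_id, row.tissue, row.marker,
                                              row.value_type, value, censored=censored))

    dataset = CohortDataset(mice=list(mice.values()), measurements=measurements,
                            provenance=provenance or str(path))
    dataset.validate()
    return dataset


def _wide_table(cohort: CohortDataset, tissue: str) -> dict[str, dict[str, float]]:
    suffix = {"frequency_percent": "%", "count": "#"}
    table: dict[str, dict[str, float]] = {}
    for meas in cohort.measurements:
        if meas.tissue != tissue or meas.value_type not in suffix:
            continue
        table.setdefault(meas.mouse_id, {})[meas.marker + suffix[meas.value_type]] = meas.value
    return table


def build_feature_matrix(cohort: CohortDataset, tissue: str,
                         variable_set: str = "ann_markers") -> FeatureMatrix:
    """Assemble the mice × variables table for one tissue.

    Each tissue is treated as an independent dataset; mice missing any
    panel variable in that tissue are dropped with a logged warning.  The
    thymic CD4:CD8 ratio is computed from CD4SP%/CD8SP% when not present
    as its own column.
    """
    if variable_set == "ann_markers":
        variables = ann_marker_panel(tissue)
    elif variable_set == "pca_variables":
        variables = pca_variable_panel(tissue)
    else:
        raise ValueError(f"unknown variable_set {variable_set!r}")

    table = _wide_table(cohort, tissue)
    if tissue == "THY":
        for mouse_id, row in table.items():
            if "CD4_CD8_ratio" not in row and row.get("CD8SP%", 0.0) > 0:
                row["CD4_CD8_ratio"] = row["CD4SP%"] / row["CD8SP%"]

    rows, grid, labels, sexes = [], [], [], []
    for mouse in cohort.mice:
        row = table.get(mouse.mouse_id)
        if row is None:
            continue
        if any(v not in row for v in variables):
            absent = [v for v in variables if v not in row]
            log.warning("dropping %s in %s: missing %s", mouse.mouse_id, tissue, absent)
            continue
        rows.append(mouse.mouse_id)
        grid.append([row[v] for v in variables])
        labels.append(1 if mouse.group == "immunized" else 0)
        sexes.append(mouse.sex)

    if not rows:
        raise EmptyTissueError(f"no mouse has a complete {variable_set} panel for {tissue}")

    return FeatureMatrix(
        tissue=tissue,
        variable_set=variable_set,
        variables=variables,
        rows=rows,
        values=np.asarray(grid, dtype=float),
        labels=np.asarray(labels, dtype=int),
        sex=np.asarray(sexes, dtype=object),
    )


def standardize(matrix: FeatureMatrix) -> StandardizedMatrix:
    """Column-wise z-scores (sample SD, n-1 denominator).

    Raises :class:`DegenerateVariableError` naming any constant column;
    callers may drop the column and retry.
    """
    X = matrix.values
    if X.shape[0] < 2:
        raise DegenerateVariableError("standardization needs at least 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0.0)
    if bad.size:
        names = [matrix.variables[j] for j in bad]
        raise DegenerateVariableError(f"constant variable(s): {names}")
    return StandardizedMatrix(
        tissue=matrix.tissue,
        variable_set=matrix.variable_set,
        variables=list(matrix.variables),
        rows=list(matrix.rows),
        values=(X - means) / sds,
        labels=matrix.labels.copy(),
        sex=matrix.sex.copy(),
        means=means,
        sds=sds,
    )


def inverse_standardize(matrix: StandardizedMatrix) -> np.ndarray:
    """Undo the z-scoring; returns the original-value grid."""
    return matrix.values * matrix.sds + matrix.means


def write_matrix(matrix: StandardizedMatrix, path, provenance: str = "") -> None:
    """Export a standardized matrix as wide CSV with a provenance comment line."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# {provenance or matrix.tissue + '/' + matrix.variable_set}\n")
        writer = csv.writer(fh)
        writer.writerow(["mouse_id", "group", "sex", *matrix.variables])
        for i, mouse_id in enumerate(matrix.rows):
            writer.writerow([mouse_id, int(matrix.labels[i]), matrix.sex[i],
                             *(repr(v) for v in matrix.values[i])])
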
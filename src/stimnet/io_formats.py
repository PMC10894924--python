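"""Readers and writers for the external formats the pipeline touches.

The pipeline's entry points are plain text tables: a genes × samples log2
expression TSV with a condition/patient sidecar, a per-patient clinical table
of cardiovascular risk factors, GMT gene-set collections, a transcription
factor list, and a drug-by-gene signature library. Everything written here is
UTF-8, tab-delimited, with "." as the decimal separator, so round trips are
bit-stable across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "CohortSummary",
    "FormatError",
    "AnnotationError",
    "SchemaError",
    "BINARY_COVARIATES",
    "CONTINUOUS_COVARIATES",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_gmt",
    "write_gmt",
    "read_tf_list",
    "read_drug_library",
    "write_drug_library",
    "write_edge_table",
    "read_edge_table",
    "summarize_cohort",
]

CONDITIONS = ("baseline", "stimulated")

#: Binary cardiovascular risk factors, coded {0, 1}.
BINARY_COVARIATES = ("sex", "renal_failure", "smoker", "diabetes")
#: Continuous cardiovascular risk factors (units: years, kg/m2, bpm, mmHg,
#: mmHg, mmol/dL, mmol/dL, mmol/dL, mmol/dL, mmol/dL).
CONTINUOUS_COVARIATES = (
    "age",
    "bmi",
    "heart_rate",
    "dbp",
    "sbp",
    "glucose",
    "triglyceride",
    "creatinine",
    "hdl",
    "ldl",
)
ALL_COVARIATES = BINARY_COVARIATES + CONTINUOUS_COVARIATES


class FormatError(ValueError):
    """Malformed input file (duplicates, non-numeric cells, short lines)."""


class AnnotationError(ValueError):
    """A sample is missing its condition or patient annotation."""


class SchemaError(ValueError):
    """A required column is absent from a clinical table."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes × samples log2-intensity matrix with sample annotations.

    ``values`` is indexed by gene id with sample ids as columns; ``condition``
    and ``patient_id`` map every sample to its stimulation state and donor.
    At most one sample per (patient, condition) pair is allowed.
    """

    values: pd.DataFrame
    condition: dict[str, str]
    patient_id: dict[str, str]

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise FormatError("expression values must be finite")
        pairs: set[tuple[str, str]] = set()
        for s in self.values.columns:
            if s not in self.condition:
                raise AnnotationError(f"sample {s!r} has no condition annotation")
            if s not in self.patient_id:
                raise AnnotationError(f"sample {s!r} has no patient annotation")
            if self.condition[s] not in CONDITIONS:
                raise AnnotationError(
                    f"sample {s!r}: condition must be one of {CONDITIONS}, "
                    f"got {self.condition[s]!r}"
                )
            key = (self.patient_id[s], self.condition[s])
            if key in pairs:
                raise AnnotationError(
                    f"more than one sample for patient {key[0]!r} in condition {key[1]!r}"
                )
            pairs.add(key)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition[s] == condition]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(self.values.loc[genes], dict(self.condition), dict(self.patient_id))

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        keep = [s for s in self.values.columns if s in set(samples)]
        return ExpressionMatrix(
            self.values[keep],
            {s: self.condition[s] for s in keep},
            {s: self.patient_id[s] for s in keep},
        )


@dataclass
class ClinicalTable:
    """Patient-by-risk-factor table (14 cardiovascular covariates).

    Binary covariates are coded {0, 1}; missing values are allowed and
    propagate as NaN (pairwise-complete handling downstream).
    """

    data: pd.DataFrame  # indexed by patient id

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "patient")
        missing = [c for c in ALL_COVARIATES if c not in self.data.columns]
        if missing:
            raise SchemaError(f"clinical table missing required columns: {missing}")
        for col in BINARY_COVARIATES:
            vals = self.data[col].dropna().unique()
            bad = [v for v in vals if v not in (0, 1, 0.0, 1.0)]
            if bad:
                raise ValueError(f"binary covariate {col!r} has non-binary values: {bad}")
        for col in ("dbp", "sbp"):
            vals = self.data[col].dropna()
            if (vals <= 0).any():
                raise ValueError(f"{col} must be strictly positive")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    def covariate(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise SchemaError(f"unknown covariate {name!r}")
        return self.data[name]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), e.g. GO or pathway collections."""

    sets: dict[str, set[str]]
    source: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")


@dataclass
class CohortSummary:
    """Table-1-style cohort summary: counts/percentages for binary covariates,
    mean ± sd for continuous ones."""

    n_patients: int
    binary: dict[str, tuple[int, float]]  # covariate -> (count, percentage)
    continuous: dict[str, tuple[float, float]]  # covariate -> (mean, sd)


# ---------------------------------------------------------------------------
# expression matrices


def _parse_sample_name(sample: str) -> tuple[str, str] | None:
    """Interpret ``<patient>_<condition>`` sample names; None if no match."""
    if "_" not in sample:
        return None
    patient, cond = sample.rsplit("_", 1)
    if cond in CONDITIONS:
        return patient, cond
    return None


def read_expression_matrix(path, condition_map=None) -> ExpressionMatrix:
    """Read a genes × samples TSV plus sample annotations.

    Annotations come either from a sidecar TSV (columns: sample, condition
    [, patient]) or from ``<patient>_<condition>`` sample names; the sidecar
    wins when both are present.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
    _check_unique(header_line.split("\t")[1:], "sample")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    _check_unique(df.index, "gene")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.argmax()]
                raise FormatError(
                    f"non-numeric expression value at gene {row!r}, sample {col!r}"
                ) from exc
        raise FormatError(str(exc)) from exc

    condition: dict[str, str] = {}
    patient: dict[str, str] = {}
    for s in values.columns:
        parsed = _parse_sample_name(str(s))
        if parsed is not None:
            patient[s], condition[s] = parsed
    if condition_map is not None:
        side = pd.read_csv(condition_map, sep="\t", dtype=str)
        cols = [c.lower() for c in side.columns]
        side.columns = cols
        if "sample" not in cols or "condition" not in cols:
            raise FormatError("sidecar must have 'sample' and 'condition' columns")
        for _, row in side.iterrows():
            s = row["sample"]
            condition[s] = row["condition"]
            if "patient" in cols and isinstance(row.get("patient"), str):
                patient[s] = row["patient"]
            elif s not in patient:
                patient[s] = s
    return ExpressionMatrix(values, condition, patient)


def write_expression_matrix(expr: ExpressionMatrix, path, sidecar=None) -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
    if sidecar is not None:
        rows = [
            {"sample": s, "condition": expr.condition[s], "patient": expr.patient_id[s]}
            for s in expr.sample_ids
        ]
        pd.DataFrame(rows).to_csv(sidecar, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clinical tables

_BINARY_CODES = {
    "yes": 1, "no": 0, "y": 1, "n": 0, "true": 1, "false": 0,
    "1": 1, "0": 0, "1.0": 1, "0.0": 0, "male": 1, "female": 0,
}


def read_clinical_table(path) -> ClinicalTable:
    """Read a per-patient risk-factor table (CSV or TSV, sniffed by header)."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in BINARY_COVARIATES:
        if col not in df.columns:
            continue
        coerced = []
        for v in df[col]:
            if pd.isna(v):
                coerced.append(np.nan)
                continue
            key = str(v).strip().lower()
            if key not in _BINARY_CODES:
                raise ValueError(f"cannot coerce {v!r} in binary column {col!r} to 0/1")
            coerced.append(_BINARY_CODES[key])
        df[col] = coerced
    return ClinicalTable(df)


def write_clinical_table(clin: ClinicalTable, path) -> None:
    out = clin.data.copy()
    out.index.name = "patient_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# gene sets and TF lists


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then members."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: expected >= 3 fields, got {len(fields)}")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            members = {m for m in fields[2:] if m}
            if not members:
                raise FormatError(f"GMT line {lineno}: set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, source=str(path), descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_tf_list(path) -> list[str]:
    """One transcription-factor identifier per line; order preserved."""
    tfs: list[str] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            tf = line.strip()
            if tf and tf not in seen:
                tfs.append(tf)
                seen.add(tf)
    return tfs


# ---------------------------------------------------------------------------
# drug-signature libraries


def read_drug_library(path) -> pd.DataFrame:
    """Drug-by-gene differential-score matrix with a ``cell_line`` column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "cell_line" not in df.columns:
        raise FormatError("drug library must have a 'cell_line' column")
    _check_unique(df.index, "drug")
    scores = df.drop(columns="cell_line").astype(float)
    if not np.isfinite(scores.to_numpy()).all():
        raise FormatError("drug signature scores must be finite")
    out = scores.copy()
    out.insert(0, "cell_line", df["cell_line"])
    return out


def write_drug_library(library: pd.DataFrame, path) -> None:
    out = library.copy()
    out.index.name = "drug_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# networks


def write_edge_table(network: nx.Graph, path, dialect: str = "tsv") -> None:
    """Write a (di)graph as SIF or a 4-column TSV in lexicographic edge order."""
    if dialect not in ("sif", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    directed = network.is_directed()
    edges = sorted(
        (str(u), str(v), data) if directed else (*sorted((str(u), str(v))), data)
        for u, v, data in network.edges(data=True)
    )
    with open(path, "w", encoding="utf-8") as fh:
        if dialect == "sif":
            for u, v, data in edges:
                interaction = str(data.get("interaction", "interacts"))
                fh.write(f"{u}\t{interaction}\t{v}\n")
        else:
            fh.write("source\ttarget\tweight\tsign\n")
            for u, v, data in edges:
                w = data.get("weight", 1.0)
                sign = data.get("sign", "")
                fh.write(f"{u}\t{v}\t{w:.10g}\t{sign}\n")
    # directed flag only affects semantics of (u, v) order; no marker needed
    _ = directed


def read_edge_table(path, directed: bool = False) -> nx.Graph:
    """Read back a TSV edge table written by :func:`write_edge_table`."""
    g: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    df = pd.read_csv(path, sep="\t")
    for _, row in df.iterrows():
        attrs = {"weight": float(row["weight"])}
        if "sign" in df.columns and not pd.isna(row["sign"]) and str(row["sign"]) != "":
            attrs["sign"] = row["sign"]
        g.add_edge(str(row["source"]), str(row["target"]), **attrs)
    return g


# ---------------------------------------------------------------------------
# cohort summary


def summarize_cohort(clin: ClinicalTable) -> CohortSummary:
    """Count/percentage per binary covariate, mean ± sd per continuous one.

    Percentages use the full cohort size as denominator and are rounded to
    two decimals; means and sample standard deviations use the non-missing
    values only.
    """
    n = len(clin.data)
    if n == 0:
        raise ValueError("clinical table is empty")
    binary: dict[str, tuple[int, float]] = {}
    for col in BINARY_COVARIATES:
        count = int(clin.data[col].fillna(0).sum())
        binary[col] = (count, round(100.0 * count / n, 2))
    continuous: dict[str, tuple[float, float]] = {}
    for col in CONTINUOUS_COVARIATES:
        vals = clin.data[col].dropna()
        continuous[col] = (float(vals.mean()), float(vals.std(ddof=1)))
    return CohortSummary(n_patients=n, binary=binary, continuous=continuous)


def cohort_summary_to_json(summary: CohortSummary) -> str:
    return json.dumps(
        {
            "n_patients": summary.n_patients,
            "binary": {k: {"count": c, "percent": p} for k, (c, p) in summary.binary.items()},
            "continuous": {
                k: {"mean": m, "sd": s} for k, (m, s) in summary.continuous.items()
            },
        },
        indent=2,
    )
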
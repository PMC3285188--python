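"""Readers, writers and validated containers for the pipeline's inputs.

Three kinds of input drive the analysis:

* a log2 expression matrix (genes x samples) with a sample design table
  mapping every sample to a patient, a response group (``IF`` insulin free /
  ``ID`` insulin dependent) and a timepoint (``pre`` / ``post`` treatment);
* gene-set collections in GMT format (the pathway database stand-in);
* a per-patient clinical table (demographics, transplant parameters,
  glycemic control, autoantibody titers, insulin doses and C-peptide).

Matrices are accepted as plain TSV (header row of sample ids, first column
of gene ids) or as GCT version ``#1.2``.  All loaders validate the paired
design and never reorder genes; samples are aligned to the design by id,
not by position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

GROUPS = ("IF", "ID")
TIMEPOINTS = ("pre", "post")

#: default analysis thresholds; overridable via a YAML config file
DEFAULT_CONFIG = {
    "p_thr": 0.05,
    "fdr_thr": 0.05,
    "diffk_thr": 0.2,
    "edge_thr": 0.8,
    "n_perm": 999,
}


class LoadError(ValueError):
    """Raised when an input file fails validation."""


# ---------------------------------------------------------------------------
# expression study
# ---------------------------------------------------------------------------


@dataclass
class ExpressionStudy:
    """A log2 expression matrix plus its paired sample design.

    Parameters
    ----------
    matrix
        genes x samples DataFrame of log2 expression values; the index holds
        unique gene ids and the columns unique sample ids.
    design
        one row per sample (index = sample id) with columns ``patient_id``,
        ``group`` and ``timepoint``.  Every patient must contribute exactly
        one ``pre`` and one ``post`` sample.
    meta
        free-form provenance (e.g. the sample-merging map).
    """

    matrix: pd.DataFrame
    design: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        m, d = self.matrix, self.design
        if m.index.duplicated().any():
            dup = m.index[m.index.duplicated()][0]
            raise LoadError(f"duplicate gene id {dup!r}")
        if m.columns.duplicated().any():
            dup = m.columns[m.columns.duplicated()][0]
            raise LoadError(f"duplicate sample id {dup!r}")
        missing = set(m.columns) - set(d.index)
        if missing:
            raise LoadError(f"samples missing from design: {sorted(missing)}")
        extra = set(d.index) - set(m.columns)
        if extra:
            raise LoadError(f"design lists samples absent from matrix: {sorted(extra)}")
        # align design rows to matrix column order (by id, never position)
        self.design = d = d.loc[m.columns]
        bad_group = set(d["group"]) - set(GROUPS)
        if bad_group:
            raise LoadError(f"unknown group label(s): {sorted(bad_group)}")
        bad_tp = set(d["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise LoadError(f"unknown timepoint label(s): {sorted(bad_tp)}")
        for pid, rows in d.groupby("patient_id", sort=False):
            tps = sorted(rows["timepoint"])
            if tps != ["post", "pre"]:
                raise LoadError(
                    f"patient {pid!r} is not paired (timepoints: {list(rows['timepoint'])})"
                )
            if rows["group"].nunique() != 1:
                raise LoadError(f"patient {pid!r} appears in more than one group")
        if m.isna().any().any():
            n_bad = int(m.isna().any(axis=1).sum())
            log.warning("dropping %d gene(s) with missing values", n_bad)
            self.matrix = m.dropna(axis=0)

    # -- accessors --------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    def patients(self, group: str | None = None) -> list[str]:
        d = self.design
        if group is not None:
            d = d[d["group"] == group]
        return list(dict.fromkeys(d["patient_id"]))

    def samples_for(self, group: str | None = None, timepoint: str | None = None) -> list[str]:
        d = self.design
        if group is not None:
            d = d[d["group"] == group]
        if timepoint is not None:
            d = d[d["timepoint"] == timepoint]
        return list(d.index)

    def subset_group(self, group: str) -> "ExpressionStudy":
        cols = self.samples_for(group=group)
        if not cols:
            raise LoadError(f"no samples in group {group!r}")
        return ExpressionStudy(self.matrix[cols].copy(), self.design.loc[cols].copy())

    def condition_matrix(self, group: str, timepoint: str) -> pd.DataFrame:
        """genes x samples slice for one of the four group/timepoint cells."""
        cols = self.samples_for(group=group, timepoint=timepoint)
        return self.matrix[cols]


def read_expression(
    path: str | Path,
    design_path: str | Path,
    log2_transform: bool = False,
    collapse_duplicates: bool = False,
) -> ExpressionStudy:
    """Load an expression matrix (TSV or GCT ``#1.2``) with its design table.

    ``log2_transform`` applies log2(x + 1) for matrices stored on the raw
    scale; downstream statistics assume log2 units.  With
    ``collapse_duplicates`` duplicate gene ids are collapsed by keeping the
    first occurrence (with a warning) instead of raising.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if first.startswith("#1.2"):
        matrix = _read_gct(path)
    else:
        matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    non_numeric = matrix.columns[
        [not np.issubdtype(dt, np.number) for dt in matrix.dtypes]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        bad = matrix[col][pd.to_numeric(matrix[col], errors="coerce").isna()]
        where = bad.index[0] if len(bad) else "?"
        raise LoadError(f"non-numeric value in column {col!r}, row {where!r}")
    if collapse_duplicates and matrix.index.duplicated().any():
        n = int(matrix.index.duplicated().sum())
        log.warning("collapsing %d duplicate gene id(s): first occurrence wins", n)
        matrix = matrix[~matrix.index.duplicated(keep="first")]
    if log2_transform:
        matrix = np.log2(matrix + 1.0)
    design = read_design(design_path)
    return ExpressionStudy(matrix, design)


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise LoadError(f"unsupported GCT version line: {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise LoadError("GCT dimension line malformed")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t")
    if df.shape != (n_genes, n_samples + 2):
        raise LoadError(
            f"GCT dimensions {df.shape} disagree with header ({n_genes}, {n_samples})"
        )
    df = df.set_index(df.columns[0]).drop(columns=[df.columns[1]])
    return df


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "group", "timepoint"}
    missing = required - set(design.columns)
    if missing:
        raise LoadError(f"design table missing column(s): {sorted(missing)}")
    return design.set_index("sample_id")


def write_expression(
    study: ExpressionStudy,
    path: str | Path,
    design_path: str | Path,
    fmt: str = "tsv",
) -> None:
    """Write the matrix (``tsv`` or ``gct``) and the design table."""
    if fmt == "tsv":
        study.matrix.to_csv(path, sep="\t", index_label="gene_id")
    elif fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{study.matrix.shape[0]}\t{study.matrix.shape[1]}\n")
            out = study.matrix.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    design = study.design.reset_index()
    if design.columns[0] != "sample_id":
        design = design.rename(columns={design.columns[0]: "sample_id"})
    design.to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional background universe."""

    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise LoadError(f"gene set {name!r} is empty")

    def restrict(self, universe: list[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop sets left empty."""
        uni = set(universe)
        sets = {}
        for name, members in self.sets.items():
            kept = [g for g in members if g in uni]
            if kept:
                sets[name] = kept
            else:
                log.warning("gene set %r empty after universe restriction; dropped", name)
        return GeneSetCollection(sets, universe=list(universe))


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LoadError(f"GMT line {lineno}: fewer than 3 fields")
            name, members = fields[0], fields[2:]
            if name in sets:
                raise LoadError(f"GMT line {lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                log.warning(
                    "gene set %r: %d duplicate member(s) removed",
                    name,
                    len(members) - len(deduped),
                )
            sets[name] = deduped
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

CLINICAL_NUMERIC = [
    "age",
    "bmi",
    "cd34_dose",
    "duration",
    "fbg",
    "pbg",
    "hba1c",
    "gada",
    "insulin_pre",
    "insulin_6mo",
    "insulin_12mo",
    "cpeptide_pre",
    "cpeptide_6mo",
    "cpeptide_12mo",
]


@dataclass
class ClinicalTable:
    """Per-patient clinical variables.

    Missing values (written ``-`` on disk) are kept as NaN, never coerced to
    zero.  GADA titers must be strictly positive so the natural-log
    transform used for its statistics is defined.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        required = {"case", "group", *CLINICAL_NUMERIC}
        missing = required - set(d.columns)
        if missing:
            raise LoadError(f"clinical table missing column(s): {sorted(missing)}")
        if d["case"].duplicated().any():
            raise LoadError("duplicate case ids in clinical table")
        bad = set(d["group"]) - set(GROUPS)
        if bad:
            raise LoadError(f"unknown group label(s): {sorted(bad)}")
        if (d["gada"] <= 0).any():
            raise LoadError("GADA must be > 0 (natural-log transform undefined)")

    def values(self, variable: str, group: str | None = None, dropna: bool = True) -> np.ndarray:
        d = self.data
        if group is not None:
            d = d[d["group"] == group]
        v = pd.to_numeric(d[variable])
        if dropna:
            v = v.dropna()
        return v.to_numpy(dtype=float)


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["-"], keep_default_na=True)
    for col in CLINICAL_NUMERIC:
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (TypeError, ValueError) as exc:
                raise LoadError(f"clinical column {col!r}: {exc}") from exc
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    out = table.data.copy()
    out.to_csv(path, sep="\t", index=False, na_rep="-")


def load_table1() -> ClinicalTable:
    """The packaged nine-patient clinical table (6 IF, 3 ID)."""
    with resources.as_file(resources.files("diffconn.data") / "table1.tsv") as p:
        return read_clinical(p)


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


def load_config(path: str | Path | None = None) -> dict:
    """Analysis thresholds; YAML file values override the defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise LoadError(f"unknown config key(s): {sorted(unknown)}")
        cfg.update(user)
    return cfg
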
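"""Clone-abundance tables and repertoire summary metrics.

A repertoire is summarised by three numbers: its size ``S`` (total templates
sequenced), its diversity ``D`` (number of unique clonotypes, i.e. richness),
and the top-``k`` clone mass ``S_k`` (templates carried by the ``k`` most
abundant clones).  ``P_k = 100 * S_k / S`` expresses the same mass as a
percentage of the repertoire and serves as a proxy for clonal expansion.
All logarithms in this package are base 10 (units of dex).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError

logger = logging.getLogger(__name__)

#: Canonical cohort-table columns (metrics part); covariates follow.
COHORT_METRIC_COLUMNS = ["subject_id", "S", "D", "S_10", "S_100", "S_1000"]
COHORT_COVARIATE_COLUMNS = ["age", "sex", "cmv_status"]

SEXES = frozenset({"male", "female"})
CMV_STATES = frozenset({"positive", "negative", "unknown"})

#: Default column names for the AIRR rearrangement dialect.
AIRR_ID_COLUMN = "sequence_id"
AIRR_COUNT_COLUMN = "duplicate_count"


@dataclass(frozen=True)
class CloneTable:
    """One subject's repertoire: opaque clone identifiers with template counts.

    Invariants (enforced in ``__post_init__``): every count is an integer
    >= 1 and clone identifiers are unique.
    """

    subject_id: str
    clone_ids: tuple[str, ...]
    templates: np.ndarray  # int64, aligned with clone_ids

    def __post_init__(self) -> None:
        counts = np.asarray(self.templates)
        if counts.size != len(self.clone_ids):
            raise FormatError("clone_ids and templates lengths differ")
        if counts.size == 0:
            raise EmptyInputError(f"clone table for {self.subject_id!r} is empty")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise FormatError(
                    "template counts must be integers; fractional abundances are rejected"
                )
            counts = counts.astype(np.int64)
        if np.any(counts < 1):
            bad = int(np.argmax(counts < 1))
            raise FormatError(
                f"clone {self.clone_ids[bad]!r} has non-positive count {int(counts[bad])}"
            )
        if len(set(self.clone_ids)) != len(self.clone_ids):
            raise FormatError(f"duplicate clone_id in table for {self.subject_id!r}")
        object.__setattr__(self, "templates", counts.astype(np.int64))
        object.__setattr__(self, "clone_ids", tuple(self.clone_ids))

    @property
    def total_templates(self) -> int:
        return int(self.templates.sum())

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)


@dataclass(frozen=True)
class RepertoireMetrics:
    """Summary metrics for one repertoire: S, D, S_k and P_k per requested k."""

    subject_id: str
    S: int
    D: int
    S_k: dict[int, int] = field(default_factory=dict)
    P_k: dict[int, float] = field(default_factory=dict)

    @property
    def log10_S(self) -> float:
        return float(np.log10(self.S))

    @property
    def log10_D(self) -> float:
        return float(np.log10(self.D))


@dataclass(frozen=True)
class SubjectCovariates:
    """Demographic / exposure covariates consumed as labels."""

    subject_id: str
    age: float
    sex: str
    cmv_status: str

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise FormatError(f"age must be positive, got {self.age}")
        if self.sex not in SEXES:
            raise FormatError(f"sex must be one of {sorted(SEXES)}, got {self.sex!r}")
        if self.cmv_status not in CMV_STATES:
            raise FormatError(
                f"cmv_status must be one of {sorted(CMV_STATES)}, got {self.cmv_status!r}"
            )


def read_clone_table(
    path,
    dialect: str = "simple",
    subject_id: str | None = None,
    id_column: str = AIRR_ID_COLUMN,
    count_column: str = AIRR_COUNT_COLUMN,
) -> CloneTable:
    """Read a clone abundance table from a TSV file.

    ``dialect="simple"`` expects a two-column TSV (clone_id, templates) with
    a header.  ``dialect="airr"`` expects an AIRR-rearrangement-style TSV and
    reads the configurable identity and template/duplicate count columns.
    """
    if dialect not in {"simple", "airr"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    if df.shape[0] == 0:
        raise EmptyInputError(f"{path}: table has no rows")

    if dialect == "simple":
        if df.shape[1] < 2:
            raise FormatError(f"{path}: simple dialect needs two columns, got {df.shape[1]}")
        id_col, count_col = df.columns[:2]
    else:
        for col in (id_column, count_column):
            if col not in df.columns:
                raise FormatError(f"{path}: missing required column {col!r}")
        id_col, count_col = id_column, count_column

    ids = df[id_col].astype(str)
    counts_raw = df[count_col]
    counts = pd.to_numeric(counts_raw, errors="coerce")
    if counts.isna().any():
        row = int(counts.isna().idxmax())
        raise FormatError(f"{path}: non-numeric count {counts_raw.iloc[row]!r} at row {row}")
    if (counts < 1).any():
        row = int((counts < 1).idxmax())
        raise FormatError(
            f"{path}: clone {ids.iloc[row]!r} at row {row} has count {counts.iloc[row]}"
        )
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate clone_id {dup!r}")
    if not np.all(counts.to_numpy() == np.floor(counts.to_numpy())):
        raise FormatError(f"{path}: fractional template counts are rejected")

    sid = subject_id if subject_id is not None else _stem(path)
    return CloneTable(subject_id=sid, clone_ids=tuple(ids), templates=counts.to_numpy(np.int64))


def write_clone_table(table: CloneTable, path) -> None:
    """Write a clone table in the simple two-column TSV dialect."""
    pd.DataFrame({"clone_id": table.clone_ids, "templates": table.templates}).to_csv(
        path, sep="\t", index=False
    )


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def compute_metrics(table: CloneTable, k_list: list[int]) -> RepertoireMetrics:
    """Compute S, D, S_k and P_k for a clone table.

    S_k is the sum of the k largest counts; S_k = S (and P_k = 100) whenever
    k >= D.  The result is independent of clone ordering.  Ties at the rank-k
    boundary do not affect S_k (tied counts are equal); the selected clone
    set is made deterministic by breaking ties on clone_id.
    """
    if not k_list:
        raise ValueError("k_list must be non-empty")
    if any(k < 1 for k in k_list):
        raise ValueError("all k must be positive integers")
    counts = np.sort(table.templates)[::-1]
    S = int(counts.sum())
    D = int(counts.size)
    cumulative = np.concatenate([[0], np.cumsum(counts)])
    S_k = {int(k): int(cumulative[min(int(k), D)]) for k in k_list}
    P_k = {k: 100.0 * v / S for k, v in S_k.items()}
    return RepertoireMetrics(subject_id=table.subject_id, S=S, D=D, S_k=S_k, P_k=P_k)


def top_k_clone_set(table: CloneTable, k: int) -> tuple[str, ...]:
    """The k most abundant clones, count-descending, ties broken on clone_id."""
    order = sorted(range(table.n_clones), key=lambda i: (-table.templates[i], table.clone_ids[i]))
    return tuple(table.clone_ids[i] for i in order[: min(k, table.n_clones)])


# ---------------------------------------------------------------------------
# Cohort table: metrics joined with covariates, one row per subject.
# ---------------------------------------------------------------------------

def build_cohort_table(
    metrics: list[RepertoireMetrics], covariates: list[SubjectCovariates]
) -> pd.DataFrame:
    """Inner-join metrics and covariates on subject_id into a cohort table.

    Subjects missing covariates are excluded with a logged count.  Duplicate
    subject ids on either side are an error.
    """
    mids = [m.subject_id for m in metrics]
    cids = [c.subject_id for c in covariates]
    for name, ids in (("metrics", mids), ("covariates", cids)):
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate subject_id {dup!r} in {name}")

    mdf = pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "S": m.S,
                "D": m.D,
                **{f"S_{k}": v for k, v in sorted(m.S_k.items())},
                **{f"P_{k}": m.P_k[k] for k in sorted(m.P_k)},
            }
            for m in metrics
        ]
    )
    cdf = pd.DataFrame(
        [
            {"subject_id": c.subject_id, "age": c.age, "sex": c.sex, "cmv_status": c.cmv_status}
            for c in covariates
        ]
    )
    merged = mdf.merge(cdf, on="subject_id", how="inner")
    excluded = len(mdf) - len(merged)
    if excluded:
        logger.info("build_cohort_table: excluded %d subject(s) without covariates", excluded)
    return merged.reset_index(drop=True)


def write_cohort_table(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV (TSV if the path ends in .tsv)."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    cohort.to_csv(path, sep=sep, index=False)


def read_cohort_table(path) -> pd.DataFrame:
    """Read a cohort table; requires subject_id, S and D; extras are preserved.

    Unknown extra columns are kept as opaque covariates so externally
    deposited metric tables can be dropped in after a column mapping.
    """
    sep = "\t" if str(path).endswith(".tsv") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except FileNotFoundError:
        raise
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    for col in ("subject_id", "S", "D"):
        if col not in df.columns:
            raise FormatError(f"{path}: cohort table missing required column {col!r}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise FormatError(f"{path}: duplicate subject_id {dup!r}")
    if df[["S", "D"]].isna().any().any():
        raise FormatError(f"{path}: rows with missing S or D")
    df["subject_id"] = df["subject_id"].astype(str)
    return df
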
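"""Cohort data model and IO for the 88-patient OSCC morphometry study.

The package ships a hand-checked transcription of the study's per-patient
table (clinical covariates plus the five per-case nuclear-morphometry
parameters) as a CSV fixture; :func:`load_table1` returns it as a
:class:`Cohort`.  The same CSV dialect is used for user-supplied and
simulated cohorts, so everything downstream (group summaries, risk models,
the CLI) consumes one schema.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "Cohort",
    "CohortSchemaError",
    "CohortIntegrityError",
    "MORPHOMETRIC_FIELDS",
    "read_cohort",
    "write_cohort",
    "load_table1",
    "group_summary",
    "summarize_nodal",
]

#: The five per-case morphometric parameters, in reporting order.
MORPHOMETRIC_FIELDS = (
    "mean_nuclear_area",
    "mean_perimeter",
    "circular_rate",
    "aspect_ratio",
    "nacv",
)

SEXES = ("M", "F")
SITES = ("tongue", "upper_gingiva", "lower_gingiva", "buccal", "mouth_floor")
DIFFERENTIATIONS = ("well", "moderate", "poorly")
NEOADJUVANT = ("none", "C", "R", "C+R")
DISSECTIONS = ("RND", "SOHND", "SMND", "FND", "Biopsy")
NODE_LEVELS = ("I", "II", "III", "IV", "V")

#: Column order of the cohort CSV dialect.
CSV_COLUMNS = (
    "case_id",
    "age",
    "sex",
    "site",
    "differentiation",
    "neoadjuvant",
    "t_class",
    "n_class_clinical",
    "m_class",
    "dissection",
    "pn_status",
    "pn_class",
    "n_positive_nodes",
    "node_levels",
) + MORPHOMETRIC_FIELDS


class CohortSchemaError(ValueError):
    """The CSV header or a cell does not match the cohort schema."""


class CohortIntegrityError(ValueError):
    """Record-level invariant violated (duplicate ids, pN inconsistency...)."""


@dataclass(frozen=True)
class PatientRecord:
    """One cohort row: clinical covariates plus per-case morphometry.

    ``pn_status`` is the binary pathologic nodal outcome driving all risk
    statistics (1 = metastasis found in the dissected nodes); ``pn_class``
    keeps the finer nodal classification (0/1/2b/2c...) as an opaque label.
    """

    case_id: int
    age: float
    sex: str
    site: str
    differentiation: str
    neoadjuvant: str
    t_class: str
    n_class_clinical: str
    m_class: str
    dissection: str
    pn_status: int
    pn_class: str
    n_positive_nodes: int
    node_levels: tuple[str, ...]
    mean_nuclear_area: float
    mean_perimeter: float
    circular_rate: float
    aspect_ratio: float
    nacv: float

    def __post_init__(self) -> None:
        def _check(cond: bool, msg: str) -> None:
            if not cond:
                raise CohortIntegrityError(f"case {self.case_id}: {msg}")

        _check(self.sex in SEXES, f"sex {self.sex!r} not in {SEXES}")
        _check(self.site in SITES, f"site {self.site!r} not in {SITES}")
        _check(
            self.differentiation in DIFFERENTIATIONS,
            f"differentiation {self.differentiation!r} not in {DIFFERENTIATIONS}",
        )
        _check(
            self.neoadjuvant in NEOADJUVANT,
            f"neoadjuvant {self.neoadjuvant!r} not in {NEOADJUVANT}",
        )
        _check(
            self.dissection in DISSECTIONS,
            f"dissection {self.dissection!r} not in {DISSECTIONS}",
        )
        _check(self.pn_status in (0, 1), "pn_status must be 0 or 1")
        _check(all(l in NODE_LEVELS for l in self.node_levels), "bad node level")
        positive = self.pn_status == 1
        _check(
            positive == (self.n_positive_nodes >= 1) == (len(self.node_levels) > 0),
            "pn_status, n_positive_nodes and node_levels must agree",
        )
        for name in MORPHOMETRIC_FIELDS:
            _check(getattr(self, name) > 0, f"{name} must be strictly positive")
        _check(self.circular_rate <= 1.0, "circular_rate must be <= 1")
        _check(self.aspect_ratio >= 1.0, "aspect_ratio must be >= 1")


@dataclass
class Cohort:
    """Ordered collection of :class:`PatientRecord` with unique case ids."""

    records: list[PatientRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.case_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortIntegrityError(f"duplicate case_id(s): {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view; ``node_levels`` joined with '+', empty for pN-."""
        rows = []
        for r in self.records:
            d = {f.name: getattr(r, f.name) for f in dc_fields(r)}
            d["node_levels"] = "+".join(r.node_levels)
            rows.append(d)
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))

    def subset(self, pn_status: int) -> "Cohort":
        return Cohort(
            [r for r in self.records if r.pn_status == pn_status],
            provenance=f"{self.provenance} [pn_status={pn_status}]",
        )


def _parse_record(row: pd.Series, rownum: int) -> PatientRecord:
    def cell(col: str, conv, default=None):
        raw = row[col]
        if (raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "") and default is not None:
            return default
        try:
            return conv(raw)
        except (TypeError, ValueError) as exc:
            raise CohortSchemaError(
                f"row {rownum}, column {col!r}: cannot parse {raw!r}"
            ) from exc

    levels_raw = row["node_levels"]
    if levels_raw is None or (isinstance(levels_raw, float) and np.isnan(levels_raw)):
        levels_raw = ""
    levels = tuple(tok for tok in str(levels_raw).strip().split("+") if tok)

    return PatientRecord(
        case_id=cell("case_id", int),
        age=cell("age", float),
        sex=cell("sex", str),
        site=cell("site", str),
        differentiation=cell("differentiation", str),
        neoadjuvant=cell("neoadjuvant", str),
        t_class=cell("t_class", str),
        n_class_clinical=cell("n_class_clinical", str),
        m_class=cell("m_class", str),
        dissection=cell("dissection", str),
        pn_status=cell("pn_status", int),
        pn_class=cell("pn_class", str),
        n_positive_nodes=cell("n_positive_nodes", int),
        node_levels=levels,
        mean_nuclear_area=cell("mean_nuclear_area", float),
        mean_perimeter=cell("mean_perimeter", float),
        circular_rate=cell("circular_rate", float),
        aspect_ratio=cell("aspect_ratio", float),
        nacv=cell("nacv", float),
    )


def read_cohort(path: str | Path | io.IOBase) -> Cohort:
    """Read a cohort CSV, validating the header and every cell.

    Raises
    ------
    CohortSchemaError
        On a missing/extra column (naming it) or an unparseable cell
        (naming row and column).
    CohortIntegrityError
        On duplicate case ids or a record violating its invariants.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    got, want = list(df.columns), list(CSV_COLUMNS)
    if got != want:
        missing = [c for c in want if c not in got]
        extra = [c for c in got if c not in want]
        raise CohortSchemaError(
            f"bad cohort header: missing columns {missing}, unexpected columns {extra}"
        )
    records = [_parse_record(row, i + 2) for i, (_, row) in enumerate(df.iterrows())]
    name = getattr(path, "name", str(path))
    return Cohort(records, provenance=f"read from {name}")


def write_cohort(cohort: Cohort, path: str | Path | io.IOBase) -> None:
    """Write the cohort in the CSV dialect that :func:`read_cohort` reads."""
    cohort.to_frame().to_csv(path, index=False)


def load_table1() -> Cohort:
    """Load the bundled 88-patient reference cohort.

    The transcription reproduces the published per-patient table verbatim,
    including its printed row order and one literal value (an age of 34)
    that the accompanying text summarises as 35.
    """
    with resources.files("nucmorph.data").joinpath("table1.csv").open("r") as fh:
        cohort = read_cohort(fh)
    cohort.provenance = "bundled 88-patient OSCC reference cohort"
    return cohort


def group_summary(
    cohort: Cohort, field_name: str
) -> dict[str, tuple[float, float]]:
    """Mean and sample SD (n-1 denominator) of one morphometric field per pN group.

    Returns ``{"negative": (mean, sd), "positive": (mean, sd)}``.
    """
    if field_name not in MORPHOMETRIC_FIELDS and field_name != "age":
        raise ValueError(
            f"{field_name!r} is not a summarisable field ({MORPHOMETRIC_FIELDS} or 'age')"
        )
    out = {}
    for label, status in (("negative", 0), ("positive", 1)):
        vals = np.array(
            [getattr(r, field_name) for r in cohort if r.pn_status == status], float
        )
        if vals.size < 2:
            raise CohortIntegrityError(
                f"pN-{label} group has {vals.size} record(s); SD undefined"
            )
        out[label] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def summarize_nodal(cohort: Cohort) -> dict[str, pd.Series]:
    """Nodal summaries over the pN-positive subset.

    Returns counts by nodal classification label, by number of positive
    nodes, and by the sorted '+'-joined level pattern.  An all-negative
    cohort yields three empty tables.
    """
    pos = [r for r in cohort if r.pn_status == 1]
    level_order = {lvl: i for i, lvl in enumerate(NODE_LEVELS)}

    def pattern(r: PatientRecord) -> str:
        return "+".join(sorted(set(r.node_levels), key=level_order.__getitem__))

    pn_class = pd.Series([r.pn_class for r in pos], dtype=object).value_counts().sort_index()
    n_nodes = pd.Series([r.n_positive_nodes for r in pos], dtype="int64").value_counts().sort_index()
    levels = pd.Series([pattern(r) for r in pos], dtype=object).value_counts().sort_index()
    return {
        "pn_class": pn_class.rename("count"),
        "n_positive_nodes": n_nodes.rename("count"),
        "node_levels": levels.rename("count"),
    }
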
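"""Cohort metadata and GST panel tables.

Reads, validates and summarizes the per-tumor clinical table and the
four-gene GST panel (integer copy numbers plus GAPDH-relative mRNA levels
on the x1000 scale), and parses the cytoband-interval loss descriptors
used to annotate chr1p / chr22q somatic deletions.

The two tables transcribed from the study's 16-tumor 1p-22q-NF2- meningioma
cohort ship as package fixtures and can be loaded with
:func:`load_cohort_fixture` and :func:`load_gst_panel_fixture`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Literal, Union

import numpy as np
import pandas as pd

__all__ = [
    "PANEL_GENES",
    "CohortTable",
    "GstPanelTable",
    "CytobandInterval",
    "CohortSummary",
    "SchemaError",
    "CytobandParseError",
    "read_cohort_table",
    "write_cohort_table",
    "read_gst_panel",
    "write_gst_panel",
    "load_cohort_fixture",
    "load_gst_panel_fixture",
    "parse_cytoband_interval",
    "interval_covers_locus",
    "summarize_cohort",
    "round_half_away",
]

#: Genes assayed on the qPCR copy-number / expression panel.
PANEL_GENES = ("GSTM1", "GSTM2", "GSTT1", "GSTT4")

_COHORT_REQUIRED = [
    "sample_id",
    "patient_id",
    "group",
    "sex",
    "age_years",
    "who_grade",
    "histology",
    "ki67_text",
    "rin",
    "mutated_genes",
    "chr22_loss",
    "chr1p_loss",
]

_PANEL_REQUIRED = ["sample_id"] + [
    f"{g}_{suffix}" for g in PANEL_GENES for suffix in ("copy", "expr_x1000")
]


class SchemaError(ValueError):
    """A table failed structural or domain validation."""


class CytobandParseError(ValueError):
    """A copy-number loss descriptor did not match any known dialect."""

    def __init__(self, text: str, reason: str = "unrecognized dialect"):
        self.text = text
        super().__init__(f"{reason}: {text!r}")


# ---------------------------------------------------------------------------
# cytoband order lists
#
# Static telomere->centromere band orders for the two arms the panel genes
# live on (chr1p for GSTM1/GSTM2 at 1p13.3, chr22q for GSTT1/GSTT4 at
# 22q11.23), restricted to bands that occur in the cohort's descriptors plus
# the two gene loci. Any band outside these lists yields coverage "unknown"
# rather than a guess.
# ---------------------------------------------------------------------------

CHR1P_BAND_ORDER = (
    "1p36.33",
    "1p36.32",
    "1p32.2",
    "1p31.3",
    "1p31.1",
    "1p22.1",
    "1p21.3",
    "1p21.1",
    "1p13.3",
    "1p13.1",
    "1p12",
    "1p11.2",
)

# q arms are conventionally written centromere-first; the tuple below is
# telomere->centromere to mirror CHR1P_BAND_ORDER.
CHR22Q_BAND_ORDER = (
    "22q13.33",
    "22q13.2",
    "22q12.2",
    "22q12.1",
    "22q11.23",
    "22q11.21",
    "22q11.1",
)

_BAND_ORDERS = {("1", "p"): CHR1P_BAND_ORDER, ("22", "q"): CHR22Q_BAND_ORDER}


@dataclass(frozen=True)
class CytobandInterval:
    """A contiguous chromosome-arm segment lost in a tumor.

    ``start_band``/``end_band`` are stored exactly as written in the source
    descriptor; coverage queries are order-insensitive. ``whole_arm`` marks
    whole-chromosome descriptors such as "Loss of chr 22".
    """

    chromosome: str
    arm: Literal["p", "q"] | None
    start_band: str | None
    end_band: str | None
    whole_arm: bool = False

    def format(self) -> str:
        if self.whole_arm:
            if self.arm:
                return f"Loss of most of {self.chromosome}{self.arm}"
            return f"Loss of chr {self.chromosome}"
        return f"Loss of {self.start_band}{self.end_band.replace(self.chromosome, '', 1)}"


_WHOLE_CHR_RE = re.compile(
    r"^loss(?:\s+of)?\s+(?:most\s+of\s+)?ch\s*r?\s*(\d{1,2}|[XY])\s*$", re.IGNORECASE
)
_BAND_PAIR_RE = re.compile(
    r"^loss(?:\s+of)?\s+(\d{1,2}|[XY])([pq])(\d+(?:\.\d+)?)"
    r"(?:([pq]))?(\d+(?:\.\d+)?)\s*$",
    re.IGNORECASE,
)
_WHOLE_ARM_RE = re.compile(
    r"^loss(?:\s+of)?\s+(?:most\s+of\s+)?(\d{1,2}|[XY])([pq])\s*$", re.IGNORECASE
)


def parse_cytoband_interval(text: str) -> CytobandInterval:
    """Parse a copy-number loss descriptor into a :class:`CytobandInterval`.

    Handles the dialects found in the cohort table: ``"Loss of chr 22"``
    (whole chromosome, tolerant of spacing slips like ``"ch r22"``),
    ``"Loss of 1p36.33p21.3"`` (band interval), ``"Loss of most of 1p"``
    (whole arm). Parenthetical annotations and secondary comma-separated
    clauses are ignored. Raises :class:`CytobandParseError` otherwise;
    callers may catch it and mark the descriptor unparseable instead of
    aborting.
    """
    if not isinstance(text, str) or not text.strip():
        raise CytobandParseError(str(text), "empty descriptor")
    clause = text.split(",")[0]
    clause = re.sub(r"\([^)]*\)", "", clause).strip()

    m = _WHOLE_CHR_RE.match(clause)
    if m:
        return CytobandInterval(m.group(1), None, None, None, whole_arm=True)
    m = _WHOLE_ARM_RE.match(clause)
    if m:
        return CytobandInterval(m.group(1), m.group(2).lower(), None, None, whole_arm=True)
    m = _BAND_PAIR_RE.match(clause)
    if m:
        chrom, arm, b1, arm2, b2 = m.groups()
        arm = arm.lower()
        arm2 = (arm2 or arm).lower()
        if arm2 != arm:
            raise CytobandParseError(text, "interval spans both arms")
        return CytobandInterval(chrom, arm, f"{chrom}{arm}{b1}", f"{chrom}{arm}{b2}")
    raise CytobandParseError(text)


def interval_covers_locus(
    interval: CytobandInterval, locus_band: str
) -> bool | Literal["unknown"]:
    """Whether a loss interval covers a locus band.

    Returns True/False by position lookup in the shipped band-order list for
    the interval's arm, or the string ``"unknown"`` when any involved band is
    absent from the list. Whole-chromosome / whole-arm losses cover every
    band of the arm. Raises ``ValueError`` on a chromosome mismatch.
    """
    m = re.match(r"^(\d{1,2}|[XY])([pq])", locus_band)
    if not m:
        raise ValueError(f"malformed locus band: {locus_band!r}")
    chrom, arm = m.group(1), m.group(2)
    if chrom != interval.chromosome:
        raise ValueError(
            f"chromosome mismatch: interval on chr{interval.chromosome}, "
            f"locus on chr{chrom}"
        )
    if interval.whole_arm:
        if interval.arm is None or interval.arm == arm:
            return True
        return False
    if interval.arm != arm:
        return False
    order = _BAND_ORDERS.get((chrom, arm))
    if order is None or locus_band not in order:
        return "unknown"
    if interval.start_band not in order or interval.end_band not in order:
        return "unknown"
    i, j = order.index(interval.start_band), order.index(interval.end_band)
    lo, hi = min(i, j), max(i, j)
    return lo <= order.index(locus_band) <= hi


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Validated per-tumor clinical/cytogenetic metadata."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"cohort table missing required column(s): {missing}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise SchemaError(f"duplicate sample_id: {dupes}")
        if len(df):
            if not df["group"].isin(["primary", "recurrent"]).all():
                bad = sorted(set(df["group"]) - {"primary", "recurrent"})
                raise SchemaError(f"group must be primary/recurrent, got {bad}")
            if (df["age_years"] <= 0).any():
                raise SchemaError("age_years must be positive")
            if ((df["rin"] <= 0) | (df["rin"] > 10)).any():
                raise SchemaError("rin must lie in (0, 10]")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def ki67_bound(self, sample_id: str) -> tuple[float, bool]:
        """Numeric Ki-67 value plus a flag for '<' (upper-bound) entries.

        Stored for completeness only; no downstream computation uses it.
        """
        text = str(self.data.set_index("sample_id").loc[sample_id, "ki67_text"])
        is_bound = text.startswith("<")
        return float(text.lstrip("<")), is_bound


@dataclass
class GstPanelTable:
    """Per-tumor integer copy numbers and relative expression (x1000) for
    the four panel genes."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _PANEL_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"GST panel missing required column(s): {missing}")
        if df["sample_id"].duplicated().any():
            raise SchemaError("duplicate sample_id in GST panel")
        for g in PANEL_GENES:
            copies = df[f"{g}_copy"]
            if not np.issubdtype(copies.dtype, np.integer):
                if not (copies.dropna() == copies.dropna().astype(int)).all():
                    raise SchemaError(f"{g}_copy must be integer")
            if len(df) and (copies < 0).any():
                raise SchemaError(f"{g}_copy must be >= 0")
            expr = df[f"{g}_expr_x1000"]
            if len(df) and (expr < 0).any():
                raise SchemaError(f"{g}_expr_x1000 must be >= 0")

    def __len__(self) -> int:
        return len(self.data)

    def copies(self, gene: str) -> pd.Series:
        return self.data.set_index("sample_id")[f"{gene}_copy"]

    def expression(self, gene: str) -> pd.Series:
        return self.data.set_index("sample_id")[f"{gene}_expr_x1000"]


def _read_table(source: Union[str, Path, IO[str]]) -> pd.DataFrame:
    # sniff tab vs comma from the header line; fixtures are TSV
    df = pd.read_csv(source, sep=None, engine="python", dtype=str, keep_default_na=False)
    return df


def read_cohort_table(source: Union[str, Path, IO[str]]) -> CohortTable:
    """Read a delimited (tab or comma) cohort metadata table."""
    df = _read_table(source)
    missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing required column(s): {missing}")
    if len(df):
        try:
            df["age_years"] = df["age_years"].astype(int)
            df["who_grade"] = df["who_grade"].astype(int)
            df["rin"] = df["rin"].astype(float)
        except ValueError as exc:
            raise SchemaError(f"non-numeric value in cohort table: {exc}") from exc
    else:
        df = df.astype(
            {"age_years": int, "who_grade": int, "rin": float}, errors="ignore"
        )
    return CohortTable(df)


def write_cohort_table(cohort: CohortTable, path: Union[str, Path]) -> None:
    df = cohort.data.copy()
    df["rin"] = df["rin"].map(lambda v: format(float(v), ".1f"))
    df.to_csv(path, sep="\t", index=False)


def read_gst_panel(source: Union[str, Path, IO[str]]) -> GstPanelTable:
    """Read a delimited GST panel table (copy + expression per gene)."""
    df = _read_table(source)
    missing = [c for c in _PANEL_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"GST panel missing required column(s): {missing}")
    for g in PANEL_GENES:
        try:
            df[f"{g}_copy"] = df[f"{g}_copy"].astype(int)
        except ValueError as exc:
            raise SchemaError(f"non-integer copy number for {g}: {exc}") from exc
        try:
            df[f"{g}_expr_x1000"] = df[f"{g}_expr_x1000"].astype(float)
        except ValueError as exc:
            raise SchemaError(f"non-numeric expression for {g}: {exc}") from exc
    return GstPanelTable(df)


def write_gst_panel(panel: GstPanelTable, path: Union[str, Path]) -> None:
    df = panel.data.copy()
    for g in PANEL_GENES:
        df[f"{g}_expr_x1000"] = df[f"{g}_expr_x1000"].map(lambda v: format(v, ".2f"))
    df.to_csv(path, sep="\t", index=False)


def _fixture_path(name: str):
    return resources.files("gstnull.data").joinpath(name)


def load_cohort_fixture() -> CohortTable:
    """The packaged 16-tumor clinical table (12 primary, 4 recurrent)."""
    with resources.as_file(_fixture_path("table1_cohort.tsv")) as p:
        return read_cohort_table(p)


def load_gst_panel_fixture() -> GstPanelTable:
    """The packaged 16-tumor GST copy-number / expression panel."""
    with resources.as_file(_fixture_path("table2_gst_panel.tsv")) as p:
        return read_gst_panel(p)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (9.15 -> 9.2), unlike banker's rounding."""
    x = round(x, ndigits + 9)  # absorb binary-float noise below the half
    factor = 10**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass
class CohortSummary:
    """Headline cohort statistics (medians are mean-of-central-order-stats)."""

    n_total: int
    n_primary: int
    n_recurrent: int
    median_age_recurrent: float | None
    median_rin: float
    median_rin_rounded: float
    counts_by_grade: dict[int, int] = field(default_factory=dict)
    counts_by_sex: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["counts_by_grade"] = {str(k): v for k, v in self.counts_by_grade.items()}
        return json.dumps(d, indent=2)


def summarize_cohort(cohort: CohortTable) -> CohortSummary:
    """Cohort counts plus median recurrent age and median RIN.

    Medians use the standard mean-of-two-central-order-statistics rule for
    even n; ``median_rin_rounded`` additionally applies one-decimal
    round-half-away-from-zero.
    """
    df = cohort.data
    if df.empty:
        raise ValueError("cannot summarize an empty cohort")
    recurrent = df[df["group"] == "recurrent"]
    median_age = float(np.median(recurrent["age_years"])) if len(recurrent) else None
    median_rin = float(np.median(df["rin"]))
    return CohortSummary(
        n_total=len(df),
        n_primary=int((df["group"] == "primary").sum()),
        n_recurrent=len(recurrent),
        median_age_recurrent=median_age,
        median_rin=median_rin,
        median_rin_rounded=round_half_away(median_rin, 1),
        counts_by_grade={int(k): int(v) for k, v in df["who_grade"].value_counts().items()},
        counts_by_sex={str(k): int(v) for k, v in df["sex"].value_counts().items()},
    )
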
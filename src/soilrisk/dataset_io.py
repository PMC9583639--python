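"""Reading, validation and descriptive summarization of PTE surface-soil
concentration datasets.

A dataset is a flat table of single measurements: one element, one
concentration in mg/kg dry soil, a province label, and a site category.
This module reads such tables from CSV, computes grouped descriptive
statistics (mean, median, 25th/75th/95th percentile, coefficient of
variation), compares means against regulatory maximum contaminant levels,
and splits total chromium into its trivalent and hexavalent forms.

Conventions (fixed so results are bit-stable):

* percentiles use linear interpolation between order statistics
  (``numpy.percentile`` default);
* the coefficient of variation uses the sample standard deviation
  (``ddof=1``); a single observation has CV 0; a zero mean leaves the CV
  undefined (``None``);
* records flagged as censored (below detection limit) carry the detection
  limit in the concentration column and are substituted with limit/2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from soilrisk.errors import DomainError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Elements covered by the compiled dataset.
ELEMENTS: tuple[str, ...] = (
    "Al", "As", "Cd", "Co", "Cr", "Cu", "Fe", "Mn", "Ni", "Pb", "Zn",
)

#: Recognized site categories; unknown labels normalize to "uncategorized".
SITE_CATEGORIES: tuple[str, ...] = (
    "urban", "suburban", "rural", "industrial", "agricultural", "uncategorized",
)

#: Turkish soil-pollution regulation maximum contaminant levels, mg/kg.
#: Al, Fe and Mn have no regulatory limit (crustal elements).
TURKISH_LIMITS: dict[str, float] = {
    "As": 20.0,
    "Ni": 30.0,
    "Pb": 50.0,
    "Cr": 100.0,
    "Cd": 1.0,
    "Cu": 50.0,
    "Zn": 150.0,
    "Co": 20.0,
}

#: Default CSV column names; a ``dialect`` mapping may override them.
DEFAULT_DIALECT: dict[str, str] = {
    "element": "element",
    "concentration": "concentration_mg_kg",
    "province": "province",
    "site_category": "site_category",
    "source_id": "source_id",
}

_REQUIRED_FIELDS = ("element", "concentration")


@dataclass(frozen=True)
class ConcentrationRecord:
    """One measured PTE concentration at a site.

    Parameters
    ----------
    element : str
        Element symbol, one of :data:`ELEMENTS`.
    concentration : float
        Mass fraction in mg/kg dry soil; nonnegative and finite.
    province : str
        Free-text administrative label.
    site_category : str
        One of :data:`SITE_CATEGORIES`.
    source_id : str
        Citation key of the originating study.
    censored : bool
        True when the value was below the detection limit and has been
        substituted with limit/2.
    """

    element: str
    concentration: float
    province: str = ""
    site_category: str = "uncategorized"
    source_id: str = ""
    censored: bool = False

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValidationError(f"unsupported element {self.element!r}")
        c = self.concentration
        if not (isinstance(c, (int, float)) and math.isfinite(c) and c >= 0):
            raise ValidationError(
                f"concentration must be finite and >= 0, got {c!r}"
            )
        if self.site_category not in SITE_CATEGORIES:
            raise ValidationError(
                f"unrecognized site category {self.site_category!r}"
            )


@dataclass(frozen=True)
class DescriptiveSummary:
    """Descriptive statistics of one group of concentration records.

    All statistics are in mg/kg except ``cv`` (unitless). ``cv`` is ``None``
    when the group mean is zero (undefined).
    """

    n: int
    mean: float
    median: float
    p25: float
    p75: float
    p95: float
    cv: float | None

    def __post_init__(self) -> None:
        if not (self.p25 <= self.median <= self.p75 <= self.p95):
            raise ValidationError("percentiles must be monotone")
        if self.cv is not None and self.cv < 0:
            raise ValidationError("cv must be >= 0")


def normalize_site_category(label: str) -> str:
    """Map a free-text site label onto the supported category set.

    Matching is case-insensitive; "noncategorized"/"none"/empty map to
    "uncategorized"; anything unrecognized also maps there with a warning.
    """
    cleaned = str(label).strip().lower()
    if cleaned in SITE_CATEGORIES:
        return cleaned
    if cleaned in ("", "none", "nan", "noncategorized", "non-categorized"):
        return "uncategorized"
    logger.warning("unrecognized site category %r mapped to 'uncategorized'", label)
    return "uncategorized"


def read_concentration_table(
    path,
    dialect: Mapping[str, str] | None = None,
) -> list[ConcentrationRecord]:
    """Read a concentration CSV into validated records.

    Parameters
    ----------
    path : path-like
        CSV file with a header row; UTF-8; "." decimal separator.
    dialect : mapping, optional
        Maps canonical field names (``element``, ``concentration``,
        ``province``, ``site_category``, ``source_id``, optionally
        ``censored``) onto the file's column names. Defaults to
        :data:`DEFAULT_DIALECT`.

    Returns
    -------
    list of ConcentrationRecord

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        If any row has a negative, non-numeric or non-finite concentration
        or an unsupported element; the error lists offending line numbers
        (header is line 1).
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)

    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for field in _REQUIRED_FIELDS:
        if cols[field] not in frame.columns:
            raise SchemaError(
                f"required column {cols[field]!r} (field {field!r}) missing; "
                f"found {list(frame.columns)}"
            )

    if frame.empty:
        logger.warning("concentration table %s contains a header only", path)
        return []

    censored_col = cols.get("censored", "censored")
    has_censored = censored_col in frame.columns

    records: list[ConcentrationRecord] = []
    bad_rows: list[int] = []
    messages: list[str] = []
    for idx, row in frame.iterrows():
        line_no = int(idx) + 2  # header is line 1
        element = str(row[cols["element"]]).strip()
        raw_conc = str(row[cols["concentration"]]).strip()
        try:
            conc = float(raw_conc)
        except ValueError:
            bad_rows.append(line_no)
            messages.append(f"line {line_no}: non-numeric concentration {raw_conc!r}")
            continue
        censored = False
        if has_censored:
            censored = str(row[censored_col]).strip().lower() in ("1", "true", "yes")
            if censored:
                # value in the table is the detection limit; substitute limit/2
                conc = conc / 2.0
        try:
            records.append(
                ConcentrationRecord(
                    element=element,
                    concentration=conc,
                    province=str(row.get(cols["province"], "")).strip(),
                    site_category=normalize_site_category(
                        row.get(cols["site_category"], "")
                    ),
                    source_id=str(row.get(cols["source_id"], "")).strip(),
                    censored=censored,
                )
            )
        except ValidationError as exc:
            bad_rows.append(line_no)
            messages.append(f"line {line_no}: {exc}")

    if bad_rows:
        raise ValidationError(
            "invalid rows in concentration table: " + "; ".join(messages),
            rows=bad_rows,
        )
    return records


def _summary_of(values: np.ndarray) -> DescriptiveSummary:
    n = int(values.size)
    mean = float(np.mean(values))
    p25, median, p75, p95 = (
        float(v) for v in np.percentile(values, [25, 50, 75, 95])
    )
    if mean == 0.0:
        cv: float | None = None
    elif n == 1:
        cv = 0.0
    else:
        cv = float(np.std(values, ddof=1) / mean)
    return DescriptiveSummary(
        n=n, mean=mean, median=median, p25=p25, p75=p75, p95=p95, cv=cv
    )


def summarize(
    records: Iterable[ConcentrationRecord],
    group_by: Sequence[str] = (),
) -> dict[tuple, DescriptiveSummary]:
    """Grouped descriptive statistics of concentration records.

    Parameters
    ----------
    records : iterable of ConcentrationRecord
    group_by : sequence drawn from {"element", "site_category", "province"}
        Grouping keys; empty means one pooled group.

    Returns
    -------
    dict mapping group-key tuple -> DescriptiveSummary
        With ``group_by=()`` the single key is the empty tuple.
    """
    allowed = {"element", "site_category", "province"}
    keys = tuple(group_by)
    unknown = set(keys) - allowed
    if unknown:
        raise DomainError(f"unsupported group_by fields: {sorted(unknown)}")

    records = list(records)
    if not records:
        logger.warning("summarize called with no records")
        return {}

    groups: dict[tuple, list[float]] = {}
    for rec in records:
        key = tuple(getattr(rec, k) for k in keys)
        groups.setdefault(key, []).append(rec.concentration)

    return {
        key: _summary_of(np.asarray(vals, dtype=float))
        for key, vals in sorted(groups.items())
    }


def summaries_to_frame(
    summaries: Mapping[tuple, DescriptiveSummary],
    group_by: Sequence[str] = (),
) -> pd.DataFrame:
    """Flatten a summary mapping into a DataFrame (group keys + statistics)."""
    rows = []
    for key, s in summaries.items():
        row = dict(zip(group_by, key))
        row.update(
            n=s.n, mean=s.mean, median=s.median,
            p25=s.p25, p75=s.p75, p95=s.p95, cv=s.cv,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def exceedance_ratio(
    summary_mean: float,
    limits: Mapping[str, float] | None = None,
    element: str = "",
) -> float:
    """Ratio of a mean concentration to the regulatory limit for an element.

    A ratio above 1 means the mean exceeds the maximum contaminant level.

    Raises
    ------
    KeyError
        If the element has no limit in ``limits``.
    DomainError
        If the mean is negative or the limit nonpositive.
    """
    if limits is None:
        limits = TURKISH_LIMITS
    if element not in limits:
        raise KeyError(f"no regulation limit for element {element!r}")
    limit = limits[element]
    if limit <= 0:
        raise DomainError(f"regulation limit must be > 0, got {limit}")
    if summary_mean < 0:
        raise DomainError(f"mean concentration must be >= 0, got {summary_mean}")
    return summary_mean / limit


def speciate_chromium(
    total_cr: float, fraction_cr6: float = 0.20
) -> tuple[float, float]:
    """Split total chromium into Cr(III) and Cr(VI) fractions.

    Soil chromium partitions into trivalent and hexavalent forms, roughly
    80% and 20% of the total; only the hexavalent form is carcinogenic by
    ingestion. Mass is conserved by construction: ``cr3 = total - cr6``,
    so the two outputs reconstruct the input to within one rounding.

    Returns
    -------
    (cr3, cr6) : tuple of float, mg/kg
    """
    if not 0.0 <= fraction_cr6 <= 1.0:
        raise DomainError(f"fraction_cr6 must be in [0, 1], got {fraction_cr6}")
    if total_cr < 0 or not math.isfinite(total_cr):
        raise DomainError(f"total_cr must be finite and >= 0, got {total_cr}")
    cr6 = total_cr * fraction_cr6
    return total_cr - cr6, cr6


def substitute_censored(
    record: ConcentrationRecord, detection_limit: float
) -> ConcentrationRecord:
    """Return a copy of a record with a below-detection value set to limit/2."""
    if detection_limit <= 0:
        raise DomainError("detection limit must be > 0")
    return replace(record, concentration=detection_limit / 2.0, censored=True)
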
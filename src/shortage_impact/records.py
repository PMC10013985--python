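"""Shortage-registry data model, validation, episode logic and CSV I/O.

A *shortage* is a marketing authorisation for human use that is nationally
unavailable for at least two weeks.  Each :class:`ShortageRecord` holds one
shortage episode together with every raw attribute needed to rate the five
patient-impact elements (alternative product, disease, susceptibility,
costs, number of patients).

Conventions
-----------
* CSV: comma-delimited (configurable), UTF-8, ISO-8601 dates, empty field
  for missing values, booleans as ``true``/``false``.
* Duration counts both the start and the end date, i.e.
  ``(end_date - start_date).days + 1``; an episode running Jan 1 – Jan 14
  spans 14 days and is therefore eligible.
* Ongoing shortages (no ``end_date``) are retained by the eligibility
  filter: impact is rated at the start of the shortage, so an unresolved
  episode is as rateable as a closed one.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, fields, replace
from datetime import date, timedelta
from typing import Iterable, Iterator, Optional, Union

import pandas as pd

from .errors import RowValidationError, SchemaError

log = logging.getLogger(__name__)

#: Routes of administration (EDQM standard-terms groups used for shortage
#: characterisation).
ROUTES = frozenset(
    {"oral", "parenteral", "nasal_inhalation", "cutaneous", "rectal",
     "ocular", "other"}
)

#: Proposed-solution ladder for the alternative-product element.
SOLUTION_CATEGORIES = frozenset(
    {"generic_substitution", "therapeutic_substitution",
     "unlicensed_product", "no_therapy"}
)

#: Categorical disease-severity grades (numeric disability weights in
#: [0, 1] are accepted as an alternative).
SEVERITIES = frozenset({"mild", "moderate", "severe", "multi_class"})

#: First-level WHO ATC anatomical main groups.
ATC_CLASSES = frozenset("ABCDGHJLMNPRSV")

#: Trust-in-alternative evidence flags.
TRUST_FLAGS = ("patient_contact_notes", "media_attention",
               "patient_forum_reports")

#: Product types carrying a regular marketing authorisation.  Records with
#: any other ``product_type`` (parallel import, homeopathic, herbal,
#: unregistered preparations ...) are dropped by :func:`filter_eligible`.
MA_PRODUCT_TYPES = frozenset({"ma", "registered", "authorized"})

ELEMENTS = ("alternative_product", "disease", "susceptibility", "costs",
            "n_patients")

#: Optional pre-assigned element-rating columns (bypass mode: a registry
#: that was rated by hand can carry the ratings directly).
RATING_COLUMNS = tuple(f"rating_{e}" for e in ELEMENTS)

MANDATORY_COLUMNS = ("shortage_id", "product_name", "atc_code", "route",
                     "originator", "start_date")

OPTIONAL_COLUMNS = (
    "end_date", "solution_category", "disease_severity", "age_min",
    "age_max", "patient_contact_notes", "media_attention",
    "patient_forum_reports", "price_original", "price_alternative",
    "users_prior_year", "hospital_product", "orphan_indication",
    "product_type", *RATING_COLUMNS,
)

ALL_COLUMNS = MANDATORY_COLUMNS + OPTIONAL_COLUMNS


@dataclass
class ShortageRecord:
    """One shortage episode with the raw inputs of the five element raters.

    Only the identity/characterisation fields are mandatory; every rating
    input may be absent, in which case the corresponding rater raises a
    :class:`~shortage_impact.errors.RatingError` when it is actually
    needed.  ``rating_*`` fields carry pre-assigned element ratings for
    registries that were rated externally.
    """

    shortage_id: str
    product_name: str
    atc_code: str
    route: str
    originator: bool
    start_date: date
    end_date: Optional[date] = None
    solution_category: Optional[str] = None
    disease_severity: Optional[Union[str, float]] = None
    age_min: Optional[float] = None
    age_max: Optional[float] = None
    patient_contact_notes: bool = False
    media_attention: bool = False
    patient_forum_reports: bool = False
    price_original: Optional[float] = None
    price_alternative: Optional[float] = None
    users_prior_year: Optional[int] = None
    hospital_product: bool = False
    orphan_indication: bool = False
    product_type: Optional[str] = None
    rating_alternative_product: Optional[int] = None
    rating_disease: Optional[int] = None
    rating_susceptibility: Optional[int] = None
    rating_costs: Optional[int] = None
    rating_n_patients: Optional[int] = None

    def __post_init__(self) -> None:
        problems = list(self._violations())
        if problems:
            raise ValueError("; ".join(problems))

    def _violations(self) -> Iterator[str]:
        if not self.shortage_id:
            yield "shortage_id is empty"
        if not self.atc_code or self.atc_code[0].upper() not in ATC_CLASSES:
            yield (f"atc_code {self.atc_code!r}: first letter must be one of "
                   f"{''.join(sorted(ATC_CLASSES))}")
        if self.route not in ROUTES:
            yield (f"route {self.route!r}: allowed values are "
                   f"{sorted(ROUTES)}")
        if self.end_date is not None and self.start_date > self.end_date:
            yield f"start_date {self.start_date} after end_date {self.end_date}"
        if (self.solution_category is not None
                and self.solution_category not in SOLUTION_CATEGORIES):
            yield (f"solution_category {self.solution_category!r}: allowed "
                   f"values are {sorted(SOLUTION_CATEGORIES)}")
        if self.disease_severity is not None:
            if isinstance(self.disease_severity, str):
                if self.disease_severity not in SEVERITIES:
                    yield (f"disease_severity {self.disease_severity!r}: "
                           f"allowed values are {sorted(SEVERITIES)} or a "
                           f"disability weight in [0, 1]")
            elif not 0.0 <= float(self.disease_severity) <= 1.0:
                yield (f"disability weight {self.disease_severity} outside "
                       f"[0, 1]")
        for name in ("age_min", "age_max"):
            v = getattr(self, name)
            if v is not None and v < 0:
                yield f"{name} {v} is negative"
        if (self.age_min is not None and self.age_max is not None
                and self.age_min > self.age_max):
            yield f"age_min {self.age_min} exceeds age_max {self.age_max}"
        for name in ("price_original", "price_alternative"):
            v = getattr(self, name)
            if v is not None and v < 0:
                yield f"{name} {v} is negative"
        if self.users_prior_year is not None and self.users_prior_year < 0:
            yield f"users_prior_year {self.users_prior_year} is negative"
        for name in RATING_COLUMNS:
            v = getattr(self, name)
            if v is not None and v not in (1, 2, 3):
                yield f"{name} {v}: ratings must be 1, 2 or 3"

    @property
    def duration_days(self) -> Optional[int]:
        """Inclusive unavailability span in days; None while ongoing."""
        if self.end_date is None:
            return None
        return (self.end_date - self.start_date).days + 1

    @property
    def atc_class(self) -> str:
        """First-level ATC anatomical main group (single letter)."""
        return self.atc_code[0].upper()

    @property
    def year(self) -> int:
        """Calendar year the shortage started (reporting convention)."""
        return self.start_date.year

    @property
    def trust_flags(self) -> frozenset:
        return frozenset(f for f in TRUST_FLAGS if getattr(self, f))

    @property
    def prerated(self) -> bool:
        """True when all five element ratings were supplied externally."""
        return all(getattr(self, c) is not None for c in RATING_COLUMNS)


@dataclass
class Cohort:
    """An ordered collection of shortage records with unique ids."""

    records: list[ShortageRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.shortage_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = sorted({i for i in ids if i in seen or seen.add(i)})
            raise ValueError(f"duplicate shortage_id(s): {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ShortageRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ShortageRecord:
        return self.records[i]

    def to_frame(self) -> pd.DataFrame:
        """Registry as a DataFrame, one column per schema field."""
        rows = []
        for r in self.records:
            rows.append({f.name: getattr(r, f.name)
                         for f in fields(ShortageRecord)})
        df = pd.DataFrame(rows, columns=list(ALL_COLUMNS))
        if rows:
            df["year"] = [r.year for r in self.records]
            df["atc_class"] = [r.atc_class for r in self.records]
        else:
            df["year"] = pd.Series(dtype=int)
            df["atc_class"] = pd.Series(dtype=str)
        return df


# ---------------------------------------------------------------------------
# Field parsing (CSV cell -> typed value)

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", ""}


def _parse_bool(text: str, column: str) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"{column} {text!r}: expected true/false")


def _parse_date(text: str, column: str) -> Optional[date]:
    t = text.strip()
    if not t:
        return None
    try:
        return date.fromisoformat(t)
    except ValueError as exc:
        raise ValueError(f"{column} {text!r}: expected ISO date "
                         f"(YYYY-MM-DD)") from exc


def _parse_float(text: str, column: str) -> Optional[float]:
    t = text.strip()
    if not t:
        return None
    try:
        return float(t)
    except ValueError as exc:
        raise ValueError(f"{column} {text!r}: expected a number") from exc


def _parse_int(text: str, column: str) -> Optional[int]:
    v = _parse_float(text, column)
    if v is None:
        return None
    if not float(v).is_integer():
        raise ValueError(f"{column} {text!r}: expected an integer")
    return int(v)


def _parse_severity(text: str) -> Optional[Union[str, float]]:
    t = text.strip()
    if not t:
        return None
    if t in SEVERITIES:
        return t
    try:
        return float(t)
    except ValueError as exc:
        raise ValueError(
            f"disease_severity {text!r}: allowed values are "
            f"{sorted(SEVERITIES)} or a disability weight in [0, 1]"
        ) from exc


def _record_from_row(row: dict) -> ShortageRecord:
    def get(col: str) -> str:
        return row.get(col, "") or ""

    kwargs: dict = {
        "shortage_id": get("shortage_id").strip(),
        "product_name": get("product_name").strip(),
        "atc_code": get("atc_code").strip(),
        "route": get("route").strip(),
        "originator": _parse_bool(get("originator"), "originator"),
        "start_date": _parse_date(get("start_date"), "start_date"),
        "end_date": _parse_date(get("end_date"), "end_date"),
        "disease_severity": _parse_severity(get("disease_severity")),
        "age_min": _parse_float(get("age_min"), "age_min"),
        "age_max": _parse_float(get("age_max"), "age_max"),
        "price_original": _parse_float(get("price_original"),
                                       "price_original"),
        "price_alternative": _parse_float(get("price_alternative"),
                                          "price_alternative"),
        "users_prior_year": _parse_int(get("users_prior_year"),
                                       "users_prior_year"),
    }
    if kwargs["start_date"] is None:
        raise ValueError("start_date is mandatory")
    sol = get("solution_category").strip()
    kwargs["solution_category"] = sol or None
    ptype = get("product_type").strip().lower()
    kwargs["product_type"] = ptype or None
    for col in ("patient_contact_notes", "media_attention",
                "patient_forum_reports", "hospital_product",
                "orphan_indication"):
        kwargs[col] = _parse_bool(get(col), col)
    for col in RATING_COLUMNS:
        kwargs[col] = _parse_int(get(col), col)
    return ShortageRecord(**kwargs)


# ---------------------------------------------------------------------------
# I/O

def read_cohort(path, *, delimiter: str = ",", encoding: str = "utf-8",
                provenance: Optional[str] = None,
                on_error: str = "raise") -> Cohort:
    """Read a shortage registry CSV/TSV into a validated :class:`Cohort`.

    Parameters
    ----------
    path : path-like
        Registry file.  The header must name at least the mandatory
        columns (:data:`MANDATORY_COLUMNS`); unknown columns are ignored.
    delimiter, encoding : str
        CSV dialect options.
    provenance : str, optional
        Label stored on the cohort; defaults to the file name.
    on_error : {"raise", "drop"}
        ``"raise"`` (default) raises :class:`RowValidationError` listing
        every offending row; ``"drop"`` discards invalid rows and logs
        them as warnings.

    Raises
    ------
    SchemaError
        If the file is missing or a mandatory column is absent.
    RowValidationError
        If any row violates a field invariant (``on_error="raise"``).
    """
    try:
        fh = open(path, "r", encoding=encoding, newline="")
    except OSError as exc:
        raise SchemaError(f"cannot read registry {path!r}: {exc}") from exc
    with fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise SchemaError(f"registry {path!r} is empty (no header row)")
        header = [h.strip() for h in reader.fieldnames]
        missing = [c for c in MANDATORY_COLUMNS if c not in header]
        if missing:
            raise SchemaError(
                f"registry {path!r} is missing mandatory column(s): "
                f"{missing}"
            )
        records: list[ShortageRecord] = []
        problems: list[tuple[int, str]] = []
        for i, row in enumerate(reader):
            try:
                records.append(_record_from_row(row))
            except ValueError as exc:
                problems.append((i, str(exc)))
    if problems:
        if on_error == "raise":
            raise RowValidationError(problems)
        for i, msg in problems:
            log.warning("dropped row %d: %s", i, msg)
    return Cohort(records=records,
                  provenance=provenance if provenance is not None
                  else str(path))


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, date):
        return value.isoformat()
    if isinstance(value, float) and math.isnan(value):
        return ""
    return str(value)


def write_cohort(cohort: Cohort, path, *, delimiter: str = ",",
                 encoding: str = "utf-8") -> None:
    """Write a cohort as a registry CSV; lossless under :func:`read_cohort`."""
    with open(path, "w", encoding=encoding, newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(ALL_COLUMNS)
        for r in cohort:
            writer.writerow([_cell(getattr(r, c)) for c in ALL_COLUMNS])


# ---------------------------------------------------------------------------
# Episode logic

MIN_DURATION_DAYS = 14
MERGE_GAP_DAYS = 30


def filter_eligible(cohort: Cohort) -> Cohort:
    """Keep shortages unavailable for at least two weeks.

    Records with a closed episode shorter than :data:`MIN_DURATION_DAYS`
    (14) days are removed; ongoing records (no end date) are retained.
    When a ``product_type`` column is present, records without a regular
    marketing authorisation (parallel imports, homeopathic/herbal and
    unregistered products) are also removed.  Removal counts are logged.
    """
    kept: list[ShortageRecord] = []
    too_short = 0
    non_ma = 0
    for r in cohort:
        if r.product_type is not None and r.product_type not in MA_PRODUCT_TYPES:
            non_ma += 1
            continue
        d = r.duration_days
        if d is not None and d < MIN_DURATION_DAYS:
            too_short += 1
            continue
        kept.append(r)
    log.info("filter_eligible: removed %d short episode(s) (<%d days) and "
             "%d non-MA product(s); %d of %d retained",
             too_short, MIN_DURATION_DAYS, non_ma, len(kept), len(cohort))
    return Cohort(records=kept, provenance=cohort.provenance)


def merge_episodes(cohort: Cohort) -> Cohort:
    """Merge reporting artefacts of one and the same shortage.

    A shortage reported within 30 days of the resolution of a previous
    shortage of the same product (``product_name`` + ``atc_code``) is the
    same shortage; the merged record spans the earliest start to the
    latest end.  A gap of more than 30 days starts a new shortage.  The
    operation is idempotent and never increases the record count.
    Overlapping episodes (including episodes following an ongoing one)
    merge with a logged warning.
    """
    by_product: dict[tuple[str, str], list[ShortageRecord]] = {}
    order: list[tuple[str, str]] = []
    for r in cohort:
        key = (r.product_name, r.atc_code)
        if key not in by_product:
            by_product[key] = []
            order.append(key)
        by_product[key].append(r)

    merged: list[ShortageRecord] = []
    for key in order:
        episodes = sorted(by_product[key], key=lambda r: r.start_date)
        current = episodes[0]
        # current_end None means the episode is still open (unbounded).
        for nxt in episodes[1:]:
            if current.end_date is None:
                log.warning("merge_episodes: %s episode starting %s overlaps "
                            "an ongoing episode; merged", key[0],
                            nxt.start_date)
                gap = -1
            else:
                gap = (nxt.start_date - current.end_date).days
                if gap < 0:
                    log.warning("merge_episodes: overlapping episodes for "
                                "%s; merged", key[0])
            if gap <= MERGE_GAP_DAYS:
                if current.end_date is None or nxt.end_date is None:
                    new_end = None
                else:
                    new_end = max(current.end_date, nxt.end_date)
                current = replace(current, end_date=new_end)
            else:
                merged.append(current)
                current = nxt
        merged.append(current)
    merged.sort(key=lambda r: (r.start_date, r.shortage_id))
    if len(merged) < len(cohort):
        log.info("merge_episodes: %d episode(s) merged into %d record(s)",
                 len(cohort), len(merged))
    return Cohort(records=merged, provenance=cohort.provenance)
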
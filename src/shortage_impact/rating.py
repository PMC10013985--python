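"""Raters for the five patient-impact elements of a medicine shortage.

Each shortage is rated on five elements — availability of an alternative
product, underlying disease, susceptibility of the patient population,
costs, and number of patients affected — on an ordinal scale:
1 = low impact, 2 = moderate, 3 = high.  Where an element comprises
several aspects (susceptibility: vulnerability + trust; costs: medicine
costs + personnel costs) the highest aspect rating is the element rating.

The medicine-cost aspect is cohort-relative: the price of the alternative
is expressed as a percentage of the price of the product in shortage, and
ratios above the cohort's upper quartile rate high, below the lower
quartile low.  Personnel costs track the alternative-product element —
the harder the substitution, the more professional time it consumes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import yaml

from .errors import RatingError, ThresholdError
from .records import (RATING_COLUMNS, SEVERITIES, SOLUTION_CATEGORIES,
                      ShortageRecord)

log = logging.getLogger(__name__)

Rating = int  # ordinal in {1, 2, 3}; 1 < 2 < 3 is the only comparison used

#: element -> its aspect slots (max over present aspects = element rating)
ASPECTS_OF = {
    "alternative_product": ("alternative_primary", "alternative_secondary"),
    "susceptibility": ("vulnerability", "trust"),
    "costs": ("medicine_cost", "personnel_cost"),
}

#: Default proposed-solution ladder.  Generic substitution is the
#: preferred, least disruptive solution; therapeutic substitution and
#: unlicensed products are moderate; absence of any therapy is high.
DEFAULT_SOLUTION_LADDER = {
    "generic_substitution": 1,
    "therapeutic_substitution": 2,
    "unlicensed_product": 2,
    "no_therapy": 3,
}


def _check_rating(value, name: str = "rating") -> Rating:
    if value not in (1, 2, 3):
        raise ValueError(f"{name} must be 1, 2 or 3, got {value!r}")
    return int(value)


@dataclass(frozen=True)
class RaterConfig:
    """Numeric cut-points and options left open by the rating framework.

    Attributes
    ----------
    disability_low_max : float
        Disability weight at or below which disease rates low (1).
    disability_high_min : float
        Disability weight strictly above which disease rates high (3).
    child_age_max, elderly_age_min : float
        Age bounds (years) delimiting vulnerable populations.
    n_patients_low_max, n_patients_high_min : int
        Prior-year user counts below/above which the number-of-patients
        element rates low/high.
    quartile_method : str
        Quantile rule for cohort cost thresholds; ``"linear"`` is linear
        interpolation on the sorted sample (the default of mainstream
        statistics software).
    solution_ladder : mapping
        Proposed-solution category -> alternative-product rating.
    """

    disability_low_max: float = 0.10
    disability_high_min: float = 0.30
    child_age_max: float = 18.0
    elderly_age_min: float = 65.0
    n_patients_low_max: int = 1_000
    n_patients_high_min: int = 100_000
    quartile_method: str = "linear"
    solution_ladder: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SOLUTION_LADDER))

    def __post_init__(self) -> None:
        if not self.disability_low_max < self.disability_high_min:
            raise ValueError("disability_low_max must be below "
                             "disability_high_min")
        if not self.n_patients_low_max < self.n_patients_high_min:
            raise ValueError("n_patients_low_max must be below "
                             "n_patients_high_min")
        for cat, r in self.solution_ladder.items():
            if cat not in SOLUTION_CATEGORIES:
                raise ValueError(f"unknown solution category {cat!r}")
            _check_rating(r, f"solution_ladder[{cat!r}]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["solution_ladder"] = dict(self.solution_ladder)
        return d

    def fingerprint(self) -> str:
        """Stable hash of the effective configuration (provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RaterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass(frozen=True)
class CostThresholds:
    """Cohort-relative quartile thresholds on cost ratios (percentages)."""

    q1: float
    q3: float
    method_label: str = "linear"

    def __post_init__(self) -> None:
        if self.q1 > self.q3:
            raise ValueError(f"q1 {self.q1} exceeds q3 {self.q3}")


@dataclass(frozen=True)
class ElementProfile:
    """The five ordinal element ratings with optional aspect sub-ratings.

    Invariants checked on construction: every rating is in {1, 2, 3};
    each rated element equals the maximum of its present aspect ratings;
    the personnel-cost aspect, when present, equals the
    alternative-product rating.
    """

    alternative_product: Optional[Rating]
    disease: Optional[Rating]
    susceptibility: Optional[Rating]
    costs: Optional[Rating]
    n_patients: Optional[Rating]
    aspects: Mapping[str, Rating] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alternative_product", "disease", "susceptibility",
                     "costs", "n_patients"):
            v = getattr(self, name)
            if v is not None:
                _check_rating(v, name)
        for a, v in self.aspects.items():
            _check_rating(v, f"aspect {a}")
        for element, slots in ASPECTS_OF.items():
            present = [self.aspects[a] for a in slots if a in self.aspects]
            rated = getattr(self, element)
            if present and rated is not None and rated != max(present):
                raise ValueError(
                    f"{element} rating {rated} != max of aspects {present}")
        pc = self.aspects.get("personnel_cost")
        if (pc is not None and self.alternative_product is not None
                and pc != self.alternative_product):
            raise ValueError("personnel_cost aspect must equal the "
                             "alternative_product rating")

    @classmethod
    def from_ratings(cls, alternative_product: Rating, disease: Rating,
                     susceptibility: Rating, costs: Rating,
                     n_patients: Rating) -> "ElementProfile":
        """Combined-only profile (no aspect detail)."""
        return cls(alternative_product, disease, susceptibility, costs,
                   n_patients)

    def as_tuple(self) -> tuple:
        return (self.alternative_product, self.disease, self.susceptibility,
                self.costs, self.n_patients)


@dataclass(frozen=True)
class AspectedRating:
    """An element rating together with the aspect ratings behind it."""

    value: Rating
    aspects: Mapping[str, Rating]


# ---------------------------------------------------------------------------
# Element raters

def rate_alternative_product(solution_category: str,
                             config: Optional[RaterConfig] = None) -> Rating:
    """Rate the alternative-product element from the proposed solution.

    The solution ladder runs from generic substitution (same active
    substance and route; low impact) through therapeutic substitution and
    unlicensed products (moderate) to absence of any suitable therapy
    (high).
    """
    config = config or RaterConfig()
    if solution_category is None:
        raise RatingError("alternative_product: solution_category missing")
    try:
        return config.solution_ladder[solution_category]
    except KeyError:
        raise RatingError(
            f"alternative_product: unknown solution_category "
            f"{solution_category!r}; allowed values are "
            f"{sorted(SOLUTION_CATEGORIES)}") from None


def rate_disease(disease_severity: Union[str, float],
                 config: Optional[RaterConfig] = None) -> Rating:
    """Rate the disease element from a severity grade or disability weight.

    ``mild``/``moderate``/``severe`` map to 1/2/3.  A disease graded at
    several levels depending on progression (``multi_class``) is regarded
    as moderate.  Numeric disability weights in [0, 1] are mapped through
    the configured cut-points.
    """
    config = config or RaterConfig()
    if disease_severity is None:
        raise RatingError("disease: disease_severity missing")
    if isinstance(disease_severity, str):
        mapping = {"mild": 1, "moderate": 2, "severe": 3, "multi_class": 2}
        try:
            return mapping[disease_severity]
        except KeyError:
            raise RatingError(
                f"disease: unknown severity {disease_severity!r}; allowed "
                f"values are {sorted(SEVERITIES)}") from None
    w = float(disease_severity)
    if not 0.0 <= w <= 1.0:
        raise RatingError(f"disease: disability weight {w} outside [0, 1]")
    if w <= config.disability_low_max:
        return 1
    if w > config.disability_high_min:
        return 3
    return 2


def rate_susceptibility(age_min: float, age_max: float,
                        trust_flags: Iterable[str],
                        config: Optional[RaterConfig] = None) -> AspectedRating:
    """Rate susceptibility from patient ages and trust-in-alternative flags.

    Vulnerability aspect: a population confined to children or the
    elderly rates 3, one that includes them among adults 2, adults only 1.
    Trust aspect: media attention or patient-forum reports rate 3, notes
    on patient contact alone 2, no signals 1.  The element is the maximum
    of the two aspects.
    """
    config = config or RaterConfig()
    if age_min is None or age_max is None:
        raise RatingError("susceptibility: age range missing")
    if age_min < 0 or age_min > age_max:
        raise RatingError(f"susceptibility: invalid age range "
                          f"[{age_min}, {age_max}]")
    if age_max <= config.child_age_max or age_min >= config.elderly_age_min:
        vulnerability = 3
    elif age_min < config.child_age_max or age_max > config.elderly_age_min:
        vulnerability = 2
    else:
        vulnerability = 1
    flags = set(trust_flags)
    if flags & {"media_attention", "patient_forum_reports"}:
        trust = 3
    elif "patient_contact_notes" in flags:
        trust = 2
    else:
        trust = 1
    return AspectedRating(max(vulnerability, trust),
                          {"vulnerability": vulnerability, "trust": trust})


def cost_ratio(record: ShortageRecord) -> Optional[float]:
    """Alternative price as a percentage of the shortage-product price.

    None when either price is missing; a zero original price makes the
    ratio undefined (logged, treated as missing).
    """
    if record.price_original is None or record.price_alternative is None:
        return None
    if record.price_original == 0:
        log.warning("cost ratio undefined for %s: price_original is 0",
                    record.shortage_id)
        return None
    return 100.0 * record.price_alternative / record.price_original


def compute_cost_thresholds(ratios: Iterable[float],
                            config: Optional[RaterConfig] = None
                            ) -> CostThresholds:
    """Quartile thresholds of the cohort's cost ratios.

    Thresholds are cohort-relative and must be recomputed per cohort.
    At least four non-missing ratios are required; with fewer, supply
    explicit :class:`CostThresholds` instead.
    """
    config = config or RaterConfig()
    vals = np.asarray([r for r in ratios if r is not None], dtype=float)
    if vals.size < 4:
        raise ThresholdError(
            f"need at least 4 cost ratios to compute cohort quartiles, got "
            f"{vals.size}; pass explicit CostThresholds")
    q1, q3 = np.percentile(vals, [25, 75], method=config.quartile_method)
    return CostThresholds(float(q1), float(q3),
                          method_label=config.quartile_method)


def rate_costs(price_original: Optional[float],
               price_alternative: Optional[float],
               thresholds: Optional[CostThresholds],
               alternative_rating: Rating) -> AspectedRating:
    """Rate the costs element (medicine-cost + personnel-cost aspects).

    The medicine-cost aspect compares the cost ratio with the cohort
    quartiles: strictly above q3 rates 3, strictly below q1 rates 1,
    otherwise 2 (boundary values are moderate).  The personnel-cost
    aspect equals the alternative-product rating.  With missing prices
    (or no priced alternative) the medicine-cost aspect is omitted and
    the element falls through to personnel costs alone.
    """
    _check_rating(alternative_rating, "alternative_rating")
    aspects: dict[str, Rating] = {"personnel_cost": alternative_rating}
    ratio = None
    if price_original is not None and price_alternative is not None:
        if price_original == 0:
            log.warning("rate_costs: price_original is 0, medicine-cost "
                        "aspect omitted")
        else:
            ratio = 100.0 * price_alternative / price_original
    if ratio is not None:
        if thresholds is None:
            raise ThresholdError("rate_costs: cost thresholds required when "
                                 "both prices are present")
        if ratio > thresholds.q3:
            aspects["medicine_cost"] = 3
        elif ratio < thresholds.q1:
            aspects["medicine_cost"] = 1
        else:
            aspects["medicine_cost"] = 2
    return AspectedRating(max(aspects.values()), aspects)


def rate_n_patients(users_prior_year: Optional[int], hospital_product: bool,
                    orphan_indication: bool,
                    config: Optional[RaterConfig] = None) -> Rating:
    """Rate the number-of-patients element.

    An orphan indication implies few patients and rates low regardless of
    the other inputs.  Hospital products without usage statistics rate
    moderate by default.  Otherwise the prior-year user count is compared
    with the configured thresholds.
    """
    config = config or RaterConfig()
    if orphan_indication:
        return 1
    if users_prior_year is None:
        if hospital_product:
            return 2
        raise RatingError(
            "n_patients: no user count and neither hospital_product nor "
            "orphan_indication set; supply users_prior_year or a flag")
    if users_prior_year <= config.n_patients_low_max:
        return 1
    if users_prior_year >= config.n_patients_high_min:
        return 3
    return 2


def rate_record(record: ShortageRecord,
                thresholds: Optional[CostThresholds] = None,
                config: Optional[RaterConfig] = None) -> ElementProfile:
    """Rate all five elements of one shortage record.

    If the record carries a full set of pre-assigned element ratings
    (bypass mode, e.g. a registry rated by hand), they are returned
    unchanged.  Otherwise the five raters are composed; aspect ratings
    are retained for the ECHO rollup.  Errors from component raters
    propagate with the element name attached.
    """
    config = config or RaterConfig()
    if record.prerated:
        return ElementProfile.from_ratings(
            *(getattr(record, c) for c in RATING_COLUMNS))
    alt = rate_alternative_product(record.solution_category, config)
    dis = rate_disease(record.disease_severity, config)
    sus = rate_susceptibility(record.age_min, record.age_max,
                              record.trust_flags, config)
    cst = rate_costs(record.price_original, record.price_alternative,
                     thresholds, alt)
    npa = rate_n_patients(record.users_prior_year, record.hospital_product,
                          record.orphan_indication, config)
    aspects = dict(sus.aspects)
    aspects.update(cst.aspects)
    return ElementProfile(alternative_product=alt, disease=dis,
                          susceptibility=sus.value, costs=cst.value,
                          n_patients=npa, aspects=aspects)
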
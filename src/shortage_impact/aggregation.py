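"""Overall impact score, ECHO outcome rollup and classification flags.

The five element ratings (each 1/2/3) are multiplied into an overall
patient-impact score between 1 and 3^5 = 243.  Multiplication (rather
than summation, range 5-15) spreads the scale and highlights shortages
rating high on several elements; the additive variant is kept as a
labelled sensitivity option.

The elements trace to the three outcome types of the ECHO (economic,
clinical, humanistic outcomes) model:

* economic  — costs, number of patients affected;
* clinical  — disease, alternative product (primary aspects),
  susceptibility (vulnerability);
* humanistic — alternative product (secondary aspects),
  susceptibility (trust in the alternative therapy).

Where the elements behind one outcome are rated differently, the highest
rating is the outcome rating.  When a profile carries no aspect detail,
the combined element rating stands in for each of its aspect slots (an
upper-bound convention, recorded as "aspect fallback").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .errors import AggregationError
from .rating import ElementProfile, Rating, _check_rating

MAX_SCORE = 243  # 3 ** 5

#: Every overall score realisable as a product of five ratings in {1,2,3}:
#: the 14 values 2^a * 3^b with a + b <= 5.
VALID_SCORES = frozenset(
    2 ** a * 3 ** b
    for a in range(6) for b in range(6 - a)
)

#: Elements carrying the direct impact on patients (the treatment itself).
DIRECT_ELEMENTS = ("alternative_product", "disease")
#: Elements carrying the indirect impact (costs, concern, system load).
INDIRECT_ELEMENTS = ("costs", "susceptibility", "n_patients")


@dataclass(frozen=True)
class ImpactScore:
    """Aggregated impact of one shortage.

    ``direct_high`` flags a high rating on an element of direct impact
    (alternative product or disease); ``indirect_high`` on an element of
    indirect impact (costs, susceptibility or number of patients).
    """

    overall: int
    n_high_elements: int
    direct_high: bool
    indirect_high: bool
    method: str = "multiplicative"

    def __post_init__(self) -> None:
        if self.method == "multiplicative" and self.overall not in VALID_SCORES:
            raise ValueError(
                f"overall {self.overall} is not a product of five ratings "
                f"in {{1,2,3}}")
        if not 0 <= self.n_high_elements <= 5:
            raise ValueError("n_high_elements must be in 0..5")


@dataclass(frozen=True)
class EchoProfile:
    """Economic / clinical / humanistic outcome ratings of one shortage."""

    economic: Rating
    clinical: Rating
    humanistic: Rating

    def __post_init__(self) -> None:
        for name in ("economic", "clinical", "humanistic"):
            _check_rating(getattr(self, name), name)


def _require_rated(profile: ElementProfile) -> tuple:
    ratings = profile.as_tuple()
    names = ("alternative_product", "disease", "susceptibility", "costs",
             "n_patients")
    for name, r in zip(names, ratings):
        if r is None:
            raise AggregationError(f"element {name!r} is not rated")
    return ratings


def overall_score(profile: ElementProfile,
                  method: str = "multiplicative") -> ImpactScore:
    """Aggregate the five element ratings into an overall impact score.

    Parameters
    ----------
    profile : ElementProfile
        All five elements must be rated.
    method : {"multiplicative", "additive"}
        ``"multiplicative"`` (default) multiplies the ratings (1..243);
        ``"additive"`` sums them (5..15), provided for sensitivity
        analysis and labelled on the result.
    """
    ratings = _require_rated(profile)
    if method == "multiplicative":
        overall = 1
        for r in ratings:
            overall *= r
    elif method == "additive":
        overall = sum(ratings)
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    n_high = sum(1 for r in ratings if r == 3)
    direct = any(getattr(profile, e) == 3 for e in DIRECT_ELEMENTS)
    indirect = any(getattr(profile, e) == 3 for e in INDIRECT_ELEMENTS)
    return ImpactScore(overall=overall, n_high_elements=n_high,
                       direct_high=direct, indirect_high=indirect,
                       method=method)


def echo_rollup(profile: ElementProfile) -> EchoProfile:
    """Roll the element/aspect ratings up to the three ECHO outcomes.

    Aspect ratings are used when present; otherwise the combined element
    rating stands in for each of its aspect slots.
    """
    _require_rated(profile)

    def aspect(name: str, element: str) -> Rating:
        return profile.aspects.get(name, getattr(profile, element))

    economic = max(profile.costs, profile.n_patients)
    clinical = max(profile.disease,
                   aspect("alternative_primary", "alternative_product"),
                   aspect("vulnerability", "susceptibility"))
    humanistic = max(aspect("alternative_secondary", "alternative_product"),
                     aspect("trust", "susceptibility"))
    return EchoProfile(economic=economic, clinical=clinical,
                       humanistic=humanistic)


def classify_unforgiving(score: ImpactScore, k: int = 2) -> bool:
    """Flag "unforgiving" shortages: high ratings on at least *k* elements.

    Such shortages demand a prompt mitigation response — a patient cannot
    miss a dose without harm.  Default k = 2 (high on multiple elements).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return score.n_high_elements >= k


def enumerate_profiles():
    """All 3^5 = 243 combined rating combinations (test/enumeration aid)."""
    for combo in itertools.product((1, 2, 3), repeat=5):
        yield ElementProfile.from_ratings(*combo)
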
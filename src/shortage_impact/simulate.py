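"""Seeded generator of synthetic shortage cohorts.

The confidential Dutch 2012-2015 registry cannot be redistributed, so
this module fabricates cohorts with its published statistical structure:
the marginal composition per start year, route, first-level ATC class
and originator status, and element-rating distributions close to the
published shares.  Raw record attributes are constructed to *invert* to
the sampled ground-truth ratings when passed through the element raters
(a record destined for disease rating 3 gets severity "severe", and so
on), so rating recovery is exact by construction and every pipeline
stage can be exercised end to end without external data.

The costs element is the one exception: its medicine-cost aspect is
cohort-relative (quartiles of the generated cost ratios), so its ground
truth is not sampled but derived inside :func:`generate` through the
same ratio/threshold code path the rater uses.  With the default 20%
missing-price share and strict quartile cuts, the high-cost share lands
near the published 20%.

Attributes are sampled independently across variables (no published
joint distribution exists); ``GeneratorSpec.joint_hook`` accepts a
callable for user-supplied dependence structures.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .aggregation import echo_rollup, overall_score
from .rating import (CostThresholds, ElementProfile, RaterConfig,
                     compute_cost_thresholds, cost_ratio, rate_costs,
                     rate_record)
from .records import Cohort, ShortageRecord

_ATC_LETTERS = "ABCDEFGHJKLMNPQRSTUVWXYZ"


def _default_marginal(variable: str) -> dict:
    return datasets.population_proportions(variable)


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic cohort generator.

    Category probabilities default to the published population marginals;
    rating probabilities default to the published element-rating shares
    where quoted (alternative product high 1% / moderate 60%; disease
    high 29%; susceptibility low 79%) with the unquoted remainders split
    once as an approximate calibration.  Cost ratios are log-normal with
    median 100% so cohort-relative quartiles are well defined.
    """

    n: int = 324
    seed: int = 0
    year_probs: Mapping[int, float] = field(
        default_factory=lambda: _default_marginal("year"))
    route_probs: Mapping[str, float] = field(
        default_factory=lambda: _default_marginal("route"))
    atc_probs: Mapping[str, float] = field(
        default_factory=lambda: _default_marginal("atc_class"))
    originator_prob: float = 1011 / 1844
    rating_probs: Mapping[str, tuple] = field(default_factory=lambda: {
        "alternative_product": (0.39, 0.60, 0.01),
        "disease": (0.33, 0.38, 0.29),
        "susceptibility": (0.79, 0.16, 0.05),
        "n_patients": (0.25, 0.60, 0.15),
    })
    cost_ratio_log_mean: float = math.log(100.0)
    cost_ratio_log_sd: float = 0.5
    missing_price_share: float = 0.20
    hospital_share: float = 0.15
    orphan_share: float = 0.05
    ongoing_share: float = 0.03
    config: RaterConfig = field(default_factory=RaterConfig)
    joint_hook: Optional[Callable] = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name in ("year_probs", "route_probs", "atc_probs"):
            probs = getattr(self, name)
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, expected 1")
        for element, p in self.rating_probs.items():
            if len(p) != 3 or abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(
                    f"rating_probs[{element!r}] must be 3 probabilities "
                    f"summing to 1")
        for name in ("missing_price_share", "hospital_share",
                     "orphan_share", "ongoing_share", "originator_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} outside [0, 1]")
        if self.orphan_share > self.rating_probs["n_patients"][0] + 1e-12:
            raise ValueError(
                "orphan_share exceeds the probability of a low "
                "number-of-patients rating; orphan products always rate low")
        if self.hospital_share > self.rating_probs["n_patients"][1] + 1e-12:
            raise ValueError(
                "hospital_share exceeds the probability of a moderate "
                "number-of-patients rating")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "config" in data:
            data["config"] = RaterConfig(**data["config"])
        for key in ("year_probs",):
            if key in data:
                data[key] = {int(k): v for k, v in data[key].items()}
        if "rating_probs" in data:
            data["rating_probs"] = {k: tuple(v)
                                    for k, v in data["rating_probs"].items()}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("joint_hook", None)
        d["rating_probs"] = {k: list(v) for k, v in self.rating_probs.items()}
        return d


@dataclass
class SyntheticCohort:
    """A generated registry plus its ground-truth element ratings.

    ``ground_truth`` is keyed by ``shortage_id`` and holds the five
    element ratings, the aspect ratings, the overall score and the ECHO
    outcome ratings the raw attributes were constructed to produce.
    """

    cohort: Cohort
    ground_truth: pd.DataFrame
    spec: GeneratorSpec
    thresholds: Optional[CostThresholds] = None


@dataclass
class RecoveryReport:
    """Per-element agreement between recovered and ground-truth ratings."""

    n: int
    agreement: dict[str, float]
    mismatches: pd.DataFrame

    @property
    def perfect(self) -> bool:
        return all(a == 1.0 for a in self.agreement.values())


def _sample_rating(rng: np.random.Generator, probs) -> int:
    return int(rng.choice((1, 2, 3), p=np.asarray(probs, dtype=float)))


def _susceptibility_inputs(rng: np.random.Generator, target: int,
                           config: RaterConfig) -> dict:
    """Ages and trust flags that rate exactly *target* (and its aspects)."""
    child, elderly = config.child_age_max, config.elderly_age_min
    out = {"patient_contact_notes": False, "media_attention": False,
           "patient_forum_reports": False}
    adult = lambda: sorted(rng.uniform(child + 1, elderly - 1, size=2))
    if target == 1:
        out["age_min"], out["age_max"] = adult()
        out["_vulnerability"], out["_trust"] = 1, 1
    elif target == 2:
        if rng.random() < 0.5:  # vulnerable groups among adults, no signals
            out["age_min"] = float(rng.uniform(0, child - 1))
            out["age_max"] = float(rng.uniform(child + 1, elderly - 1))
            out["_vulnerability"], out["_trust"] = 2, 1
            if rng.random() < 0.3:
                out["patient_contact_notes"] = True
                out["_trust"] = 2
        else:  # adults only, but notes on patient contact
            out["age_min"], out["age_max"] = adult()
            out["patient_contact_notes"] = True
            out["_vulnerability"], out["_trust"] = 1, 2
    else:
        if rng.random() < 0.5:  # population confined to children or elderly
            if rng.random() < 0.5:
                out["age_min"] = 0.0
                out["age_max"] = float(rng.uniform(1, child))
            else:
                out["age_min"] = float(rng.uniform(elderly, elderly + 15))
                out["age_max"] = out["age_min"] + float(rng.uniform(1, 10))
            out["_vulnerability"], out["_trust"] = 3, 1
        else:  # media attention or patient-forum reports
            out["age_min"], out["age_max"] = adult()
            if rng.random() < 0.5:
                out["media_attention"] = True
            else:
                out["patient_forum_reports"] = True
            out["_vulnerability"], out["_trust"] = 1, 3
    return out


def _n_patients_inputs(rng: np.random.Generator, target: int,
                       spec: GeneratorSpec) -> dict:
    config = spec.config
    p1, p2, _ = spec.rating_probs["n_patients"]
    out = {"users_prior_year": None, "hospital_product": False,
           "orphan_indication": False}
    if target == 1:
        if rng.random() < (spec.orphan_share / p1 if p1 > 0 else 0.0):
            out["orphan_indication"] = True
            if rng.random() < 0.5:
                out["users_prior_year"] = int(
                    rng.integers(1, config.n_patients_low_max + 1))
        else:
            out["users_prior_year"] = int(
                rng.integers(1, config.n_patients_low_max + 1))
    elif target == 2:
        if rng.random() < (spec.hospital_share / p2 if p2 > 0 else 0.0):
            out["hospital_product"] = True  # no usage statistics collected
        else:
            out["users_prior_year"] = int(
                rng.integers(config.n_patients_low_max + 1,
                             config.n_patients_high_min))
    else:
        out["users_prior_year"] = int(
            rng.integers(config.n_patients_high_min,
                         config.n_patients_high_min * 10))
    return out


def _disease_inputs(rng: np.random.Generator, target: int,
                    config: RaterConfig):
    """Severity grade or disability weight rating exactly *target*."""
    if rng.random() < 0.5:
        if target == 1:
            return "mild"
        if target == 2:
            return "moderate" if rng.random() < 0.7 else "multi_class"
        return "severe"
    lo, hi = config.disability_low_max, config.disability_high_min
    if target == 1:
        return float(rng.uniform(0.005, lo * 0.95))
    if target == 2:
        return float(rng.uniform(lo * 1.1, hi * 0.95))
    return float(rng.uniform(hi * 1.1, 0.95))


_SOLUTION_FOR = {1: ("generic_substitution",),
                 2: ("therapeutic_substitution", "unlicensed_product"),
                 3: ("no_therapy",)}


def generate(spec: GeneratorSpec) -> SyntheticCohort:
    """Generate a synthetic cohort with per-record ground-truth ratings.

    Fully reproducible for a fixed ``spec.seed``.  Every generated
    episode is eligible (>= 14 days or ongoing) and products are unique,
    so the scoring pipeline's filters pass the cohort through unchanged.
    """
    rng = np.random.default_rng(spec.seed)
    config = spec.config
    records: list[ShortageRecord] = []
    truth_rows: list[dict] = []
    years = list(spec.year_probs)
    routes = list(spec.route_probs)
    atcs = list(spec.atc_probs)
    for i in range(spec.n):
        sid = f"SYN-{i:05d}"
        year = int(years[rng.choice(len(years),
                                    p=list(spec.year_probs.values()))])
        route = str(routes[rng.choice(len(routes),
                                      p=list(spec.route_probs.values()))])
        atc_class = str(atcs[rng.choice(len(atcs),
                                        p=list(spec.atc_probs.values()))])
        atc_code = (f"{atc_class}{rng.integers(1, 17):02d}"
                    f"{_ATC_LETTERS[rng.integers(0, 24)]}"
                    f"{_ATC_LETTERS[rng.integers(0, 24)]}"
                    f"{rng.integers(1, 100):02d}")
        start = date(year, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
        if rng.random() < spec.ongoing_share:
            end = None
        else:
            end = start + timedelta(days=int(rng.integers(13, 200)))

        alt = _sample_rating(rng, spec.rating_probs["alternative_product"])
        dis = _sample_rating(rng, spec.rating_probs["disease"])
        sus = _sample_rating(rng, spec.rating_probs["susceptibility"])
        npa = _sample_rating(rng, spec.rating_probs["n_patients"])

        sus_in = _susceptibility_inputs(rng, sus, config)
        npa_in = _n_patients_inputs(rng, npa, spec)
        solutions = _SOLUTION_FOR[alt]
        solution = str(solutions[rng.integers(0, len(solutions))])

        if rng.random() < spec.missing_price_share:
            price_original = price_alternative = None
        else:
            price_original = max(
                0.01, round(float(rng.lognormal(math.log(25.0), 1.0)), 2))
            ratio = float(rng.lognormal(spec.cost_ratio_log_mean,
                                        spec.cost_ratio_log_sd))
            price_alternative = max(
                0.01, round(price_original * ratio / 100.0, 2))

        record = ShortageRecord(
            shortage_id=sid,
            product_name=f"synthetic product {i:05d}",
            atc_code=atc_code,
            route=route,
            originator=bool(rng.random() < spec.originator_prob),
            start_date=start,
            end_date=end,
            solution_category=solution,
            disease_severity=_disease_inputs(rng, dis, config),
            age_min=sus_in["age_min"],
            age_max=sus_in["age_max"],
            patient_contact_notes=sus_in["patient_contact_notes"],
            media_attention=sus_in["media_attention"],
            patient_forum_reports=sus_in["patient_forum_reports"],
            price_original=price_original,
            price_alternative=price_alternative,
            users_prior_year=npa_in["users_prior_year"],
            hospital_product=npa_in["hospital_product"],
            orphan_indication=npa_in["orphan_indication"],
        )
        if spec.joint_hook is not None:
            record = spec.joint_hook(rng, record) or record
        records.append(record)
        truth_rows.append({
            "shortage_id": sid,
            "rating_alternative_product": alt,
            "rating_disease": dis,
            "rating_susceptibility": sus,
            "rating_n_patients": npa,
            "vulnerability": sus_in["_vulnerability"],
            "trust": sus_in["_trust"],
        })

    cohort = Cohort(records=records,
                    provenance=f"synthetic (seed={spec.seed}, n={spec.n})")

    # Costs ground truth is cohort-relative: derive it from the generated
    # prices through the same ratio/quartile path the rater uses.
    ratios = [cost_ratio(r) for r in records]
    present = [x for x in ratios if x is not None]
    thresholds = (compute_cost_thresholds(present, config)
                  if len(present) >= 4 else None)
    for row, record in zip(truth_rows, records):
        cst = rate_costs(record.price_original, record.price_alternative,
                         thresholds, row["rating_alternative_product"])
        row["rating_costs"] = cst.value
        row["medicine_cost"] = cst.aspects.get("medicine_cost")
        row["personnel_cost"] = cst.aspects["personnel_cost"]
        profile = ElementProfile(
            alternative_product=row["rating_alternative_product"],
            disease=row["rating_disease"],
            susceptibility=row["rating_susceptibility"],
            costs=row["rating_costs"],
            n_patients=row["rating_n_patients"],
            aspects={k: v for k, v in (
                ("vulnerability", row["vulnerability"]),
                ("trust", row["trust"]),
                ("medicine_cost", row["medicine_cost"]),
                ("personnel_cost", row["personnel_cost"]),
            ) if v is not None})
        score = overall_score(profile)
        echo = echo_rollup(profile)
        row["overall"] = score.overall
        row["echo_economic"] = echo.economic
        row["echo_clinical"] = echo.clinical
        row["echo_humanistic"] = echo.humanistic

    columns = ["shortage_id", "rating_alternative_product", "rating_disease",
               "rating_susceptibility", "rating_costs", "rating_n_patients",
               "vulnerability", "trust", "medicine_cost", "personnel_cost",
               "overall", "echo_economic", "echo_clinical",
               "echo_humanistic"]
    ground_truth = pd.DataFrame(truth_rows, columns=columns)
    return SyntheticCohort(cohort=cohort, ground_truth=ground_truth,
                           spec=spec, thresholds=thresholds)


ELEMENTS = ("alternative_product", "disease", "susceptibility", "costs",
            "n_patients")


def recover_ratings_check(synth: SyntheticCohort) -> RecoveryReport:
    """Re-rate a generated cohort and compare with its ground truth.

    Contract: exact (100%) per-element agreement whenever generator and
    rater share a configuration, including cost ratings at quartile
    boundaries (the thresholds are recomputed from the same cohort).
    An empty cohort yields a vacuous report (n = 0, agreement 1.0).
    """
    config = synth.spec.config
    records = synth.cohort.records
    if not records:
        return RecoveryReport(n=0, agreement={e: 1.0 for e in ELEMENTS},
                              mismatches=pd.DataFrame())
    ratios = [cost_ratio(r) for r in records]
    present = [x for x in ratios if x is not None]
    thresholds = (compute_cost_thresholds(present, config)
                  if len(present) >= 4 else None)
    truth = synth.ground_truth.set_index("shortage_id")
    agree = {e: 0 for e in ELEMENTS}
    mismatch_rows = []
    for record in records:
        profile = rate_record(record, thresholds, config)
        expected = truth.loc[record.shortage_id]
        for element, got in zip(ELEMENTS, profile.as_tuple()):
            want = int(expected[f"rating_{element}"])
            if got == want:
                agree[element] += 1
            else:
                mismatch_rows.append({"shortage_id": record.shortage_id,
                                      "element": element,
                                      "expected": want, "recovered": got})
    n = len(records)
    return RecoveryReport(
        n=n,
        agreement={e: agree[e] / n for e in ELEMENTS},
        mismatches=pd.DataFrame(mismatch_rows,
                                columns=["shortage_id", "element",
                                         "expected", "recovered"]))
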
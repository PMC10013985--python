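"""Model/Results interface tying the scoring pipeline together.

:class:`ShortageImpactModel` is built from a shortage registry (a
:class:`~shortage_impact.records.Cohort`, a DataFrame or a CSV file) and
a :class:`~shortage_impact.rating.RaterConfig`.  ``fit()`` runs the full
pipeline — eligibility filter, episode merge, cohort-relative cost
thresholds, element rating, multiplicative aggregation and ECHO rollup —
and returns an :class:`ImpactResults` carrying the scored registry plus
the cohort-level summaries, comparisons and a ``summary()`` table.

Example
-------
>>> from shortage_impact import GeneratorSpec, ShortageImpactModel, generate
>>> synth = generate(GeneratorSpec(n=324, seed=7))
>>> res = ShortageImpactModel(synth.cohort).fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import logging
from dataclasses import fields
from typing import Optional, Union

import pandas as pd

from . import analysis
from .aggregation import classify_unforgiving, echo_rollup, overall_score
from .analysis import (CohortCharacteristics, RatingDistribution,
                       ScoreSummary, TestResult, YearlyTrends)
from .rating import (CostThresholds, RaterConfig, compute_cost_thresholds,
                     cost_ratio, rate_record)
from .records import Cohort, ShortageRecord, read_cohort

log = logging.getLogger(__name__)

_RECORD_FIELDS = [f.name for f in fields(ShortageRecord)]


def _coerce_cohort(data) -> Cohort:
    if isinstance(data, Cohort):
        return data
    if isinstance(data, pd.DataFrame):
        records = []
        for _, row in data.iterrows():
            kwargs = {k: (None if pd.isna(v) else v)
                      for k, v in row.items() if k in _RECORD_FIELDS}
            records.append(ShortageRecord(**kwargs))
        return Cohort(records=records, provenance="dataframe")
    raise TypeError(f"expected Cohort or DataFrame, got {type(data)!r}")


class ShortageImpactModel:
    """Patient-impact scoring model for a shortage registry.

    Parameters
    ----------
    cohort : Cohort or DataFrame
        The shortage registry to score.
    config : RaterConfig, optional
        Rating cut-points; defaults are used when omitted.
    apply_filter : bool
        Apply the two-week eligibility filter (and the marketing-
        authorisation exclusions when a product_type column is present).
    merge : bool
        Merge episodes of the same product separated by at most 30 days.
    thresholds : CostThresholds, optional
        Explicit cost-ratio quartiles; when omitted they are computed
        from the cohort (requires >= 4 priced records with alternatives).
    """

    def __init__(self, cohort: Union[Cohort, pd.DataFrame],
                 config: Optional[RaterConfig] = None, *,
                 apply_filter: bool = True, merge: bool = True,
                 thresholds: Optional[CostThresholds] = None):
        self.cohort = _coerce_cohort(cohort)
        self.config = config or RaterConfig()
        self.apply_filter = apply_filter
        self.merge = merge
        self.thresholds = thresholds

    @classmethod
    def from_csv(cls, path, config: Optional[RaterConfig] = None,
                 **kwargs) -> "ShortageImpactModel":
        reader_opts = {k: kwargs.pop(k) for k in ("delimiter", "encoding")
                       if k in kwargs}
        return cls(read_cohort(path, **reader_opts), config, **kwargs)

    def fit(self) -> "ImpactResults":
        """Run the scoring pipeline and return the results."""
        from .records import filter_eligible, merge_episodes

        cohort = self.cohort
        n_input = len(cohort)
        if self.apply_filter:
            cohort = filter_eligible(cohort)
        n_eligible = len(cohort)
        if self.merge:
            cohort = merge_episodes(cohort)
        n_scored = len(cohort)

        thresholds = self.thresholds
        if thresholds is None:
            ratios = [cost_ratio(r) for r in cohort]
            present = [x for x in ratios if x is not None]
            if len(present) >= 4:
                thresholds = compute_cost_thresholds(present, self.config)
            else:
                log.info("fewer than 4 cost ratios; no cohort cost "
                         "thresholds (medicine-cost aspects will require "
                         "missing prices)")

        rows = []
        for record in cohort:
            profile = rate_record(record, thresholds, self.config)
            score = overall_score(profile)
            echo = echo_rollup(profile)
            row = {f: getattr(record, f) for f in _RECORD_FIELDS
                   if not f.startswith("rating_")}
            row.update({
                "year": record.year,
                "atc_class": record.atc_class,
                "rating_alternative_product": profile.alternative_product,
                "rating_disease": profile.disease,
                "rating_susceptibility": profile.susceptibility,
                "rating_costs": profile.costs,
                "rating_n_patients": profile.n_patients,
                "aspect_vulnerability": profile.aspects.get("vulnerability"),
                "aspect_trust": profile.aspects.get("trust"),
                "aspect_medicine_cost": profile.aspects.get("medicine_cost"),
                "aspect_personnel_cost": profile.aspects.get("personnel_cost"),
                "overall": score.overall,
                "n_high_elements": score.n_high_elements,
                "direct_high": score.direct_high,
                "indirect_high": score.indirect_high,
                "unforgiving": classify_unforgiving(score),
                "echo_economic": echo.economic,
                "echo_clinical": echo.clinical,
                "echo_humanistic": echo.humanistic,
                "config_fingerprint": self.config.fingerprint(),
            })
            rows.append(row)
        scored = pd.DataFrame(rows)
        scored.attrs["config"] = self.config.to_dict()
        return ImpactResults(model=self, scored=scored,
                             thresholds=thresholds,
                             counts={"input": n_input,
                                     "eligible": n_eligible,
                                     "scored": n_scored})


class ImpactResults:
    """Scored registry plus cohort-level summaries.

    Attributes
    ----------
    scored : DataFrame
        One row per scored shortage: raw attributes, the five element
        ratings, aspect ratings, overall score, ECHO ratings,
        classification flags and the config fingerprint.
    thresholds : CostThresholds or None
        The cohort-relative cost quartiles used.
    counts : dict
        Record counts at each pipeline stage (input/eligible/scored).
    """

    def __init__(self, model: ShortageImpactModel, scored: pd.DataFrame,
                 thresholds: Optional[CostThresholds], counts: dict):
        self.model = model
        self.scored = scored
        self.thresholds = thresholds
        self.counts = counts
        self.config = model.config

    @property
    def n(self) -> int:
        return len(self.scored)

    def rating_distribution(self) -> RatingDistribution:
        return analysis.rating_distribution(self.scored)

    def stratified_scores(self, by: str) -> list[ScoreSummary]:
        return analysis.stratified_scores(
            self.scored, by, quartile_method=self.config.quartile_method)

    def compare_strata(self, by: str,
                       adjust: str = "bonferroni") -> list[TestResult]:
        return analysis.compare_strata(self.scored, by, adjust=adjust)

    def characterize(self, sample=None) -> CohortCharacteristics:
        return analysis.characterize(self.scored, sample)

    def yearly_trends(self) -> YearlyTrends:
        return analysis.yearly_trends(
            self.scored, quartile_method=self.config.quartile_method)

    def save(self, path, **kwargs) -> None:
        """Write the scored registry as CSV."""
        self.scored.to_csv(path, index=False, **kwargs)

    def summary(self) -> str:
        """Human-readable summary of the scored cohort."""
        lines = []
        add = lines.append
        add("Shortage patient-impact results")
        add("=" * 55)
        add(f"records input/eligible/scored : "
            f"{self.counts['input']}/{self.counts['eligible']}/"
            f"{self.counts['scored']}")
        if self.thresholds is not None:
            add(f"cost-ratio quartiles (q1, q3) : "
                f"({self.thresholds.q1:.1f}%, {self.thresholds.q3:.1f}%) "
                f"[{self.thresholds.method_label}]")
        add(f"config fingerprint            : {self.config.fingerprint()}")
        if self.n == 0:
            add("(empty cohort)")
            return "\n".join(lines)
        overall = self.scored["overall"].to_numpy(dtype=float)
        s = analysis._summary("all", overall, self.config.quartile_method)
        add(f"overall score median (IQR)    : {s.median:g} "
            f"({s.q1:g}-{s.q3:g})")
        dist = self.rating_distribution()
        add("")
        add("share of records per element rating (%)")
        add(f"{'element':<22}{'low':>7}{'moderate':>10}{'high':>7}")
        for element, row in dist.element_pct.iterrows():
            add(f"{element:<22}{row[1]:>7.1f}{row[2]:>10.1f}{row[3]:>7.1f}")
        if not dist.echo_pct.empty:
            add("")
            add("share of records per ECHO outcome rating (%)")
            for outcome, row in dist.echo_pct.iterrows():
                add(f"{outcome:<22}{row[1]:>7.1f}{row[2]:>10.1f}"
                    f"{row[3]:>7.1f}")
        add("")
        add(f"high on >= 1 element          : "
            f"{dist.shares['high_on_ge1']:.1f}%")
        add(f"high on >= 2 elements         : "
            f"{dist.shares['high_on_ge2']:.1f}%")
        add(f"low on all elements           : "
            f"{dist.shares['low_on_all']:.1f}%")
        add(f"direct impact rated high      : "
            f"{dist.shares['direct_high']:.1f}%")
        add(f"indirect-only high            : "
            f"{dist.shares['indirect_only_high']:.1f}%")
        return "\n".join(lines)
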
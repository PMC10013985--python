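"""Cohort-level statistics over scored shortage registries.

Covers the study-design side of the framework: the finite-population
sample-size rule used to pick a representative sample, seeded random
sampling, characterisation tables (year, route of administration,
first-level ATC class, originator/generic), chi-square representativeness
checks of a sample against its population, per-stratum medians/IQRs of
the overall impact score, Kruskal-Wallis omnibus comparison with Dunn
post-hoc tests, element/ECHO rating distributions and per-year trends.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ShortageDataError
from .records import Cohort

log = logging.getLogger(__name__)

#: Characterisation variables of a shortage registry.
STRATA = ("year", "route", "atc_class", "originator")


# ---------------------------------------------------------------------------
# Sample size

@dataclass(frozen=True)
class SampleSizeParams:
    """Inputs of the finite-population sample-size calculation."""

    population_size: int
    confidence: float = 0.95
    margin: float = 0.05
    proportion: float = 0.5

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if not 0 < self.margin < 1:
            raise ValueError("margin must be in (0, 1)")
        if not 0 < self.proportion < 1:
            raise ValueError("proportion must be in (0, 1)")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")


def required_sample_size(params: SampleSizeParams) -> int:
    """Smallest representative sample size for a finite population.

    Cochran's formula with finite-population correction::

        n0 = z^2 p (1 - p) / e^2
        n  = n0 / (1 + (n0 - 1) / N)

    with ``z`` the exact two-sided normal quantile for the confidence
    level, rounded up to an integer.  With N = 1844 at 95% confidence,
    +/-5% margin and p = 0.5 this yields 319.
    """
    z = stats.norm.ppf(0.5 + params.confidence / 2.0)
    p, e, n_pop = params.proportion, params.margin, params.population_size
    n0 = z * z * p * (1.0 - p) / (e * e)
    n = n0 / (1.0 + (n0 - 1.0) / n_pop)
    return int(math.ceil(n - 1e-12))


def draw_sample(cohort: Cohort, n: int, seed: int) -> Cohort:
    """Simple random sample without replacement, reproducible per seed."""
    if n > len(cohort):
        raise ShortageDataError(
            f"cannot sample {n} records from a cohort of {len(cohort)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cohort), size=n, replace=False)
    return Cohort(records=[cohort.records[i] for i in sorted(idx)],
                  provenance=f"{cohort.provenance} [sample n={n} seed={seed}]")


# ---------------------------------------------------------------------------
# Characterisation

@dataclass
class CohortCharacteristics:
    """Counts and percentages per characterisation variable.

    ``tables[variable]`` is a DataFrame with columns ``category``,
    ``count``, ``pct`` and, when a paired sample was given,
    ``sample_count``/``sample_pct``.  Percentages are always recomputed
    from the counts.
    """

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    n: int = 0
    sample_n: Optional[int] = None

    def counts(self, variable: str) -> pd.Series:
        t = self.tables[variable]
        return pd.Series(t["count"].to_numpy(), index=t["category"])

    @classmethod
    def from_counts(cls, counts: Mapping[str, Mapping]) -> "CohortCharacteristics":
        """Build characteristics from already-tabulated counts."""
        tables = {}
        n = 0
        for variable, cat_counts in counts.items():
            total = sum(cat_counts.values())
            n = max(n, total)
            tables[variable] = pd.DataFrame({
                "category": list(cat_counts.keys()),
                "count": list(cat_counts.values()),
                "pct": [100.0 * c / total if total else 0.0
                        for c in cat_counts.values()],
            })
        return cls(tables=tables, n=n)


def _as_frame(cohort: Union[Cohort, pd.DataFrame]) -> pd.DataFrame:
    if isinstance(cohort, Cohort):
        return cohort.to_frame()
    return cohort


def _counts(df: pd.DataFrame, variable: str) -> pd.Series:
    if variable not in df.columns:
        raise ShortageDataError(f"unknown stratum variable {variable!r}")
    return df[variable].value_counts().sort_index()


def characterize(cohort: Union[Cohort, pd.DataFrame],
                 sample: Union[Cohort, pd.DataFrame, None] = None,
                 variables: Sequence[str] = STRATA) -> CohortCharacteristics:
    """Tabulate counts and percentages per characterisation variable.

    When *sample* is given, its counts/percentages are appended as
    additional columns (categories aligned to the population; absent
    categories count 0).
    """
    df = _as_frame(cohort)
    sdf = _as_frame(sample) if sample is not None else None
    tables = {}
    for variable in variables:
        counts = _counts(df, variable)
        total = int(counts.sum())
        table = pd.DataFrame({
            "category": counts.index.to_list(),
            "count": counts.to_numpy(),
            "pct": 100.0 * counts.to_numpy() / total if total else 0.0,
        })
        if sdf is not None:
            s_counts = _counts(sdf, variable).reindex(counts.index,
                                                      fill_value=0)
            s_total = int(s_counts.sum())
            table["sample_count"] = s_counts.to_numpy()
            table["sample_pct"] = (100.0 * s_counts.to_numpy() / s_total
                                   if s_total else 0.0)
        tables[variable] = table
    return CohortCharacteristics(
        tables=tables, n=len(df),
        sample_n=len(sdf) if sdf is not None else None)


# ---------------------------------------------------------------------------
# Tests

@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test."""

    name: str
    statistic: float
    p_value: float
    df: Optional[int] = None
    adjustment: str = "none"
    groups: Optional[tuple] = None
    notes: tuple = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def chi_square_gof(sample_counts: pd.Series,
                   population_counts: pd.Series,
                   variable: str = "") -> TestResult:
    """Chi-square goodness of fit of sample counts to population proportions.

    The sample is a subset of the population, so the comparison is a
    goodness-of-fit of the observed sample counts against expected counts
    proportional to the population composition (df = categories - 1).
    Categories with expected count < 5 are flagged in ``notes``.
    """
    obs = np.asarray(sample_counts, dtype=float)
    popc = np.asarray(population_counts.reindex(sample_counts.index,
                                                fill_value=0), dtype=float)
    if len(obs) < 2:
        raise ShortageDataError(
            f"representativeness test for {variable!r} needs at least 2 "
            f"categories (df would be 0)")
    if popc.sum() <= 0:
        raise ShortageDataError("population counts are all zero")
    expected = popc / popc.sum() * obs.sum()
    notes = []
    if (expected == 0).any():
        zero = [str(c) for c, e in zip(sample_counts.index, expected)
                if e == 0]
        raise ShortageDataError(
            f"zero expected count for categories {zero}; pool or drop them "
            f"before testing")
    small = [str(c) for c, e in zip(sample_counts.index, expected) if e < 5]
    if small:
        notes.append(f"expected count < 5 for: {', '.join(small)}")
    statistic, p = stats.chisquare(obs, expected)
    return TestResult(name=f"chi-square goodness-of-fit ({variable})",
                      statistic=float(statistic), p_value=float(p),
                      df=len(obs) - 1, notes=tuple(notes))


def representativeness_test(population: CohortCharacteristics,
                            sample: CohortCharacteristics,
                            variable: str) -> TestResult:
    """Test whether a drawn sample matches the population composition."""
    pop_counts = population.counts(variable)
    sample_counts = sample.counts(variable).reindex(pop_counts.index,
                                                    fill_value=0)
    return chi_square_gof(sample_counts, pop_counts, variable)


# ---------------------------------------------------------------------------
# Stratified scores

@dataclass(frozen=True)
class ScoreSummary:
    """Median and IQR of the overall impact score within one stratum."""

    stratum: object
    n: int
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.q1 <= self.median <= self.q3:
            raise ValueError("expected q1 <= median <= q3")


def _summary(label, scores: np.ndarray,
             method: str = "linear") -> ScoreSummary:
    q1, med, q3 = np.percentile(scores, [25, 50, 75], method=method)
    return ScoreSummary(stratum=label, n=int(scores.size),
                        median=float(med), q1=float(q1), q3=float(q3))


def stratified_scores(scored: pd.DataFrame, by: str,
                      score_column: str = "overall",
                      quartile_method: str = "linear") -> list[ScoreSummary]:
    """Median/IQR of the overall score per stratum of *by*.

    Uses the same quantile interpolation as the cost thresholds for
    internal consistency.  Empty strata are omitted (with a warning when
    the stratum column holds NA values).
    """
    if by not in scored.columns:
        raise ShortageDataError(f"unknown stratum variable {by!r}")
    out = []
    na = scored[by].isna().sum()
    if na:
        log.warning("stratified_scores: %d record(s) with missing %s "
                    "omitted", na, by)
    for label, group in scored.dropna(subset=[by]).groupby(by, sort=True):
        out.append(_summary(label, group[score_column].to_numpy(dtype=float),
                            quartile_method))
    return out


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn

def _dunn_pairwise(groups: dict, adjust: str) -> list[TestResult]:
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    start = 0
    for g in labels:
        size = groups[g].size
        mean_rank[g] = ranks[start:start + size].mean()
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()
                / (12.0 * (n_total - 1))) if n_total > 1 else 0.0
    variance = n_total * (n_total + 1) / 12.0 - tie_term
    raw = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            se = math.sqrt(variance * (1.0 / groups[a].size
                                       + 1.0 / groups[b].size))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            raw.append((a, b, z, p))
    m = len(raw)
    if adjust == "none":
        adjusted = [p for *_, p in raw]
    elif adjust == "bonferroni":
        adjusted = [min(1.0, p * m) for *_, p in raw]
    elif adjust == "holm":
        order = np.argsort([p for *_, p in raw])
        adjusted = [0.0] * m
        running = 0.0
        for rank_i, idx in enumerate(order):
            p = raw[idx][3]
            running = max(running, min(1.0, (m - rank_i) * p))
            adjusted[idx] = running
    else:
        raise ValueError(f"unknown p-adjustment {adjust!r}; use "
                         f"'bonferroni', 'holm' or 'none'")
    return [
        TestResult(name="Dunn", statistic=float(z), p_value=float(p_adj),
                   adjustment=adjust, groups=(a, b))
        for (a, b, z, _), p_adj in zip(raw, adjusted)
    ]


def compare_strata(scored: pd.DataFrame, by: str,
                   score_column: str = "overall",
                   adjust: str = "bonferroni") -> list[TestResult]:
    """Kruskal-Wallis omnibus test plus pairwise Dunn post-hoc tests.

    Returns the omnibus result first, followed by one Dunn result per
    stratum pair (adjustment label recorded on each).  When every score
    is identical across all strata, the rank test is degenerate and the
    limiting values (statistic 0, p = 1) are returned.
    """
    if by not in scored.columns:
        raise ShortageDataError(f"unknown stratum variable {by!r}")
    groups = {
        label: g[score_column].to_numpy(dtype=float)
        for label, g in scored.dropna(subset=[by]).groupby(by, sort=True)
        if len(g) > 0
    }
    if len(groups) < 2:
        raise ShortageDataError(
            f"compare_strata needs >= 2 non-empty strata, got {len(groups)}")
    pooled = np.concatenate(list(groups.values()))
    df = len(groups) - 1
    if np.ptp(pooled) == 0:  # all scores identical: H = 0 in the limit
        omnibus = TestResult(name=f"Kruskal-Wallis ({by})", statistic=0.0,
                             p_value=1.0, df=df,
                             notes=("all scores identical",))
        dunn = [TestResult(name="Dunn", statistic=0.0, p_value=1.0,
                           adjustment=adjust, groups=pair)
                for pair in _pairs(list(groups))]
        return [omnibus] + dunn
    h, p = stats.kruskal(*groups.values())
    omnibus = TestResult(name=f"Kruskal-Wallis ({by})", statistic=float(h),
                         p_value=float(p), df=df)
    return [omnibus] + _dunn_pairwise(groups, adjust)


def _pairs(labels: list) -> list[tuple]:
    return [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]


# ---------------------------------------------------------------------------
# Rating distributions and trends

ELEMENT_COLUMNS = ("rating_alternative_product", "rating_disease",
                   "rating_susceptibility", "rating_costs",
                   "rating_n_patients")
ECHO_COLUMNS = ("echo_economic", "echo_clinical", "echo_humanistic")


@dataclass
class RatingDistribution:
    """Share of records at each rating per element and ECHO outcome.

    ``element_pct``/``echo_pct`` are DataFrames indexed by element (or
    outcome) with columns 1/2/3 holding percentages; ``shares`` holds the
    summary percentages (high on >= 1 element, high on >= 2, low on all
    elements, plus the direct/indirect high-impact split).
    """

    element_pct: pd.DataFrame
    echo_pct: pd.DataFrame
    shares: dict
    n: int


def _pct_table(scored: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    if not columns:
        return pd.DataFrame(columns=[1, 2, 3])
    rows = {}
    for col in columns:
        counts = scored[col].value_counts()
        total = int(counts.sum())
        rows[col.replace("rating_", "").replace("echo_", "")] = {
            r: 100.0 * counts.get(r, 0) / total if total else 0.0
            for r in (1, 2, 3)
        }
    return pd.DataFrame(rows).T[[1, 2, 3]]


def rating_distribution(scored: pd.DataFrame) -> RatingDistribution:
    """Distribution of ratings per element and per ECHO outcome."""
    n = len(scored)
    element_pct = _pct_table(scored, ELEMENT_COLUMNS)
    echo_pct = _pct_table(scored, [c for c in ECHO_COLUMNS
                                   if c in scored.columns])
    ratings = scored[list(ELEMENT_COLUMNS)].to_numpy()
    n_high = (ratings == 3).sum(axis=1)
    all_low = (ratings == 1).all(axis=1)
    direct = scored["direct_high"].to_numpy(dtype=bool) \
        if "direct_high" in scored.columns else np.zeros(n, dtype=bool)
    indirect = scored["indirect_high"].to_numpy(dtype=bool) \
        if "indirect_high" in scored.columns else np.zeros(n, dtype=bool)

    def share(mask) -> float:
        return 100.0 * float(np.sum(mask)) / n if n else 0.0

    shares = {
        "high_on_ge1": share(n_high >= 1),
        "high_on_ge2": share(n_high >= 2),
        "low_on_all": share(all_low),
        "direct_high": share(direct),
        "indirect_only_high": share(indirect & ~direct),
    }
    return RatingDistribution(element_pct=element_pct, echo_pct=echo_pct,
                              shares=shares, n=n)


@dataclass
class YearlyTrends:
    """Per-year score summaries and rating distributions."""

    score_summaries: list[ScoreSummary]
    distributions: dict[int, RatingDistribution]


def yearly_trends(scored: pd.DataFrame,
                  quartile_method: str = "linear") -> YearlyTrends:
    """Overall-score summary and rating distribution per start year."""
    if "year" not in scored.columns:
        raise ShortageDataError("scored cohort lacks a 'year' column")
    summaries = stratified_scores(scored, "year",
                                  quartile_method=quartile_method)
    distributions = {
        int(year): rating_distribution(group)
        for year, group in scored.dropna(subset=["year"]).groupby("year")
    }
    return YearlyTrends(score_summaries=summaries,
                        distributions=distributions)
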
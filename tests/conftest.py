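from datetime import date

import pytest

from shortage_impact import Cohort, ShortageRecord


@pytest.fixture
def make_record():
    """Factory for valid records with sensible rating inputs."""

    def _make(**overrides):
        kwargs = dict(
            shortage_id="S-001",
            product_name="amoxicillin capsule",
            atc_code="J01CA04",
            route="oral",
            originator=False,
            start_date=date(2013, 3, 1),
            end_date=date(2013, 5, 1),
            solution_category="generic_substitution",
            disease_severity="moderate",
            age_min=20.0,
            age_max=60.0,
            price_original=10.0,
            price_alternative=10.0,
            users_prior_year=50_000,
        )
        kwargs.update(overrides)
        return ShortageRecord(**kwargs)

    return _make


@pytest.fixture
def make_cohort(make_record):
    def _make(n=5, **overrides):
        records = [make_record(shortage_id=f"S-{i:03d}",
                               product_name=f"product {i}", **overrides)
                   for i in range(n)]
        return Cohort(records=records, provenance="test")

    return _make
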
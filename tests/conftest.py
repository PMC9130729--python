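import pytest

from nscdyn import (
    DEFAULT_RATES,
    DivisionProportions,
    init_labeled_cohort,
)


@pytest.fixture(scope="session")
def rates():
    """The published per-day reaction rates."""
    return DEFAULT_RATES


@pytest.fixture(scope="session")
def published_props():
    """The published steady-state division proportions."""
    return DivisionProportions()


@pytest.fixture(scope="session")
def cohort1000(published_props):
    """Default labeled cohort from 1000 labeling divisions: (500, 1040, 460)."""
    return init_labeled_cohort(1000, published_props)
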
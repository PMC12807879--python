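import pytest

from sehg.config import StudyConfig
from sehg.records import FoodSample
from sehg.synth import gen_lms_table


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def lms_table():
    return gen_lms_table()


def make_samples(category, se_values, hg_values, subcategory=None, prefix="S"):
    """Build FoodSample records with given concentration vectors."""
    return [
        FoodSample(
            sample_id=f"{prefix}{i:03d}",
            category=category,
            subcategory=subcategory,
            se_conc=se,
            hg_conc=hg,
        )
        for i, (se, hg) in enumerate(zip(se_values, hg_values))
    ]


def symmetric_panel(category, se_mean, hg_mean, n, spread=0.1, subcategory=None, prefix="S"):
    """n samples whose sample means equal the targets exactly.

    Values are placed symmetrically around each mean so the arithmetic
    mean is exact regardless of n; spread is relative.
    """
    def values(mean):
        deltas = [spread * mean * (i - (n - 1) / 2) / max(n - 1, 1) for i in range(n)]
        return [mean + d for d in deltas]

    return make_samples(category, values(se_mean), values(hg_mean), subcategory, prefix)
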
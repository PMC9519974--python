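import numpy as np
import pandas as pd
import pytest

from psycop.simulate import CohortDesign, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced but CDA-viable cohort (32 mice) shared across tests."""
    return generate_cohort(CohortDesign(group_sizes=(8, 8, 8, 8), seed=42))


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    from psycop.model import BehavioralProfile
    return BehavioralProfile.from_cohort(small_cohort).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_design():
    """Unbalanced 2x2 design over 14 mice."""
    rows = []
    k = 0
    for s, a, n in (("placebo", "placebo", 3), ("placebo", "aripiprazole", 4),
                    ("spironolactone", "placebo", 3),
                    ("spironolactone", "aripiprazole", 4)):
        for _ in range(n):
            k += 1
            rows.append({"mouse_tag": f"m{k}", "S": s, "A": a})
    return pd.DataFrame(rows).set_index("mouse_tag")
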
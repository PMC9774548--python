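import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from gazebias import GeneratorConfig, simulate_cohort
from gazebias.pipeline import compute_metrics


SMALL_COHORT = {
    ("somali", "woman"): 4,
    ("somali", "man"): 4,
    ("czech", "woman"): 4,
    ("czech", "man"): 4,
}


@pytest.fixture(scope="session")
def small_cohort():
    """One 16-participant cohort shared by read-only tests."""
    cfg = GeneratorConfig(n_participants=dict(SMALL_COHORT))
    recs, roster, schedule, truth = simulate_cohort(cfg, seed=42)
    return {"config": cfg, "recordings": recs, "roster": roster,
            "schedule": schedule, "truth": truth}


@pytest.fixture(scope="session")
def small_metrics(small_cohort) -> pd.DataFrame:
    return compute_metrics(small_cohort["recordings"])
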
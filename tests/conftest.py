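import numpy as np
import pandas as pd
import pytest

from grscreen.config import ScreenConfig
from grscreen.simulate import DrugTruth, LineTruth, simulate_screen


def tiny_records(k: float = 2.0, t0: float = 1.0e6) -> pd.DataFrame:
    """A minimal noiseless screen: one model, one drug, 4 doses, 1 replicate.

    Vehicle fold-change is ``k``; treated wells follow a perfect cytotoxic
    Hill response (GR_inf = -1, GEC50 = 0.1, hill = 1).
    """
    truth = DrugTruth(gr_inf=-1.0, gec50=0.1, hill=1.0)
    doses = np.array([0.01, 0.1, 1.0, 10.0])
    rows = []
    for i in range(4):
        rows.append(dict(plate_id="D0", well=f"A{i+1:02d}", model_id="m1", drug_id="",
                         dose_uM=0.0, role="day0", bio_rep=1, tech_rep=1,
                         luminescence=t0))
    rows.append(dict(plate_id="P1", well="A01", model_id="m1", drug_id="",
                     dose_uM=0.0, role="vehicle", bio_rep=1, tech_rep=1,
                     luminescence=t0 * k))
    for j, d in enumerate(doses):
        gr = float(truth.gr(d))
        rows.append(dict(plate_id="P1", well=f"B{j+1:02d}", model_id="m1",
                         drug_id="drugA", dose_uM=float(d), role="treated",
                         bio_rep=1, tech_rep=1,
                         luminescence=t0 * k ** np.log2(gr + 1.0)))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_screen():
    """A seeded 3-line x 4-drug screen with one drug of each archetype."""
    rng = np.random.default_rng(42)
    lines = []
    for i, dt in enumerate([3.5, 5.0, 7.5]):
        truths = {
            "inertX": None,
            "weakY": DrugTruth(0.8, float(rng.uniform(0.1, 0.5)), 1.5),
            "stasisZ": DrugTruth(0.3, float(rng.uniform(0.1, 0.5)), 1.5),
            "toxW": DrugTruth(-0.8, float(rng.uniform(0.1, 0.5)), 1.5),
        }
        lines.append(LineTruth(f"m{i}", dt, ["TNBC", "HR+", "HER2+"][i], truths))
    return simulate_screen(lines, ScreenConfig(), seed=7)


@pytest.fixture(scope="session")
def small_metrics(small_screen):
    from grscreen.gr import score_screen

    return score_screen(small_screen.records)
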
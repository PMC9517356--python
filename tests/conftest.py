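import numpy as np
import pandas as pd
import pytest

from comoscore import load_map
from comoscore.io import Cohort, EpisodeRecord


@pytest.fixture(scope="session")
def charlson_map():
    return load_map("charlson")


@pytest.fixture(scope="session")
def elixhauser_map():
    return load_map("elixhauser")


@pytest.fixture
def toy_cohort():
    """Six hand-built episodes covering deaths, an obstetric case and a child."""
    eps = [
        EpisodeRecord("e1", 72, "male", False, 4, ("J189", "I500", "E119")),
        EpisodeRecord("e2", 80, "female", True, 10, ("A090", "C780", "C509")),
        EpisodeRecord("e3", 56, "male", False, 2, ("K358",)),
        EpisodeRecord("e4", 30, "female", False, 3, ("O800",), obstetric_flag=True),
        EpisodeRecord("e5", 10, "male", False, 1, ("J189",)),
        EpisodeRecord("e6", 65, "female", True, 7, ("R073", "I10", "E669")),
    ]
    return Cohort(episodes=eps)


def wide_frame(rows):
    """Build a wide-layout episode DataFrame from (id, age, sex, death, los, obst, codes)."""
    recs = []
    for eid, age, sex, death, los, obst, codes in rows:
        rec = {
            "episode_id": eid, "age": age, "sex": sex, "death": death,
            "length_of_stay": los, "obstetric_flag": obst, "year": 2020,
            "dx_main": codes[0],
        }
        for i, c in enumerate(codes[1:], start=1):
            rec[f"dx_sec_{i:02d}"] = c
        recs.append(rec)
    return pd.DataFrame(recs)


@pytest.fixture
def wide_csv(tmp_path):
    def _write(rows, name="episodes.csv"):
        path = tmp_path / name
        wide_frame(rows).to_csv(path, index=False)
        return path

    return _write


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220907)
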
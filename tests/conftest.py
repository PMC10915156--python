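import pandas as pd
import pytest

from dyadlink import SimulationParams, score_dyad_table, simulate_dyads


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    return SimulationParams(n_pairs=1500, seed=11)


@pytest.fixture(scope="session")
def scored_table(default_params) -> pd.DataFrame:
    """A scored synthetic cohort with default (study-like) settings."""
    return score_dyad_table(simulate_dyads(default_params))


@pytest.fixture(scope="session")
def complete_scored_table() -> pd.DataFrame:
    """A fully observed scored cohort (no missingness, all parents)."""
    params = SimulationParams(
        n_pairs=2000, seed=23, missing_rate=0.0,
        mother_available=1.0, father_available=1.0,
    )
    return score_dyad_table(simulate_dyads(params))


def expand_counts(cells: dict[tuple[float, float], int]) -> pd.DataFrame:
    """Expand {(x, y): count} into one row per observation."""
    rows = []
    for (x, y), n in cells.items():
        rows.extend({"x": x, "y": y} for _ in range(n))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def marital_by_loneliness() -> pd.DataFrame:
    """The published 2x2 split of marital status by offspring
    loneliness (not lonely: 581 married / 126 single; lonely: 178
    married / 106 single), expanded to rows."""
    return expand_counts(
        {
            (1.0, 0.0): 581,
            (0.0, 0.0): 126,
            (1.0, 1.0): 178,
            (0.0, 1.0): 106,
        }
    ).rename(columns={"x": "marital", "y": "lonely"})
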
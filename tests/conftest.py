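import warnings

import numpy as np
import pandas as pd
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


def balanced_table(
    n_per_cell: int,
    n_participants: int = 1,
    n_items: int = 4,
    group: str = "HC",
    rt: float = 600.0,
) -> pd.DataFrame:
    """Fully crossed congruency x proportion table, one row per trial."""
    rows = []
    for p in range(n_participants):
        for c in ("congruent", "incongruent"):
            for b in ("MC", "MI"):
                for t in range(n_per_cell):
                    rows.append(
                        {
                            "participant_id": f"s{p:02d}",
                            "group": group,
                            "item_id": f"i{t % n_items}",
                            "congruency": c,
                            "proportion_condition": b,
                            "rt_ms": rt,
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def recovery_design():
    """8 participants x 160 trials (40 per cell), one group, 4 items."""
    return balanced_table(40, n_participants=8)


@pytest.fixture
def small_montage():
    return ("Fz", "FC1", "FCz", "FC2", "Cz", "Pz")
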
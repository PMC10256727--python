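import numpy as np
import pandas as pd
import pytest

from refstab.ct_io import CtMatrix, ct_to_quantity
from refstab.synthetic import study_like_config, simulate_ct


def make_ct(data: dict[str, list[float]], days=None, body_parts=None, colonies=None) -> CtMatrix:
    """Build a CtMatrix from per-gene Ct lists with generated metadata."""
    n = len(next(iter(data.values())))
    samples = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "colony": colonies or ["c1"] * n,
            "body_part": body_parts or ["head"] * n,
            "day": days or [f"d{i}" for i in range(n)],
        }
    ).set_index("sample_id")
    ct = pd.DataFrame(data, index=samples).T
    return CtMatrix(ct, meta)


@pytest.fixture
def toy_ct() -> CtMatrix:
    """Three-gene hand toy: G1 = G2 rising one cycle per sample, G3 constant."""
    return make_ct(
        {"G1": [20, 21, 22, 23], "G2": [20, 21, 22, 23], "G3": [20, 20, 20, 20]}
    )


@pytest.fixture
def toy_q(toy_ct) -> pd.DataFrame:
    return ct_to_quantity(toy_ct)  # E = 2 for all genes


@pytest.fixture(scope="session")
def study_dataset():
    """One frozen draw of the default simulation scenario."""
    cfg = study_like_config()
    return simulate_ct(cfg)


@pytest.fixture(scope="session")
def random_ct_matrices():
    """100 random 8 x 40 Ct matrices (shared across cross-method checks)."""
    rng = np.random.default_rng(20230609)
    mats = []
    for _ in range(100):
        vals = rng.uniform(18, 32, size=(8, 40))
        mats.append(
            make_ct({f"g{i}": vals[i].tolist() for i in range(8)},
                    days=[f"d{j % 5}" for j in range(40)])
        )
    return mats
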
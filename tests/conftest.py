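import numpy as np
import pytest

from cattletemp.efa import FactorStructure
from cattletemp.synthetic import (
    REFERENCE_LOADINGS,
    simulate_measurement_observations,
    simulate_pedigree,
)


@pytest.fixture(scope="session")
def reference_structure() -> FactorStructure:
    """The two-factor, cross-loading-free confirmatory structure."""
    return FactorStructure(
        {t: f for t, (f, _) in REFERENCE_LOADINGS.items()},
        ["difficult", "easy"],
        {"difficult": "ts", "easy": "calm"},
    )


@pytest.fixture(scope="session")
def measurement_data():
    """n = 1,528 draws from the reference two-factor measurement model."""
    return simulate_measurement_observations(1528, seed=42)


@pytest.fixture(scope="session")
def small_pedigree():
    """Three-generation pedigree of ~50 animals."""
    return simulate_pedigree(10, 2, 10, 2, seed=11)


def random_pedigree_records(rng: np.random.Generator, n: int):
    """Random valid (animal, sire, dam) records, parents drawn from earlier animals."""
    records = []
    for i in range(n):
        if i < 2 or rng.random() < 0.3:
            records.append((f"a{i}", "0", "0"))
        else:
            s, d = rng.choice(i, size=2, replace=False)
            # occasionally leave one parent unknown
            sire = f"a{s}" if rng.random() < 0.9 else "0"
            dam = f"a{d}" if rng.random() < 0.9 else "0"
            records.append((f"a{i}", sire, dam))
    return records


def kinship_oracle(records) -> np.ndarray:
    """Brute-force numerator relationships by recursive coancestry.

    Independent of the tabular method: A_ij = 2 f(i, j) with the classic
    kinship recursion f(i,i) = (1 + f(s_i, d_i))/2 and, for i listed after j,
    f(i,j) = (f(s_i, j) + f(d_i, j))/2; unknown parents contribute 0.
    """
    ids = [a for a, _, _ in records]
    pos = {a: i for i, a in enumerate(ids)}
    parents = {pos[a]: (pos.get(s, -1), pos.get(d, -1)) for a, s, d in records}

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            s, d = parents[i]
            return 0.5 * (1.0 + f(*sorted((s, d))))
        if i < j:
            i, j = j, i
        s, d = parents[i]
        return 0.5 * (f(*sorted((s, j))) + f(*sorted((d, j))))

    n = len(ids)
    return np.array([[2 * f(*sorted((i, j))) for j in range(n)] for i in range(n)])
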
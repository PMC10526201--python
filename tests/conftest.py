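import numpy as np
import pytest

from ntcpkit import DifferentialDVH


def random_dvh(rng: np.random.Generator, structure: str = "liver_minus_gtv",
               max_bins: int = 30, max_dose: float = 80.0) -> DifferentialDVH:
    """Random valid differential DVH: sorted distinct doses, >=1 nonzero volume."""
    n = int(rng.integers(2, max_bins + 1))
    doses = np.sort(rng.uniform(0.0, max_dose, size=n))
    doses = np.unique(np.round(doses, 6))
    while doses.size < 2:
        doses = np.unique(np.round(np.sort(rng.uniform(0.0, max_dose, size=n)), 6))
    vols = rng.uniform(0.0, 50.0, size=doses.size)
    vols[int(rng.integers(0, doses.size))] += 1.0  # guarantee nonzero volume
    return DifferentialDVH(structure, doses, vols, float(vols.sum()))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
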
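import numpy as np
import pandas as pd
import pytest

from cuniqg.pedigree import Pedigree, pedigree_from_frame
from cuniqg.simulate import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """~1,000-kit two-environment population with all trait blocks."""
    cfg = SimulationConfig(
        n_sires=30, n_dams=90, litters_per_dam=2, kits_per_litter=6,
        n_batches=8, seed=42,
    )
    ped, pheno, tv = simulate_population(cfg)
    return cfg, ped, pheno, tv


@pytest.fixture()
def trio_pedigree():
    df = pd.DataFrame({
        "animal_id": ["S1", "D1", "O1"],
        "sire_id": ["0", "0", "S1"],
        "dam_id": ["0", "0", "D1"],
        "sex": ["M", "F", "M"],
    })
    return pedigree_from_frame(df)


def random_pedigree(n, seed, n_founders=10):
    """Random-mating pedigree with overlapping generations and inbreeding."""
    rng = np.random.default_rng(seed)
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    sex = np.array(["M", "F"] * (n // 2 + 1), dtype=object)[:n]
    for i in range(n_founders, n):
        males = [j for j in range(i) if sex[j] == "M"]
        females = [j for j in range(i) if sex[j] == "F"]
        if males and females:
            sire[i] = rng.choice(males)
            dam[i] = rng.choice(females)
    return Pedigree(
        ids=np.array([f"a{i}" for i in range(n)], dtype=object),
        sire=sire, dam=dam, sex=sex,
    )
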
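import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import stresspanel as sp
from stresspanel.config import STRESSES
from stresspanel.synthdata import GeneSpec, SimulationConfig

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_genes(markers_per_stress: int = 2, effect: float = 2.0) -> list[GeneSpec]:
    """Compact panel: 3 references + a few shared-responder markers per stress."""
    genes = [
        GeneSpec("ACT", 21.0, is_reference=True),
        GeneSpec("TIF", 22.0, is_reference=True),
        GeneSpec("TIF-GTP", 23.0, is_reference=True),
    ]
    for stress in STRESSES:
        for j in range(markers_per_stress):
            direction = "up" if j % 2 == 0 else "down"
            e = effect if direction == "up" else -effect
            genes.append(
                GeneSpec(
                    f"{stress}_{direction}{j}",
                    24.0 + j,
                    expected_direction=direction,
                    stresses=(stress,),
                    mapman_bin="stress" if j % 2 else "protein metabolism",
                    effects={stress: (e, e)},
                )
            )
    return genes


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    defaults = dict(
        genes=small_genes(),
        variety_archetypes={
            "V01": "tolerant",
            "V02": "sensitive",
            "V03": "tolerant",
            "V04": "sensitive",
        },
        stress_intensity={
            "SiteA": {s: 1.0 for s in STRESSES},
            "SiteB": {s: 0.6 for s in STRESSES},
        },
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def noise_free_dataset() -> sp.CqDataset:
    return sp.simulate_experiment(
        sp.default_simulation_config(seed=11, sd_bio=0.0, sd_tech=0.0)
    )


@pytest.fixture(scope="session")
def noise_free_results(noise_free_dataset):
    model = sp.StressArrayModel.from_simulation(noise_free_dataset)
    return model.fit(run_stats=False)


@pytest.fixture(scope="session")
def noisy_dataset() -> sp.CqDataset:
    return sp.simulate_experiment(sp.default_simulation_config(seed=7))


def make_ratio_table(rows) -> pd.DataFrame:
    """Ratio-summary rows: (gene_id, variety, location, mean) tuples or dicts."""
    out = []
    for r in rows:
        if not isinstance(r, dict):
            r = dict(zip(("gene_id", "variety", "location", "log2_ratio_mean"), r))
        r.setdefault("treatment", "stressed")
        r.setdefault("control_ref", "tolerant_control")
        r.setdefault("log2_ratio_sd", 0.1)
        r.setdefault("n_bio", 3)
        r.setdefault("significant", True)
        out.append(r)
    return pd.DataFrame(out)
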
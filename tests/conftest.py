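import numpy as np
import pandas as pd
import pytest

from mitonuclear import (
    SimulationParams,
    Strain,
    StrainPanel,
    example_panel,
    simulate_fitness_observations,
    simulate_true_fitness,
)


def make_panel(clades: dict[str, int], prefix: str = "S") -> StrainPanel:
    """Panel with the given clade-size composition, e.g. {'A': 2, 'B': 2}."""
    strains = []
    i = 0
    for clade, n in clades.items():
        for _ in range(n):
            sid = f"{prefix}{i}"
            strains.append(Strain(sid, sid, sid, clade))
            i += 1
    return StrainPanel(strains=strains, reference_strain_id="REF")


def fitness_frame(records) -> pd.DataFrame:
    """Build a FitnessTable from (nuclear, mitotype, env, bio, tech, fitness) tuples."""
    return pd.DataFrame(
        records,
        columns=["nuclear_id", "mitotype_id", "environment_id", "bio_rep", "tech_rep", "fitness"],
    )


def simulated_fitness(seed, proportions=(0.0, 0.4, 0.2, 0.4), reps=3, total_var=0.04,
                      media=("CSM",), temperatures=(30,), panel=None):
    """One-environment replicate-level fitness table with known variance structure."""
    params = SimulationParams(seed=seed, media=media, temperatures=temperatures)
    params = params.with_variance_proportions(*proportions, total=total_var)
    truth = simulate_true_fitness(params, panel)
    obs = simulate_fitness_observations(truth, params, reps=reps, seed=seed + 10_000)
    return truth, obs


@pytest.fixture(scope="session")
def paper_scale_panel() -> StrainPanel:
    return example_panel()


@pytest.fixture(scope="session")
def small_fitness():
    """15x15 single-environment fitness table, proportions (0, .4, .2, .4), r=3."""
    _, obs = simulated_fitness(seed=11)
    return obs
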
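import numpy as np
import pytest

from phewaskit.simulate import CodeSpec, SimulationConfig, SnpSpec, simulate_cohort


def small_config(**overrides) -> SimulationConfig:
    base = dict(
        n_samples=1500,
        snp_specs=[SnpSpec(f"rs{i}", 0.2) for i in range(4)],
        code_specs=[
            CodeSpec("272.1", 0.10, effects=[("rs0", 2.0)]),
            CodeSpec("272.4", 0.08),
            CodeSpec("250.00", 0.15),
            CodeSpec("401.1", 0.20),
        ],
        sites={"siteA": 0.5, "siteB": 0.3, "siteC": 0.2},
        platforms={"chip1": 0.6, "chip2": 0.4},
        ancestry_groups={"EA": 0.8, "AA": 0.2},
        n_background_snps=200,
        background_structure_sd=0.05,
        epsilon_undercount=0.05,
        delta_ruleout=0.02,
        related_pairs=[("duplicate", 1), ("full_sib", 1)],
        seed=7,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """A 1500-sample cohort with one planted effect, confounder structure,
    and one duplicate plus one sibling pair."""
    return simulate_cohort(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
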
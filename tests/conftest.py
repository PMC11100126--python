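import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def filter_fixture():
    """Ten-variant toy genotype table with constructed call rates and MAFs.

    Variant j is a column of n=2000 dosages: ``het[j]`` heterozygotes among
    the non-missing individuals, the rest homozygous reference, and
    ``miss[j]`` missing entries.  Expected survivors under the standard
    (call rate 0.90, MAF 0.001) and stringent (0.99, 0.01) filters were
    counted by hand from the table below.
    """
    from prseval.synth import GenotypeMatrix

    n = 2000
    #        id    miss  het    call rate   MAF
    table = [
        ("v0", 0, 800),     # 1.000      0.2000
        ("v1", 0, 20),      # 1.000      0.0050
        ("v2", 0, 2),       # 1.000      0.0005
        ("v3", 100, 1140),  # 0.950      0.3000
        ("v4", 300, 1020),  # 0.850      0.3000
        ("v5", 10, 199),    # 0.995      0.0500
        ("v6", 200, 540),   # 0.900      0.1500
        ("v7", 20, 792),    # 0.990      0.2000
        ("v8", 0, 40),      # 1.000      0.0100
        ("v9", 400, 2),     # 0.800      0.000625
    ]
    dosages = np.zeros((n, len(table)))
    for j, (_, miss, het) in enumerate(table):
        dosages[:het, j] = 1.0
        if miss:
            dosages[n - miss:, j] = np.nan
    g = GenotypeMatrix(
        dosages=dosages,
        variant_ids=np.array([t[0] for t in table]),
        effect_alleles=np.array(["A"] * len(table)),
        other_alleles=np.array(["G"] * len(table)),
        sample_ids=np.array([f"s{i}" for i in range(n)]),
        population_labels=np.array(["train"] * n),
    )
    expected_primary = {"v0", "v1", "v3", "v5", "v6", "v7", "v8"}
    expected_stringent = {"v0", "v5", "v7", "v8"}
    return g, expected_primary, expected_stringent


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-population cohort shared by several tests."""
    from prseval.synth import ArchitectureSpec, PopulationSpec, simulate_cohort

    pops = [
        PopulationSpec("train_pop", 800),
        PopulationSpec(
            "target", 300, fst=0.1, effect_correlation=0.9, env_shift=-1.0
        ),
    ]
    arch = ArchitectureSpec(
        m=400, causal_fraction=0.05, heritability=0.5, missing_rate=0.01,
        seed=77,
    )
    return simulate_cohort(pops, arch)
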
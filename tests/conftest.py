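import pytest

from plastokit.synthetic_plastome import SimulationParams, mutate_genome, simulate_plastome


def small_params(seed: int, **overrides) -> SimulationParams:
    """Compact genome (~26 kb) for fast unit tests; structure unchanged."""
    defaults = dict(
        lsc_len=12_000,
        ssc_len=4_000,
        ir_len=5_000,
        n_cds=6,
        n_trna=3,
        n_rrna=1,
        intron_genes=2,
        include_trans_spliced=True,
        ssr_plants=[
            ("A", 10, "LSC"),
            ("T", 12, "LSC"),
            ("AT", 5, "SSC"),
            ("AAT", 4, "LSC"),
            ("AATGCC", 3, "LSC"),
        ],
        n_substitutions={"LSC": 60, "SSC": 20, "IR": 8},
        n_indels={"LSC": 2, "SSC": 1, "IR": 1},
    )
    defaults.update(overrides)
    return SimulationParams(seed=seed, **defaults)


@pytest.fixture(scope="session")
def small_genome():
    """(record, truth, params) for a compact synthetic plastome."""
    params = small_params(seed=11)
    record, truth = simulate_plastome(params)
    return record, truth, params


@pytest.fixture(scope="session")
def small_pair(small_genome):
    """Compact genome plus its mutated partner."""
    record, truth, params = small_genome
    mutated, mut_truth = mutate_genome(record, truth, params)
    return record, truth, mutated, mut_truth, params


@pytest.fixture(scope="session")
def study_pair():
    """Full-size (~152 kb) genome pair under the default study conditions."""
    params = SimulationParams(seed=2026)
    record, truth = simulate_plastome(params)
    mutated, mut_truth = mutate_genome(record, truth, params)
    return record, truth, mutated, mut_truth, params
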
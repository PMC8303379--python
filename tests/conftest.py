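import pytest

from immlncnet.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def two_arm_experiment():
    """Default-strength simulation on the two vehicle arms (18 samples)."""
    cfg = SimulationConfig(seed=1, arms=("WT_vehicle", "KO_vehicle"))
    mat, ann, sigs, truth = simulate_experiment(cfg)
    return cfg, mat, ann, sigs, truth


@pytest.fixture(scope="session")
def small_experiment():
    """Scaled-down three-arm simulation for pipeline-level tests."""
    cfg = SimulationConfig(
        seed=3,
        n_pc_genes=660,
        n_lnc_genes=120,
        markers_per_celltype=3,
        n_imm_lnc=4,
    )
    mat, ann, sigs, truth = simulate_experiment(cfg)
    return cfg, mat, ann, sigs, truth
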
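import numpy as np
import pytest

from hiberseq.clustering import DEFAULT_TEMPLATES
from hiberseq.config import SimulationConfig
from hiberseq import simulate as sim


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def design(default_config):
    return sim.gen_design(default_config)


@pytest.fixture(scope="session")
def planted_bundle():
    """1000 genes: 60 per template x 10 templates + 400 null, seed fixed."""
    fractions = {name: 0.06 for name in DEFAULT_TEMPLATES}
    cfg = SimulationConfig(seed=11, n_genes=1000, cluster_fractions=fractions)
    design = sim.gen_design(cfg)
    counts, truth = sim.gen_counts(design, cfg)
    return cfg, design, counts, truth


@pytest.fixture(scope="session")
def null_lsv_bundle():
    cfg = SimulationConfig(seed=7)
    design = sim.gen_design(cfg)
    templates = [sim.LsvTemplate("null", np.tile([0.5, 0.5], (6, 1)))]
    table, truth = sim.gen_lsv_counts(design, 40, templates, 100, cfg)
    return cfg, design, table, truth
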
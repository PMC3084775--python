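import numpy as np
import pytest
from hypothesis import settings

import jawfem as jf
from jawfem.sensitivity import ModelConfig, ModelRunner, run_all_sweeps

settings.register_profile("det", derandomize=True, deadline=None,
                          max_examples=50)
settings.load_profile("det")


@pytest.fixture(scope="session")
def runner():
    """Shared model runner: meshes and stiffness matrices are cached."""
    return ModelRunner()


@pytest.fixture(scope="session")
def mandible_l1(runner):
    """Coarse (refine_level 1) default mandible."""
    return runner.mesh(1)


@pytest.fixture(scope="session")
def mandible_base(runner):
    """Base-configuration mandible (refine_level 2)."""
    return runner.mesh(2)


@pytest.fixture(scope="session")
def base_solution(runner):
    """Base-configuration solved model (record, result, mesh, extras)."""
    return runner.solve(ModelConfig())


@pytest.fixture(scope="session")
def all_sweeps(runner):
    """All seven sensitivity sweeps at the base configuration."""
    return run_all_sweeps(runner=runner)


@pytest.fixture(scope="session")
def beam_solution():
    """Cantilever fixture solve used by several energy/stress checks."""
    mesh = jf.build_beam_fixture(100.0, 10.0, 10.0, 4)
    mats = jf.homogeneous_table(mesh, 20.0, 0.3)
    K = jf.assemble(mesh, mats)
    cs = jf.ConstraintSet()
    cs.fix_nodes(mesh.node_sets["fixed_end"])
    loads = np.zeros((mesh.n_nodes, 3))
    tip = mesh.node_sets["tip"]
    loads[tip, 2] = -10.0 / len(tip)
    result = jf.solve_static(K, loads, cs)
    return mesh, mats, K, loads, result
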
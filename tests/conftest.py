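import pytest

from protstab import make_toy_structure
from protstab.pipeline import train
from protstab.sdm import build_esst
from protstab.synthetic import (BENCHMARK_MCSM_PARAMS, make_esst_observations,
                                make_synthetic_training_set)


@pytest.fixture(scope="session")
def mini_helix():
    """12-residue polyalanine ideal helix, 60 atoms; the module-wide fixture."""
    return make_toy_structure("helix", 12, "A" * 12, seed=1, structure_id="mini_helix")


@pytest.fixture()
def mini_helix_pdb(tmp_path):
    path = tmp_path / "mini_helix.pdb"
    make_toy_structure("helix", 12, "A" * 12, seed=1, path=str(path))
    return str(path)


@pytest.fixture(scope="session")
def demo_esst():
    return build_esst(make_esst_observations(seed=0), pseudocount=1.0)


@pytest.fixture(scope="session")
def tiny_predictor(tmp_path_factory):
    """A trained bundle on a small synthetic set with fixed hyperparameters."""
    out_dir = tmp_path_factory.mktemp("tiny_model")
    table, _truth = make_synthetic_training_set(80, seed=3, noise_sd=0.3,
                                                out_dir=str(out_dir))
    predictor = train(table, seed=3,
                      mcsm_hyperparams=dict(BENCHMARK_MCSM_PARAMS),
                      consensus_hyperparams={"C": 10.0, "gamma": 0.01, "epsilon": 0.1})
    return predictor, table, str(out_dir)
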
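import warnings

import pytest

from mabdev.conditions import FormulationCondition
from mabdev.pipeline import RunConfig, run_analyze, run_simulate


@pytest.fixture
def cond():
    return FormulationCondition("mAb-X", 6.0, 0.0)


@pytest.fixture(scope="session")
def study_outputs(tmp_path_factory):
    """Simulate and analyse the full built-in 75-sample study panel once."""
    base = tmp_path_factory.mktemp("study")
    cfg = RunConfig(panel_dir=str(base / "panel"), output_dir=str(base / "out"),
                    seed=11)
    run_simulate(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        outputs = run_analyze(cfg)
    return outputs
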
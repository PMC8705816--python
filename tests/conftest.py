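import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from bifiphage.pipeline import PipelineConfig, run_pipeline
from bifiphage.synthetic import Dataset, GeneratorConfig, generate_dataset

#: Fixed study seed for the synthetic-recovery suite.
STUDY_SEED = 7


@pytest.fixture(scope="session")
def default_dataset() -> Dataset:
    """The default 20-genome study dataset (mutation-free)."""
    return generate_dataset(GeneratorConfig(seed=STUDY_SEED, n_genomes=20))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run on the default study dataset."""
    out = tmp_path_factory.mktemp("pipeline20")
    cfg = PipelineConfig(outdir=str(out), generator=GeneratorConfig(seed=STUDY_SEED, n_genomes=20))
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def determinism_runs(tmp_path_factory):
    """Two independent pipeline runs with the same small config and seed."""
    dirs = []
    for tag in ("detA", "detB"):
        out = tmp_path_factory.mktemp(tag)
        cfg = PipelineConfig(outdir=str(out), generator=GeneratorConfig(seed=5, n_genomes=3))
        run_pipeline(cfg)
        dirs.append(Path(out))
    return tuple(dirs)
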
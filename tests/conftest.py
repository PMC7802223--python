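import pathlib

import pytest

from cernakit import SimulationConfig, simulate_dataset, write_fixture
from cernakit.pipeline_io import PipelineConfig


# small but large enough that the shared-miRNA universe exceeds 20, so a
# single shared sponge miRNA can reach p < 0.05 (p = 1/N for k=K=n=1)
SMALL_KW = dict(
    n_per_group=3,
    n_circ=30,
    n_mirna=40,
    n_mrna=60,
    n_de_per_class=25,
    n_triads=3,
    n_decoys=20,
    seed=7,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(**SMALL_KW)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_fixture_dir(small_dataset, tmp_path_factory) -> pathlib.Path:
    directory = tmp_path_factory.mktemp("fixture")
    write_fixture(small_dataset, directory)
    return directory


def make_pipeline_config(fixture_dir: pathlib.Path, out_dir: pathlib.Path, **overrides):
    kw = dict(
        counts_circ=str(fixture_dir / "counts_circRNA.tsv"),
        counts_mirna=str(fixture_dir / "counts_miRNA.tsv"),
        counts_mrna=str(fixture_dir / "counts_mRNA.tsv"),
        samples=str(fixture_dir / "samples.tsv"),
        mirna_fasta=str(fixture_dir / "mirna.fasta"),
        target_fasta=str(fixture_dir / "targets.fasta"),
        out_dir=str(out_dir),
    )
    kw.update(overrides)
    return PipelineConfig(**kw)
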
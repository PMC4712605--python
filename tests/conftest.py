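import pytest

from ribodrug.pipeline import load_bundle
from ribodrug.simulate import (
    SimConfig,
    generate_transcriptome,
    simulate_profiles,
    write_fixture_bundle,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_coding=40, n_lncrna=20, n_snorna=10, seed=1)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(transcripts, truth, profile frame) for a small synthetic experiment."""
    transcripts, truth = generate_transcriptome(small_cfg)
    profiles = simulate_profiles(transcripts, truth, small_cfg)
    return transcripts, truth, profiles


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_cfg, small_sim):
    """On-disk fixture bundle (with SAM) for the small experiment."""
    transcripts, truth, profiles = small_sim
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_fixture_bundle(
        transcripts, profiles, truth, outdir, config=small_cfg, write_sam=True
    )
    return outdir, paths


@pytest.fixture(scope="session")
def small_loaded(small_bundle):
    outdir, _ = small_bundle
    return load_bundle(outdir)
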
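import pytest

from hapcull.synthetic_data import SimConfig, generate


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic genome: seed 42, 10 primary scaffolds,
    3 haplotigs at 1% divergence with inversion_prob 1.0."""
    return generate(SimConfig(seed=42))


@pytest.fixture(scope="session")
def sim_dir(default_sim, tmp_path_factory):
    """Default synthetic genome written to disk once per session."""
    outdir = tmp_path_factory.mktemp("simdata")
    paths = default_sim.write(outdir)
    return outdir, paths
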
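import numpy as np
import pytest

from holopop import synth
from holopop.gl import GLMatrix


def make_certain_gl(genotypes, positions=None, sample_ids=None) -> GLMatrix:
    """GLMatrix with error-free, fully-covered entries (one-hot likelihoods
    on the linear scale; big negative log10 elsewhere)."""
    genotypes = np.asarray(genotypes)
    S, N = genotypes.shape
    gl = np.full((S, N, 3), -30.0)
    for g in (0, 1, 2):
        gl[:, :, g][genotypes == g] = 0.0
    return GLMatrix(
        gl=gl,
        mask=np.zeros((S, N), dtype=bool),
        positions=np.arange(S) if positions is None else np.asarray(positions),
        sample_ids=(
            [f"s{i}" for i in range(N)] if sample_ids is None else sample_ids
        ),
        depth=np.full((S, N), 30),
        minor_count=np.asarray(genotypes) * 15,
    )


@pytest.fixture(scope="session")
def host_sim():
    """One small three-cluster simulation shared across tests."""
    cfg = synth.HostSimConfig(
        n_pops=3, sample_sizes=(8, 8, 8), nu=(1.0, 1.0, 1.0), T_div=2.0,
        theta=900.0, seq_length=2e6, n_chunks=50, seed=11,
    )
    return cfg, synth.simulate_host_genotypes(cfg)


@pytest.fixture(scope="session")
def reads_5x(host_sim):
    cfg, (geno, sfs, pos, pops) = host_sim
    rc = synth.ReadSimConfig(
        mean_depth=5.0, error_rate=0.01, n_clone_groups=2,
        n_tech_replicates=3, seed=7,
    )
    return synth.simulate_reads_and_gls(geno, rc, pos)
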
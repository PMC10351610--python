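import numpy as np
import pytest

import spica


@pytest.fixture(scope="session")
def small_synth():
    """Default planted-module fixture: 3 blocks, 4 modules, SNR ~5."""
    return spica.generate(seed=11)


@pytest.fixture(scope="session")
def noiseless_synth():
    return spica.generate(noise_sd=0.0, seed=7)


@pytest.fixture
def tiny_blocks():
    """Three tiny hand-built blocks sharing samples b, c."""
    rng = np.random.default_rng(0)

    def mk(name, feats, samples):
        return spica.OmicsBlock(name, feats, samples,
                                rng.random((len(feats), len(samples))))

    return [
        mk("mRNA", ["g1", "g2", "g3", "g4"], ["a", "b", "c"]),
        mk("miRNA", ["m1", "m2"], ["b", "c", "d"]),
        mk("lncRNA", ["l1", "l2", "l3"], ["b", "c"]),
    ]


def grouped_points(seed, n_groups=2, n_per=3, spread=0.3, sep=8.0, dim=3):
    """Well-separated point groups; the regime where affinity propagation
    reliably attains the global optimum of its energy."""
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((n_groups, dim)) * sep
    pts = np.vstack([c + rng.normal(0, spread, (n_per, dim)) for c in centers])
    labels = np.repeat(np.arange(n_groups), n_per)
    return pts, labels
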
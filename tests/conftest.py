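import numpy as np
import pytest

import rhizoindic as ri


@pytest.fixture(scope="session")
def small_taxonomy():
    return ri.generate_taxonomy(300, unclassified_fraction=0.3, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_taxonomy):
    """A 3-pair experiment with one abundant clearly-identified taxon
    quadrupled in the treated samples."""
    base = ri.draw_abundances(300, lognormal_sigma=2.0, seed=12)
    target = ri.pick_specific_taxon(small_taxonomy, base, 0.10)
    base = ri.set_proportion(base, target, 0.10)
    truth = ri.GroundTruth(base_proportions=base, effects={target: 4.0}, seed=13)
    exp = ri.sample_experiment(
        truth, small_taxonomy, depth_per_sample=5000, n_pairs=3, seed=14
    )
    exp.target_index = target
    return exp


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
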
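import numpy as np
import pytest

from tsmr import SimConfig, simulate_two_sample, harmonize_panels
from tsmr.harmonize import HarmonizedInstrument, HarmonizedSet
from tsmr.simulate import PleiotropyConfig


def make_hset(g, sx, G, sy, ids=None, name="exposure", outcome="outcome"):
    """Build a harmonized set directly from effect arrays (test helper)."""
    g, sx, G, sy = map(np.asarray, (g, sx, G, sy))
    ids = ids or [f"rs{i}" for i in range(len(g))]
    hset = HarmonizedSet(name, outcome)
    for i in range(len(g)):
        hset.instruments.append(
            HarmonizedInstrument(
                snp_id=ids[i],
                beta_exp=float(g[i]),
                se_exp=float(sx[i]),
                beta_out=float(G[i]),
                se_out=float(sy[i]),
                eaf_exp=0.3,
                eaf_out=0.3,
                palindromic=False,
                action="kept",
            )
        )
    return hset


def sim_hset(seed, beta=0.3, **kwargs):
    """Simulate one two-sample dataset and harmonize it."""
    res = simulate_two_sample(SimConfig(beta_causal=beta, seed=seed, **kwargs))
    return harmonize_panels(res.exposure, res.outcome)


@pytest.fixture
def clean_hset():
    """A clean 10-instrument set with true causal effect 0.3."""
    return sim_hset((11, 0), beta=0.3)


@pytest.fixture
def pleiotropy_config():
    return PleiotropyConfig
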
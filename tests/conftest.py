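import numpy as np
import pandas as pd
import pytest

from mrkit import SimConfig, SumStatsTable, harmonise, simulate_pair
from mrkit.sumstats import HarmonisedSet


def make_table(rows, label="trait", trait_type="continuous", **kw):
    """Build a SumStatsTable from a list of dicts (test shorthand)."""
    return SumStatsTable(
        trait_label=label, trait_type=trait_type, records=pd.DataFrame(rows), **kw
    )


def make_harmonised(beta_exp, se_exp, beta_out, se_out, eaf=None, rsid=None):
    """Direct HarmonisedSet construction from arrays."""
    beta_exp = np.asarray(beta_exp, float)
    k = len(beta_exp)
    return HarmonisedSet(
        exposure_label="x",
        outcome_label="y",
        rsid=np.array(rsid if rsid is not None else [f"rs{i}" for i in range(k)]),
        beta_exp=beta_exp,
        se_exp=np.asarray(se_exp, float),
        beta_out=np.asarray(beta_out, float),
        se_out=np.asarray(se_out, float),
        eaf_exp=np.asarray(eaf, float) if eaf is not None else np.full(k, 0.3),
        dropped=pd.DataFrame(columns=["rsid", "reason"]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def sim_pair():
    """A null simulated exposure/outcome pair with CRC-like outcome."""
    return simulate_pair(SimConfig(theta=0.0, seed=1234))


@pytest.fixture
def sim_harmonised(sim_pair):
    exposure, outcome, _ = sim_pair
    return harmonise(exposure, outcome)


def random_harmonised(rng, k=10):
    """A random, well-conditioned harmonised set for property tests."""
    beta_exp = rng.normal(0.1, 0.05, k)
    beta_exp[np.abs(beta_exp) < 1e-3] = 0.05
    return make_harmonised(
        beta_exp=beta_exp,
        se_exp=rng.uniform(0.005, 0.02, k),
        beta_out=rng.normal(0.0, 0.05, k),
        se_out=rng.uniform(0.005, 0.05, k),
        eaf=rng.uniform(0.05, 0.95, k),
    )
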
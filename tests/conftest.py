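import numpy as np
import pandas as pd
import pytest

from hydroxycall import sim, singlebase


@pytest.fixture(scope="session")
def small_truth() -> sim.TrueMethylome:
    """5k-CpG methylome with the default feature landscape and chemistry."""
    return sim.simulate_methylome(5000, seed=11)


@pytest.fixture(scope="session")
def small_calls(small_truth) -> pd.DataFrame:
    bis, oxbis = sim.simulate_bisoxbis_counts(small_truth, 30.0, seed=12)
    return singlebase.call_hmc(bis, oxbis)


@pytest.fixture(scope="session")
def null_truth() -> sim.TrueMethylome:
    """Methylome with no 5hmC anywhere (p_5hmC = 0 at every CpG)."""
    model = {
        f: {**cfg, "hmc_mean": 0.0}
        for f, cfg in sim.DEFAULT_LEVEL_MODEL.items()
    }
    return sim.simulate_methylome(5000, level_model=model, seed=13)


def make_calls_frame(deltas, pvals, positions=None, chrom="chrS", alpha=0.05):
    """Hand-built call table for rule tests (significance per the call rule)."""
    deltas = np.asarray(deltas, dtype=float)
    pvals = np.asarray(pvals, dtype=float)
    pos = np.asarray(positions if positions is not None else np.arange(len(deltas)) * 10)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "p_bis": np.clip(0.5 + deltas, 0, 1),
            "p_oxbis": 0.5,
            "delta": deltas,
            "p_value": pvals,
            "significant": (pvals < alpha) & (deltas > 0),
            "n_bis": 30,
            "n_oxbis": 30,
        }
    )
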
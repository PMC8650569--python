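import numpy as np
import pandas as pd
import pytest

from biofilmnet.simulate import default_scenario, simulate_counts


def make_table(levels, times=(0.0, 72.0), replicates=5, noise_sd=0.0,
               detection_limit=1e3, seed=0, context="full"):
    """Small count table with per-(species, time) expected levels.

    ``levels``: {species: level} (constant over time) or
    {species: {time: level}}.  Lognormal noise in log10 units; values below
    the detection limit are stored at the limit and flagged.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sp, lv in levels.items():
        for t in times:
            mu = lv[t] if isinstance(lv, dict) else lv
            for rep in range(1, replicates + 1):
                v = mu * 10 ** (noise_sd * rng.standard_normal())
                cens = v < detection_limit
                rows.append((context, sp, rep, float(t),
                             detection_limit if cens else v, cens,
                             detection_limit))
    return pd.DataFrame(rows, columns=[
        "context", "species", "replicate", "time_h", "cfu_per_cm2",
        "censored", "detection_limit"])


@pytest.fixture(scope="session")
def default_table():
    """One seeded simulation of the wild-type scenario (all contexts)."""
    return simulate_counts(default_scenario(seed=11))
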
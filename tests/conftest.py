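"""Shared fixtures: generated datasets are session-scoped to amortize cost."""

import numpy as np
import pandas as pd
import pytest

from phenobreed import linmod, synth


@pytest.fixture(scope="session")
def default_dataset() -> synth.TrialDataset:
    """One clean draw of the default two-study trial (no missing, no outliers)."""
    return synth.generate_trial(synth.default_config(seed=7))


@pytest.fixture(scope="session")
def default_blups(default_dataset) -> pd.DataFrame:
    return linmod.compute_blups(default_dataset)


def balanced_records(
    n_geno=4, n_env=3, n_rep=2, n_trt=2, mu=100.0, noise_sd=1.0, seed=0, study="S"
) -> pd.DataFrame:
    """A small balanced RCB frame with i.i.d. noise, for linear-model fixtures."""
    rng = np.random.default_rng(seed)
    rows = []
    for e in range(n_env):
        for r in range(n_rep):
            for g in range(n_geno):
                for t in range(n_trt):
                    rows.append(
                        {
                            "study": study,
                            "environment": f"E{e + 1}",
                            "replication": f"R{r + 1}",
                            "genotype": f"G{g + 1:02d}",
                            "treatment": f"T{t + 1}",
                            "seed_yield": mu + rng.normal(0, noise_sd),
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture
def balanced_dataset() -> synth.TrialDataset:
    return synth.TrialDataset(balanced_records(seed=3))
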
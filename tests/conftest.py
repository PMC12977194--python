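"""Shared fixtures: small synthetic datasets built once per session."""

import numpy as np
import pytest

from hglock.dataio import AnalysisConfig
from hglock.simulate import (SimulationConfig, SitePlanRow, SyntheticDataset,
                             simulate_dataset)


def small_site_plan():
    """Three sites per pattern over two participants (cheap end-to-end)."""
    plan = []
    combos = [("stimulus", "STGP"), ("behavior", "MFG"),
              ("intermediate", "MTGP"), ("none", "OG")] * 3
    for i, (pattern, roi) in enumerate(combos):
        plan.append(SitePlanRow(
            participant=f"sub-{i % 2 + 1:02d}",
            hemisphere="L" if i % 2 else "R", roi=roi,
            intended_pattern=pattern,
            post_burst_db=6.0 if pattern in ("stimulus", "intermediate") else 0.0,
            pre_burst_db=6.0 if pattern in ("behavior", "intermediate") else 0.0))
    return plan


@pytest.fixture(scope="session")
def small_sim_config():
    return SimulationConfig(rng_seed=4, n_participants=2,
                            site_plan=small_site_plan(),
                            n_trials_per_block=60)


@pytest.fixture(scope="session")
def small_dataset(small_sim_config):
    return SyntheticDataset(small_sim_config)


@pytest.fixture(scope="session")
def small_dataset_dir(small_sim_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("ds") / "synth"
    simulate_dataset(small_sim_config, out)
    return out


@pytest.fixture
def analysis_config():
    return AnalysisConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
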
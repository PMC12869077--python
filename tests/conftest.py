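import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mistraq import simulate as sim

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


REPORT_DEFAULTS = {
    "run_id": "s_rep1",
    "strain_id": "s",
    "replicate_id": "rep1",
    "protein_id": "PROT1",
    "start": 1,
    "charge": 2,
    "intensity": 1000.0,
    "global_q": 0.001,
    "sub_pos": np.nan,
    "sub_from": pd.NA,
    "sub_to": pd.NA,
}


def make_report(rows):
    """Build a precursor-report frame from partial row dicts."""
    filled = []
    for row in rows:
        d = dict(REPORT_DEFAULTS)
        d.update(row)
        if "modified_sequence" not in d:
            d["modified_sequence"] = d["base_sequence"]
        filled.append(d)
    return pd.DataFrame(filled)


@pytest.fixture(scope="session")
def small_config():
    return sim.SimulationConfig(n_genes=40, seed=11)


@pytest.fixture(scope="session")
def small_orfeome(small_config):
    return sim.generate_orfeome(small_config)


@pytest.fixture(scope="session")
def small_result(small_config, small_orfeome):
    return sim.simulate_reports(small_orfeome, small_config)
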
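import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from edna_occupancy import everglades_fixture
from edna_occupancy.ddpcr import (
    ReplicateRun,
    apply_lob,
    compute_lob,
    estimate_concentration,
    pool_and_select,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_dataset():
    """The deterministic paired-survey fixture."""
    return everglades_fixture()


def quantify_fixture(ds):
    """Run the fixture through quantification + LOB; returns (samples, det, lob)."""
    t = ds.tables
    runs = [
        ReplicateRun(
            r.sample_id,
            int(r.replicate_id),
            int(r.run_id),
            int(r.m_total),
            int(r.m_pos),
            float(r.ipc_conc),
        )
        for r in t["replicates"].itertuples()
    ]
    selected = pool_and_select(runs)
    controls = {
        str(r.control_id): estimate_concentration(int(r.m_total), int(r.m_pos))
        for r in t["neg_controls"].itertuples()
    }
    lob = compute_lob(controls)
    det = apply_lob(
        {sid: est for sid, (est, _) in selected.items()},
        runs,
        lob,
        selected_runs={sid: rid for sid, (_, rid) in selected.items()},
    )
    samples = t["samples"].merge(
        t["sites"][["site_id", "pair_id", "island_type"]], on="site_id"
    )
    samples["concentration"] = det.loc[samples["sample_id"], "concentration"].to_numpy()
    return samples, det, lob


@pytest.fixture(scope="session")
def fixture_quantified(fixture_dataset):
    return quantify_fixture(fixture_dataset)
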
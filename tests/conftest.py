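import numpy as np
import pandas as pd
import pytest

from fcx.io_config import ParcelTable, PipelineConfig


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture
def toy_parcels():
    """4 regions, 2 networks, two regions with cluster overlap."""
    frame = pd.DataFrame(
        {
            "region_id": [1, 2, 3, 4],
            "region_label": ["V1L", "V1R", "M1L", "M1R"],
            "hemisphere": ["left", "right", "left", "right"],
            "network": ["visual", "visual", "somatomotor", "somatomotor"],
            "cluster_overlap": [
                frozenset({"visual"}),
                frozenset(),
                frozenset({"manual"}),
                frozenset(),
            ],
        }
    )
    return ParcelTable(frame)


def make_trials(rows):
    """Build a trial table from compact tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "run_id", "block_id", "task_type", "pairing",
            "component_task", "congruency", "response_modality_used", "rt",
            "correct", "difficulty",
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
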
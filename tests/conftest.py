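import numpy as np
import pandas as pd
import pytest

from naivebench.core import CountMatrix, SampleSheet, Thresholds


@pytest.fixture
def thresholds():
    return Thresholds()


@pytest.fixture
def esc_sheet():
    return SampleSheet.from_records([
        {"sample_id": f"{state}_r{r}", "state": state, "stage": None,
         "sex": "female", "replicate": r}
        for state in ("primed", "naive_5iLA") for r in (1, 2, 3)
    ])


@pytest.fixture
def small_counts(esc_sheet):
    rng = np.random.default_rng(7)
    counts = rng.poisson(100, size=(20, 6))
    return CountMatrix([f"f{i}" for i in range(20)], esc_sheet.sample_ids, counts)


@pytest.fixture
def embryo_sheet():
    records = []
    for stage in ("eight_cell", "morula"):
        for k in range(1, 7):
            records.append({"sample_id": f"{stage}_c{k}", "state": "embryo",
                            "stage": stage, "sex": "unknown", "replicate": k})
    return SampleSheet.from_records(records)
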
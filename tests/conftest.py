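import numpy as np
import pandas as pd
import pytest

from kitox import synthetic
from kitox.faers import AdverseEventReportTable, EventGroupDefinition


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared by read-only tests (300 genes)."""
    cfg = synthetic.SyntheticStudyConfig(n_genes=300, n_drugs=23, seed=42)
    return synthetic.generate_study(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_study):
    return synthetic.study_regression_dataset(small_study)


@pytest.fixture()
def toy_report_table():
    rows = [
        ("A", "HF", 3),
        ("A", "rash", 7),
        ("B", "HF", 5),
        ("B", "rash", 5),
    ]
    return AdverseEventReportTable(
        pd.DataFrame(rows, columns=["drug", "event_term", "count"])
    )


@pytest.fixture()
def hf_group():
    return EventGroupDefinition("HF", included=frozenset({"HF"}))


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
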
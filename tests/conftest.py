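import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import fraclift as fl

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def make_table(counts: dict, otu_ids=None) -> fl.OtuTable:
    """OtuTable from a {sample: [counts]} dict."""
    df = pd.DataFrame(counts)
    if otu_ids is not None:
        df.index = otu_ids
    else:
        df.index = [f"OTU_{i + 1}" for i in range(len(df))]
    return fl.OtuTable(df)


def make_metadata(rows: dict) -> fl.SampleMetadata:
    """SampleMetadata from {sample: (fraction, treatment, period[, rep])}."""
    records = {}
    for sid, spec in rows.items():
        frac, treat, period, *rest = spec
        records[sid] = {
            "fraction": frac,
            "treatment": treat,
            "period": period,
            "replicate": rest[0] if rest else 1,
        }
    return fl.SampleMetadata(pd.DataFrame.from_dict(records, orient="index"))


def random_table(rng, n_otus, n_samples, max_count=200, prefix="S"):
    counts = rng.integers(0, max_count, size=(n_otus, n_samples))
    counts[0, :] += 1  # keep every sample's depth positive
    df = pd.DataFrame(
        counts,
        index=[f"OTU_{i + 1}" for i in range(n_otus)],
        columns=[f"{prefix}{j + 1}" for j in range(n_samples)],
    )
    return fl.OtuTable(df)


@pytest.fixture
def paired_meta_factory():
    """Metadata for n paired samples S1..Sn alternating FL/PA."""

    def build(sample_ids, periods=None, treatment="S0"):
        rows = {}
        for i, sid in enumerate(sample_ids):
            frac = "FL" if i % 2 == 0 else "PA"
            period = periods[i] if periods is not None else 24
            rows[sid] = (frac, treatment, period)
        return make_metadata(rows)

    return build


@pytest.fixture(scope="session")
def sim_default():
    """One realization of the default 28-sample study design."""
    cfg = fl.SimulationConfig(seed=7)
    return fl.simulate_tables(cfg)
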
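import numpy as np
import pandas as pd
import pytest

from ctcpanel import (
    CtcClassifier, DeltaDeltaCtQuantifier, SimConfig, gen_cohort,
    gen_panel_cascade_dataset,
)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def cohort(default_config):
    return gen_cohort(default_config)


@pytest.fixture(scope="session")
def cohort_calls(cohort):
    controls = list(
        cohort.samples.loc[cohort.samples["role"] == "healthy_control",
                           "sample_id"])
    quant = DeltaDeltaCtQuantifier().fit(cohort.ct[controls])
    return quant.call(cohort.ct)


@pytest.fixture(scope="session")
def cohort_status(cohort, cohort_calls, default_config):
    clf = CtcClassifier(panel=list(default_config.panel_genes))
    return clf.predict(cohort_calls)


@pytest.fixture(scope="session")
def cascade_data(default_config):
    return gen_panel_cascade_dataset(default_config)


def run_cascade(data):
    """Quantify the spike-in and pilot Ct tables and fit the cascade."""
    from ctcpanel import PanelSelector

    quant = DeltaDeltaCtQuantifier()
    control = list(data.spike_manifest.loc[
        data.spike_manifest["spike_cells"] == 0, "sample_id"])
    spike_calls = quant.fit(data.ct_spike[control]).call(data.ct_spike)
    pilot_controls = list(data.pilot_manifest.loc[
        data.pilot_manifest["role"] == "healthy_control", "sample_id"])
    pilot_calls = DeltaDeltaCtQuantifier().fit(
        data.ct_pilot[pilot_controls]).call(
        data.ct_pilot.drop(columns=pilot_controls))
    sel = PanelSelector()
    sel.fit(data.counts, data.populations,
            data.ct_pure["PBMC"], data.ct_pure["tumor"],
            spike_calls, data.spike_manifest, pilot_calls)
    return sel


@pytest.fixture(scope="session")
def cascade_selector(cascade_data):
    return run_cascade(cascade_data)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def small_ct_table():
    """4 genes + reference over 3 samples, one Undetermined well."""
    return pd.DataFrame(
        {
            "S1": [20.0, 25.0, 28.0, 30.0, 24.0],
            "S2": [20.0, 24.0, np.nan, 31.0, 23.0],
            "S3": [21.0, 26.0, 29.0, 29.0, 25.0],
        },
        index=pd.Index(["GAPDH", "G1", "G2", "G3", "G4"], name="gene"),
    )
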
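"""Shared fixtures: small synthetic panels, runs and studies."""

import numpy as np
import pandas as pd
import pytest

from pulsedims import synth
from pulsedims.design import StudyDesign
from pulsedims.features import FeatureTable


@pytest.fixture(scope="session")
def panel():
    """A 20-feature panel with 4 planted differential features."""
    return synth.generate_panel(
        n_features=20, n_differential=4, fc=5.0, seed=7, sporadic_fraction=0.0
    )


@pytest.fixture(scope="session")
def quiet_acq():
    """Noise-free acquisition: no amplitude variation, no outlier pulses."""
    return synth.AcquisitionConfig(
        noise_sd=0.0, amplitude_cv=0.0, outlier_pulse_prob=0.0
    )


@pytest.fixture(scope="session")
def default_acq():
    return synth.AcquisitionConfig()


@pytest.fixture(scope="session")
def quiet_run(panel, quiet_acq):
    """One noise-free 40-pulse run plus its generator truth."""
    return synth.generate_run(panel, panel.base_abundance, quiet_acq, seed=11)


@pytest.fixture(scope="session")
def small_study():
    """A compact full study (6+6 samples, 3 QCs, 1 blank) for pipeline tests."""
    p = synth.generate_panel(n_features=40, n_differential=4, fc=5.0, seed=3)
    design = StudyDesign(n_per_group=6)
    acq = synth.AcquisitionConfig(n_pulses=20)
    return synth.generate_study(design, p, acq, between_sample_cv=0.2, seed=3)


def table_from_arrays(values, roles, groups=None, mzs=None):
    """Build a FeatureTable from plain arrays (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    ids = [f"r{i}" for i in range(n)]
    mzs = mzs if mzs is not None else (100.0 + np.arange(p))
    data = pd.DataFrame(values, index=pd.Index(ids, name="run_id"), columns=mzs)
    meta = pd.DataFrame(
        {
            "role": roles,
            "group": groups if groups is not None else [None] * n,
        },
        index=data.index,
    )
    return FeatureTable(data, meta)


@pytest.fixture
def make_table():
    return table_from_arrays


def random_table(rng, n_samples=6, n_qc=3, n_blank=1, n_features=12, missing=0.2):
    """Random positive table with missingness, for oracle-equivalence tests."""
    n = n_samples + n_qc + n_blank
    vals = rng.lognormal(2.0, 1.0, size=(n, n_features))
    mask = rng.random((n, n_features)) < missing
    vals[mask] = np.nan
    roles = ["sample"] * n_samples + ["QC"] * n_qc + ["blank"] * n_blank
    groups = (["a", "b"] * n_samples)[:n_samples] + [None] * (n_qc + n_blank)
    return table_from_arrays(vals, roles, groups)
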
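import numpy as np
import pytest

import hairpinmelt as hm


@pytest.fixture(scope="session")
def default_dataset():
    """One draw of the packaged 30-proton dataset with its ground truth."""
    series, truth = hm.generate_melt_series(hm.default_melt_spec(seed=0))
    return series, truth


@pytest.fixture(scope="session")
def default_fits(default_dataset):
    series, _ = default_dataset
    return [hm.fit_melt_curve(s) for s in series]


@pytest.fixture(scope="session")
def truth_class_map(default_dataset):
    _, truth = default_dataset
    return {
        hm.ProtonID(int(r.residue_number), r.atom_name, r.residue_type): r.class_label
        for r in truth.itertuples()
    }


@pytest.fixture()
def grid_14():
    """The 278-343 K / 5 K melting grid (14 points)."""
    return np.arange(278.0, 343.0 + 1e-9, 5.0)
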
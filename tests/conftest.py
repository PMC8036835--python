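import dataclasses

import numpy as np
import pytest

import radarvitals as rv


@pytest.fixture(scope="session")
def table2():
    return rv.table2_config()


@pytest.fixture(scope="session")
def vital_cfg(table2):
    """Vital-sign acquisition geometry with a single receiver for bulk simulations."""
    return dataclasses.replace(table2, n_rx=1)


@pytest.fixture(scope="session")
def agreement_study(vital_cfg):
    """Noiseless, movement-free 10-child study shared by agreement tests."""
    return rv.generate_study(10, vital_cfg, 60.0, seed=7,
                             noise_std=0.0, movement_rate_per_min=0.0)


@pytest.fixture(scope="session")
def classifier_study(vital_cfg):
    """50-child study under generator defaults, shared by classifier tests."""
    return rv.generate_study(50, vital_cfg, 31.0, seed=11, sex_counts=(24, 26))


def pooled_pairs(study, which, econfig=None):
    """Extract every participant and pool aligned radar/reference pairs."""
    radar, ref = [], []
    for pid in study.participant_ids:
        est = rv.extract_vitals(study.load_cube(pid), econfig)
        pairs = rv.align_rates(est, study.load_reference(pid), which)
        radar.append(pairs.radar)
        ref.append(pairs.reference)
    return rv.PairedRates(np.concatenate(radar), np.concatenate(ref))
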
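import numpy as np
import pytest

from rehomvpa.classify import CONTROL, PATIENT, build_feature_matrix
from rehomvpa.preproc import PreprocConfig, preprocess_subject
from rehomvpa.reho import reho_map
from rehomvpa.synthetic import SimulationConfig, simulate_cohort


def cohort_to_features(cohort):
    """Preprocess + ReHo-map every subject and stack the feature matrix."""
    pcfg = PreprocConfig(tr_s=cohort.config.tr_s)
    maps, labels = [], []
    for s in cohort.subjects:
        clean = preprocess_subject(
            s.bold, s.motion, cohort.wm_mask, cohort.csf_mask, pcfg
        )
        maps.append(reho_map(clean, cohort.gm_mask))
        labels.append(PATIENT if s.group == "patient" else CONTROL)
    return build_feature_matrix(maps, labels), maps


@pytest.fixture(scope="session")
def toy_config():
    return SimulationConfig(
        n_per_group=4,
        grid_shape=(12, 12, 12),
        n_volumes=60,
        effect_rois=(((6, 6, 6), 2),),
        synchrony_lambda=0.9,
        seed=7,
    )


@pytest.fixture(scope="session")
def toy_cohort(toy_config):
    return simulate_cohort(toy_config)


@pytest.fixture(scope="session")
def toy_features(toy_cohort):
    fm, maps = cohort_to_features(toy_cohort)
    return fm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
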
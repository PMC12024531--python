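"""Shared fixtures: phantom cohorts and the session-scoped trained models
that the slower property tests reuse."""
import os

# single-threaded BLAS keeps numerics identical across machines and avoids
# oversubscription on small CPU counts; set before numpy loads
for _v in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_v, "1")

import numpy as np
import pytest

from euslite import archnet, phantom
from euslite import train_harness as th


@pytest.fixture(scope="session")
def dev_cohort():
    """Development-style phantom cohort: 50 patients x 4 frames, 9.3±5.7 mm."""
    return phantom.generate_cohort(phantom.CohortConfig(n_patients=50, seed=7))


@pytest.fixture(scope="session")
def dev_arrays(dev_cohort):
    return th.arrays_from_phantoms(dev_cohort, 96)


@pytest.fixture(scope="session")
def desk_fold(dev_arrays):
    """The desk-preset training run (96 px, 200 images) used by the
    learnability, saliency and ROC checks."""
    spec = archnet.build_desk(96, dropout_rate=0.5)
    return th.train(spec, dev_arrays, th.TrainConfig.desk(seed=0))


@pytest.fixture(scope="session")
def desk_model(desk_fold):
    return desk_fold.model


@pytest.fixture(scope="session")
def heldout_arrays(dev_arrays):
    """The validation side of the desk run's patient-grouped split."""
    cfg = th.TrainConfig.desk(seed=0)
    _, val_ids = th.split_train_val(dev_arrays.patient_ids, 1 - cfg.val_ratio, cfg.seed)
    return dev_arrays.by_patients(val_ids)


@pytest.fixture(scope="session")
def small64_arrays():
    """A small 64-px dataset for cross-validation / grid mechanics tests."""
    cfg = phantom.CohortConfig(n_patients=25, images_per_patient=(2, 2), seed=11)
    return th.arrays_from_phantoms(phantom.generate_cohort(cfg), 64)


@pytest.fixture(scope="session")
def memorization64_arrays():
    """Memorization-prone preset: few images, heavy speckle (low looks)."""
    cfg = phantom.CohortConfig(
        n_patients=15, images_per_patient=(4, 4), speckle_looks=4.0, seed=3
    )
    return th.arrays_from_phantoms(phantom.generate_cohort(cfg), 64)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
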
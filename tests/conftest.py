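"""Shared fixtures: a study-shaped synthetic dataset and cached pipeline runs.

The expensive end-to-end artifacts (dataset synthesis, network images,
cross-validated score matrices) are session-scoped so the evaluation,
fusion and acceptance tests share one computation.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import roarid as R
from roarid.classify import BackboneSpec, TrainConfig
from roarid.evaluation import cross_validate, make_day_folds, make_sample_folds
from roarid.representations import (RepresentationConfig,
                                    extract_representation, to_network_image)

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")

SEED = 11


@pytest.fixture(scope="session")
def paper_ds():
    """Study-shaped dataset: 5 individuals x 4 day-groups, high SNR.

    Clip duration is reduced to 0.5 s to keep the suite fast; the
    grouping structure (20 day groups, bouts of 1-3) is unchanged.
    """
    return R.paper_shaped_dataset(seed=SEED, duration_s=0.5, noise_snr_db=30.0)


@pytest.fixture(scope="session")
def rep_cfg():
    return RepresentationConfig()


def images_for(dataset, representation, cfg, size=64):
    return {
        s.sample_id: to_network_image(
            extract_representation(s.clip, representation, cfg), size, size)
        for s in dataset.samples
    }


@pytest.fixture(scope="session")
def lm_images(paper_ds, rep_cfg):
    return images_for(paper_ds, "lm", rep_cfg)


@pytest.fixture(scope="session")
def day_eval(paper_ds, lm_images):
    """(EvalResult, pooled ScoreMatrix) of tiny-scratch + LM under day LOOCV."""
    return cross_validate(lm_images, paper_ds.labels(),
                          make_day_folds(paper_ds), BackboneSpec(),
                          TrainConfig(seed=5))


@pytest.fixture(scope="session")
def naive_eval(paper_ds, lm_images):
    """Same classifier under naive per-sample LOOCV (leakage-prone design)."""
    return cross_validate(lm_images, paper_ds.labels(),
                          make_sample_folds(paper_ds), BackboneSpec(),
                          TrainConfig(seed=5))


def random_metadata_dataset(rng) -> R.RoarDataset:
    """A structurally random dataset with stub audio (fold plans only read
    the grouping metadata)."""
    stub = R.AudioClip(np.zeros(16), 16000)
    n_ind = int(rng.integers(2, 5))
    samples, labels = [], []
    for i in range(n_ind):
        ind = f"ind{i}"
        labels.append(ind)
        for d in range(int(rng.integers(2, 4))):
            day = f"{ind}_d{d}"
            for b in range(int(rng.integers(1, 4))):
                bout = f"{day}_b{b}"
                for m in range(1, int(rng.integers(1, 4)) + 1):
                    sid = f"{bout}_s{m}"
                    samples.append(R.RoarSample(stub, ind, day, bout, m, sid))
    return R.RoarDataset(samples, labels)
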
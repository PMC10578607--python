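"""Shared fixtures: small glyph sets, simulated cohorts, tiny network specs."""

import numpy as np
import pytest

import glyphcurate as gc


@pytest.fixture(scope="session")
def prototypes():
    return gc.default_prototypes(4)


@pytest.fixture(scope="session")
def instances(prototypes):
    """80 glyph instances (20 per class) at the default deformation level."""
    return gc.generate_instances(prototypes, 20, 11.0, seed=101, sigma_tau=7.5)


@pytest.fixture(scope="session")
def instance_map(instances):
    return {i.instance_id: i for i in instances}


@pytest.fixture(scope="session")
def cohort_records(instances):
    """50 simulated participants, two presentations of each of 80 instances."""
    return gc.simulate_cohort(50, gc.CohortParams(), instances, 2, seed=202)


@pytest.fixture(scope="session")
def retained(cohort_records):
    return gc.filter_participants(cohort_records, 0.75)


@pytest.fixture(scope="session")
def rank_table(cohort_records, retained):
    return gc.rank_within_class(cohort_records, retained)


@pytest.fixture(scope="session")
def instance_scores(rank_table, cohort_records):
    return gc.score_instances(rank_table, cohort_records)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small-image network spec so unit tests train in well under a second."""
    return gc.NetSpec(n_classes=4, image_size=16, dense1=32, dense2=16,
                      epochs=4, batch_size=16)


@pytest.fixture(scope="session")
def tiny_train_set(tiny_spec):
    """Linearly separable 16x16 quadrant blobs, 32 per class."""
    rng = np.random.default_rng(7)
    xs, ys = [], []
    corners = [(0, 0), (0, 8), (8, 0), (8, 8)]
    for label, (r, c) in enumerate(corners):
        for _ in range(32):
            img = np.zeros((16, 16))
            img[r:r + 8, c:c + 8] = (rng.random((8, 8)) > 0.35).astype(float)
            xs.append(img)
            ys.append(label)
    return np.stack(xs), np.array(ys)
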
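import numpy as np
import pytest

import cephgrowth as cg
from cephgrowth.datasets import SupervisedDataset

PX_PER_MM = 10.0


def as_dataset(X: np.ndarray, Y: np.ndarray) -> SupervisedDataset:
    """Wrap raw arrays as a SupervisedDataset for direct model-fitting tests."""
    Y = Y if Y.ndim == 2 else Y[:, None]
    return SupervisedDataset(
        X=np.asarray(X, dtype=float),
        Y=np.asarray(Y, dtype=float),
        feature_names=[f"f{j}" for j in range(X.shape[1])],
        target_names=[f"t{j}" for j in range(Y.shape[1])],
        subject_ids=[f"s{i}" for i in range(len(X))],
        age_window=(6,),
    )


def measurements_for(config: cg.SyntheticConfig):
    """Generate → normalize → interpolate → measure."""
    population = cg.generate_population(config)
    normed = [
        cg.interpolate_missing(cg.normalize_coordinates(s, px_per_mm=PX_PER_MM))
        for s in population
    ]
    return cg.compute_measurement_table(normed)


@pytest.fixture(scope="session")
def small_population():
    """Twelve subjects with realistic defaults, raw pixel frame."""
    return cg.generate_population(cg.SyntheticConfig(n_subjects=12, seed=11))


@pytest.fixture(scope="session")
def small_measurements():
    return measurements_for(cg.SyntheticConfig(n_subjects=12, seed=11))


@pytest.fixture(scope="session")
def noisefree_subject():
    """One deterministic subject: no noise, no subject variation, identity acquisition."""
    config = cg.SyntheticConfig(
        n_subjects=1, noise_sd=0.0, subject_sd=0.0, missing_rate=0.0,
        acquisition=cg.AcquisitionConfig(rotation_deg=0.0, translation_px=0.0, px_per_mm=1.0),
        seed=0,
    )
    return cg.generate_population(config)[0]
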
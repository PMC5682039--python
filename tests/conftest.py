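import numpy as np
import pytest

from npairspls import (
    PhantomSpec,
    Region,
    assemble_data_matrix,
    brain_ellipsoid_probabilities,
    build_mask,
    build_phantom,
    encode_design,
    simulate_cohort,
)


def build_cohort(spec):
    """Simulate a cohort and assemble everything downstream stages need."""
    volumes, design = simulate_cohort(spec)
    gm, csf = brain_ellipsoid_probabilities(spec)
    mask = build_mask(gm, csf)
    X = assemble_data_matrix(volumes, design, mask)
    Y = encode_design(design)
    _, effect = build_phantom(spec)
    truth = mask.extract(effect)
    return {
        "spec": spec, "volumes": volumes, "design": design, "mask": mask,
        "X": X, "Y": Y, "truth": truth,
    }


@pytest.fixture(scope="session")
def default_cohort():
    """The study conditions: 13+6 subjects, two seasons, default phantom."""
    return build_cohort(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def strong_cohort():
    """Strong planted signal at low noise, for recovery-limit checks.

    Columns are standardized before PLS, so "strong" means the planted
    network must dominate in spatial extent as well as amplitude: two
    6.5 mm spheres cover ~38% of the masked ellipsoid.
    """
    spec = PhantomSpec(
        grid_shape=(12, 12, 12),
        regions=(
            Region(center=(4, 4, 5), radius_mm=6.5, effect_sign=+1, effect_size=0.5),
            Region(center=(8, 8, 7), radius_mm=6.5, effect_sign=-1, effect_size=0.5),
        ),
        subject_sd=0.05,
        noise_sd=0.02,
        seed=11,
    )
    return build_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted effect: pure subject intercepts plus voxel noise."""
    return build_cohort(PhantomSpec(grid_shape=(12, 12, 12), regions=(), seed=21))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
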
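import numpy as np
import pytest

from dpdquant import GradeScenario, build_phantom

GRID = (64, 64, 64)
SPACING = (4.0, 4.0, 4.0)


@pytest.fixture(scope="session")
def clean_phantom_grade2():
    """Noiseless, blur-free grade-2 phantom at the cohort-mean uptake."""
    sc = GradeScenario(grade=2, psf_sigma_mm=0.0, counts_per_suv=None)
    return build_phantom(sc, GRID, SPACING)


@pytest.fixture(scope="session")
def noisy_phantom_grade2():
    """Default degraded grade-2 phantom (PSF blur + Poisson noise)."""
    sc = GradeScenario(grade=2, psf_sigma_mm=6.0, counts_per_suv=500.0, seed=42)
    return build_phantom(sc, GRID, SPACING)
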
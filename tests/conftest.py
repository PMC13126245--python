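import warnings

import pytest

from bcl3meth import synth

# baseline shifts for planted effects are an expected, logged event in the
# small fixture cohorts
warnings.filterwarnings("ignore", message="shifted .* baselines")


@pytest.fixture(scope="session")
def annotation_small():
    return synth.generate_annotation(2000, seed=1)


@pytest.fixture(scope="session")
def cohort_small(annotation_small):
    """20 cases / 10 per control group, 2000 CpGs, planted 196 hypo + 4 hyper."""
    cfg = synth.CohortConfig(
        n_cases=20, n_controls=10, n_cpgs=2000, n_hypo=196, n_hyper=4,
        delta_beta=0.35, precision=80.0, purity_range=(0.8, 1.0), seed=7,
    )
    beta, sheet, truth = synth.generate_cohort(cfg, annotation_small)
    return cfg, beta, sheet, truth


@pytest.fixture(scope="session")
def loci():
    return synth.generate_loci(seed=0)
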
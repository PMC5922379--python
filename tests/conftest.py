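import numpy as np
import pandas as pd
import pytest

import episcore as ep


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 20-gene x 120-patient cohort with one strong
    planted gene, shared by tests that only need plausible survival data."""
    spec = ep.SyntheticCohortSpec(
        n_patients=120,
        n_genes=20,
        planted_genes=(ep.PlantedGene(0, float(np.log(3)), 0.5),),
        seed=42,
    )
    expr, clin, truth = ep.generate_cohort(spec)
    return ep.align_cohort(expr, clin), truth


@pytest.fixture(scope="session")
def pipeline_cohorts():
    """Training/validation cohort pair at the screening-study scale:
    400 patients each, 100 genes, three planted prognostic genes with
    log hazard ratio log(2.5) cut at the median."""
    spec = ep.SyntheticCohortSpec(
        n_patients=400,
        n_genes=100,
        planted_genes=tuple(
            ep.PlantedGene(i, float(np.log(2.5)), 0.5) for i in (3, 41, 77)
        ),
        seed=11,
    )
    return ep.generate_cohort_pair(spec)


def null_survival(rng, n, scale=30.0, horizon=120.0):
    """Exponential survival unrelated to anything, uniformly censored."""
    t = rng.exponential(scale, n)
    c = rng.uniform(0.0, horizon, n)
    return np.minimum(t, c), (t <= c).astype(int)
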
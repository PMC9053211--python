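import numpy as np
import pytest

from evmced import (
    CANCERS,
    Cohort,
    MarkerMeta,
    PipelineConfig,
    SimSpec,
    Subject,
    simulate_cohort,
)


@pytest.fixture
def tiny_cohort() -> Cohort:
    """3 subjects x 2 markers, one below-LOD cell and one missing cell."""
    subjects = [
        Subject(id="s1", group="control", age=55.0, sex="female"),
        Subject(id="s2", group="pancreatic", age=62.0, sex="male", stage="I"),
        Subject(id="s3", group="ovarian", age=60.0, sex="female", stage="II"),
    ]
    markers = [
        MarkerMeta(name="CA19-9", lod=2.0, units="U/mL", panel="p1"),
        MarkerMeta(name="CA125", lod=4.0, units="U/mL", panel="p1"),
    ]
    values = np.array([[0.5, 8.0], [16.0, np.nan], [8.0, 64.0]])
    return Cohort(subjects=subjects, markers=markers, values=values)


def null_sim_spec(seed: int, n_markers: int = 6) -> SimSpec:
    """Study-sized cohort in which no marker separates cases from controls."""
    return SimSpec(
        n_markers=n_markers,
        n_informative_per_cancer=2,
        effect_sizes={c: np.zeros(2) for c in CANCERS},
        lod_quantile=0.05,
        missing_rate=0.0,
        seed=seed,
    )


@pytest.fixture
def informative_cohort():
    """Small cohort with 5 strongly informative markers among 15."""
    spec = SimSpec(
        n_markers=15,
        n_informative_per_cancer=5,
        informative_markers={c: [0, 1, 2, 3, 4] for c in CANCERS},
        effect_sizes={c: np.array([2.5, 2.25, 2.0, 1.75, 1.5]) for c in CANCERS},
        lod_quantile=0.05,
        missing_rate=0.0,
        seed=42,
    )
    return simulate_cohort(spec)


@pytest.fixture
def fast_config() -> PipelineConfig:
    return PipelineConfig(rfe_reps=2, resamples=10, bootstrap_B=100, seed=7)
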
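import numpy as np
import pytest

from ellipsekin import (
    AnalysisConfig,
    CohortSpec,
    CycleSpec,
    RecordingSpec,
    analyze_cohort,
    generate_cohort,
    generate_harmonic_cycle,
    generate_recording,
)


@pytest.fixture(scope="session")
def harmonic_recording():
    """Ten noise-free harmonic cycles of the 8 x 2 cm template at 1 Hz."""
    return generate_harmonic_cycle(a=8.0, b=2.0, frequency=1.0,
                                   sample_rate=200.0, n_cycles=10)


@pytest.fixture(scope="session")
def template_recording():
    """Ten noise-free template-shaped cycles, right-hand convention
    (rotated +45 deg, CCW)."""
    spec = RecordingSpec(cycle=CycleSpec(a=8.0, b=2.0, beta=1 / 3,
                                         duration=1.0, rotation=45.0),
                         n_cycles=10, jitter_cv=0.0, noise_sd=0.0)
    return generate_recording(spec, seed=0)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-subject cohort analyzed end to end (trajectories, ground truth,
    cycle features, condition summaries)."""
    spec = CohortSpec(n_subjects=6, seed=11)
    trajectories, truth = generate_cohort(spec)
    features, summaries = analyze_cohort(trajectories)
    return {"trajectories": trajectories, "truth": truth,
            "features": features, "summaries": summaries}
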
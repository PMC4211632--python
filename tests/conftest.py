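import numpy as np
import pytest

import nirsmotion as nm


@pytest.fixture
def probe8():
    """The study probe: 2 sources x 4 detectors, 8 channels."""
    return nm.default_probe()


@pytest.fixture
def probe2():
    """Minimal single-pair probe (690 + 830 nm)."""
    return nm.ProbeGeometry([[0.0, 0.0, 0.0]], [[3.0, 0.0, 0.0]],
                            [(0, 0, 690.0), (0, 0, 830.0)])


@pytest.fixture
def quiet_run():
    """Artifact-free, noise-free, flat-baseline 6-min run with injected HRF."""
    return nm.generate_run(nm.quiet_config(seed=1))


@pytest.fixture
def artifact_free_run():
    """Realistic physiology + HRF but zero motion-artifact events."""
    cfg = nm.GeneratorConfig(seed=4, artifacts=nm.ArtifactSpec(rate_per_min=0.0))
    return nm.generate_run(cfg)


@pytest.fixture
def contaminated_run():
    """Default-severity motion-contaminated run."""
    cfg = nm.GeneratorConfig(seed=3,
                             artifacts=nm.ArtifactSpec(rate_per_min=6.0))
    return nm.generate_run(cfg)


def make_od(data, fs_hz=25.0):
    """Wrap a (n, 2) array as an ODSeries on the minimal probe."""
    probe = nm.ProbeGeometry([[0.0, 0.0, 0.0]], [[3.0, 0.0, 0.0]],
                             [(0, 0, 690.0), (0, 0, 830.0)])
    data = np.asarray(data, float)
    if data.ndim == 1:
        data = np.column_stack([data, data])
    return nm.ODSeries(fs_hz, data, probe)
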
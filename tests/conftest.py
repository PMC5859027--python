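import numpy as np
import pytest

from perfcov.normal_limits import fit_normal_limits
from perfcov.polarmap import PolarMap, build_segment_model, normalize_map
from perfcov.synthcohort import generate_normal_map


@pytest.fixture(scope="session")
def model():
    """Default 24x36 segment model."""
    return build_segment_model()


@pytest.fixture(scope="session")
def small_model():
    """Coarser 12x24 model (apical segments get 6 sectors each)."""
    return build_segment_model(R=12, A=24, zone_fractions=(1 / 6, 5 / 18, 5 / 18, 5 / 18))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def male_limits(model):
    """Normal limits from a 60-map synthetic male cohort."""
    rng = np.random.default_rng(7)
    maps = [
        normalize_map(generate_normal_map(model, "male", 8.0, rng, subject_id=f"n{i}"))
        for i in range(60)
    ]
    return fit_normal_limits(maps, "male")


def make_map(values, gender="male", normalized=False, subject_id="s"):
    return PolarMap(
        subject_id=subject_id, gender=gender, values=np.asarray(values, float),
        normalized=normalized,
    )
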
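import numpy as np
import pytest

from falafl import (
    BinaryCoverageMatrix,
    CoverageFractionMatrix,
    PatientMeta,
    SiteId,
)


@pytest.fixture
def two_by_three():
    """The worked-example binary matrix: 2 patients x 3 sites."""
    return np.array([[1, 1, 0], [1, 0, 1]], dtype=np.uint8)


@pytest.fixture
def small_fraction_matrix():
    patients = [PatientMeta("p1", group="L"), PatientMeta("p2", group="R")]
    sites = [SiteId("chr1", 100), SiteId("chr1", 200), SiteId("chr2", 50)]
    values = np.array([[0.0, 0.5, 1.0], [0.25, 0.75, 0.1]])
    return CoverageFractionMatrix(patients, sites, values)


@pytest.fixture
def binary_matrix(two_by_three):
    patients = [PatientMeta("p1"), PatientMeta("p2")]
    sites = [SiteId("chr1", i * 100) for i in (1, 2, 3)]
    return BinaryCoverageMatrix(patients, sites, two_by_three)


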
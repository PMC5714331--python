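import numpy as np
import pytest

from mirpanel import CtMatrix, SampleAnnotation
from mirpanel.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across read-only tests."""
    return generate_cohort(SyntheticConfig(seed=42))


@pytest.fixture
def tiny_ct():
    """3 assays x 4 samples, fully detected, hand-checkable values."""
    return CtMatrix(
        assay_ids=["mir-a", "mir-b", "mir-c"],
        sample_ids=["s1", "s2", "s3", "s4"],
        ct=np.array(
            [
                [20.0, 21.0, 22.0, 23.0],
                [30.0, 29.0, 28.0, 27.0],
                [25.0, 25.5, 24.5, 25.0],
            ]
        ),
    )


@pytest.fixture
def four_group_annotations():
    """9/4/5/9 cohort annotations without clinical covariates."""
    anns = []
    for g, n in (("NGT", 9), ("NP_IGT", 4), ("P_IGT", 5), ("T2D", 9)):
        for i in range(n):
            anns.append(SampleAnnotation(sample_id=f"{g}-{i + 1:02d}", group=g))
    return anns
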
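"""Shared builders for hand-constructed test inputs."""

import numpy as np
import pandas as pd

from mirpanel import SampleAnnotation
from mirpanel.normalization import NrqMatrix


def make_nrq(values: dict[str, dict[str, float]]) -> NrqMatrix:
    """Build a minimal NrqMatrix directly from per-assay per-sample values."""
    assays = sorted(values)
    samples = sorted({s for row in values.values() for s in row})
    grid = np.array(
        [[values[a].get(s, np.nan) for s in samples] for a in assays]
    )
    return NrqMatrix(
        assay_ids=assays,
        sample_ids=samples,
        lognrq=grid,
        base=10.0,
        global_mean=pd.Series(0.0, index=samples),
    )


def make_annotations(mapping: dict[str, str]) -> list[SampleAnnotation]:
    return [SampleAnnotation(s, g) for s, g in mapping.items()]
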
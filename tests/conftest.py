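import numpy as np
import pandas as pd
import pytest

from membranebench.io import (
    AnnotationRecord,
    QuantMatrix,
    Sample,
    SampleDesign,
)


@pytest.fixture
def design3():
    """One workflow, two conditions, three replicates."""
    return SampleDesign(
        Sample(f"W_{c}_{r}", "W", c, r)
        for c in ("LFD", "HFD")
        for r in (1, 2, 3)
    )


@pytest.fixture
def quant_small(design3):
    """4 proteins x 6 samples, linear scale, one missing cell."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.lognormal(mean=16, sigma=1, size=(4, 6)),
        index=[f"P{i}" for i in range(4)],
        columns=design3.sample_ids,
    )
    data.iloc[0, 0] = np.nan
    return QuantMatrix(data, scale="linear")


def make_annotation(pid="P0", gene="Gene1", keywords="cytosol", tm=0, mw=50.0):
    return AnnotationRecord(pid, gene, keywords, tm, mw)


@pytest.fixture
def annotations4():
    return {
        "P0": make_annotation("P0", "Gnai1", "cytosol", 0, 40.0),
        "P1": make_annotation("P1", "Alb", "secreted", 0, 69.0),
        "P2": make_annotation("P2", "Slc2a1", "plasma membrane; integral component of membrane", 12, 54.0),
        "P3": make_annotation("P3", "Atp5a1", "membrane; mitochondrion inner membrane", 3, 60.0),
    }
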
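import numpy as np
import pytest

from icc_intervals import AnovaSummary, DataGrid, DesignSpec


@pytest.fixture(scope="session")
def rater_study_summary() -> AnovaSummary:
    """ANOVA summary of the published 24-children x 10-raters agreement study."""
    return AnovaSummary(
        ms_subject=95.450, ms_rater=4.414, ms_error=0.786, design=DesignSpec(24, 10, 1)
    )


@pytest.fixture(scope="session")
def rater_study_reduced_summary() -> AnovaSummary:
    """Summary after deleting one child and transforming the scores (23 x 10)."""
    return AnovaSummary(
        ms_subject=8.3721, ms_rater=0.3667, ms_error=0.0671, design=DesignSpec(23, 10, 1)
    )


@pytest.fixture()
def random_grid() -> DataGrid:
    rng = np.random.default_rng(42)
    design = DesignSpec(6, 4, 2)
    y = (
        1.5
        + rng.normal(0, 1.2, (design.b0, 1, 1))
        + rng.normal(0, 0.7, (1, design.l0, 1))
        + rng.normal(0, 0.4, (design.b0, design.l0, design.r0))
    )
    return DataGrid(values=y, design=design)
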
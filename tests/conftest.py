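import numpy as np
import pytest

from chirokit import (
    BandShapeParams,
    ConformerRecord,
    Ensemble,
    TransitionRecord,
    default_grid,
)


@pytest.fixture
def two_conformer_ensemble():
    """Minimal ensemble: reference conformer plus one at +1 kcal/mol."""
    t = (TransitionRecord(4.275, 12.0), TransitionRecord(5.5, -20.0))
    return Ensemble(
        [
            ConformerRecord("c0", 0.0, "180", t),
            ConformerRecord("c1", 1.0, "0", t),
        ]
    )


@pytest.fixture
def single_band_params():
    return BandShapeParams(zeta=0.36, uv_shift=0.0)


@pytest.fixture
def grid():
    return default_grid()
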
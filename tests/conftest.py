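import numpy as np
import pytest

from pcai.cohort import CaseRecord
from pcai.preprocess import SpotImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_case():
    """Event-free case with long follow-up and all spread flags observed false."""
    return CaseRecord(
        case_id="c1", tma_id="t1", follow_up_years=6.0,
        pn_flag=False, pv_flag=False, pl_flag=False,
        bcr_flag=False, met_flag=False, cdeath_flag=False,
    )


def make_case(**overrides) -> CaseRecord:
    base = dict(
        case_id="c0", tma_id="t0", follow_up_years=6.0,
        pn_flag=False, pv_flag=False, pl_flag=False,
        bcr_flag=False, met_flag=False, cdeath_flag=False,
    )
    base.update(overrides)
    return CaseRecord(**base)


@pytest.fixture
def tissue_spot(rng):
    """Synthetic half-tissue image: left half dark tissue, right half white."""
    px = np.full((64, 64, 3), 0.98)
    px[:, :32] = 0.3
    px = np.clip(px + rng.normal(0, 0.01, px.shape), 0, 1)
    return SpotImage(pixels=px, spot_id="s", case_id="c", tma_id="t")
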
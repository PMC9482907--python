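import numpy as np
import pytest

from napsri import calibration as cal


@pytest.fixture
def simple_anchors():
    """Two anchors spanning RI 400-500 over 4-6 min."""
    return cal.AnchorSet(ris=(400.0, 500.0), rts=(4.0, 6.0))


@pytest.fixture
def spread_anchors():
    """A well-spread 8-anchor set (no co-elution)."""
    ns = range(4, 12)
    rts = (1.0, 1.4, 2.0, 2.9, 4.1, 5.5, 7.0, 8.6)
    return cal.make_anchors(list(zip(ns, rts)))


@pytest.fixture
def pileup_anchors():
    """C1-C12 anchors with the early void-volume pileup: C1-C3 nearly
    co-eluting (unequal sub-0.02 min gaps), then spreading over the ramp."""
    rts = (0.840, 0.852, 0.870, 1.30, 2.10, 3.10, 4.20, 5.35, 6.50, 7.65, 8.80, 9.95)
    return cal.make_anchors(list(zip(range(1, 13), rts)))


@pytest.fixture
def collinear_anchors():
    rts = np.linspace(2.0, 10.0, 9)
    return cal.AnchorSet(ris=tuple(100.0 * n for n in range(4, 13)), rts=tuple(rts))
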
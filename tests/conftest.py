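import numpy as np
import pytest

from cowgait.keypoint_io import KEYPOINTS, bout_from_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_bout():
    """Factory for small hand-built bouts from per-keypoint coordinates."""

    def _make(coords=None, likelihoods=None, n=None, fps=25.0, bout_id="b0"):
        if coords is None:
            n = n or 8
            # straight back, head-to-tail along x
            coords = {
                kp: np.column_stack(
                    [np.full(n, 100.0 + 100.0 * i) + np.arange(n), np.full(n, 50.0)]
                )
                for i, kp in enumerate(reversed(KEYPOINTS))
            }
        return bout_from_arrays(bout_id, fps, coords, likelihoods)

    return _make
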
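import numpy as np
import pytest

from lequant.locio import ROI, LocalizationTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def roi_10um():
    return ROI.rectangle(0.0, 0.0, 10_000.0, 10_000.0)


@pytest.fixture
def roi_20um():
    return ROI.rectangle(0.0, 0.0, 20_000.0, 20_000.0)


def make_locs(x, y, lpx=None, lpy=None, frame=None, photons=None, label="test"):
    """Build a LocalizationTable from coordinate lists with sensible defaults."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    return LocalizationTable(
        frame=np.zeros(n, dtype=int) if frame is None else np.asarray(frame),
        x=x,
        y=np.asarray(y, dtype=float),
        photons=np.full(n, 1000.0) if photons is None else np.asarray(photons),
        lpx=np.full(n, 5.0) if lpx is None else np.asarray(lpx, dtype=float),
        lpy=np.full(n, 5.0) if lpy is None else np.asarray(lpy, dtype=float),
        channel_label=label,
    )


@pytest.fixture
def cloud_table(rng):
    """Two well-separated localization clouds (20 locs each, sigma 5 nm)."""
    centers = np.array([[500.0, 500.0], [700.0, 500.0]])
    pts = np.vstack([c + rng.normal(0, 5.0, (20, 2)) for c in centers])
    return make_locs(pts[:, 0], pts[:, 1]), centers
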
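import numpy as np
import pytest

from hybridrank.hsqc import HsqcPeak, HsqcPeakList


def random_peak_list(
    rng: np.random.Generator,
    n_peaks: int,
    label: str,
    kind: str = "predicted",
) -> HsqcPeakList:
    """Uniform random peaks over typical solution-state shift ranges."""
    peaks = tuple(
        HsqcPeak(float(rng.uniform(0.5, 9.5)), float(rng.uniform(10.0, 145.0)))
        for _ in range(n_peaks)
    )
    return HsqcPeakList(label=label, kind=kind, peaks=peaks)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def square_peaks():
    """Four well-separated cross-peaks used as a minimal experimental list."""
    return HsqcPeakList(
        label="exp",
        kind="experimental",
        peaks=(
            HsqcPeak(1.0, 20.0),
            HsqcPeak(2.5, 35.0),
            HsqcPeak(4.0, 60.0),
            HsqcPeak(7.2, 120.0),
        ),
    )
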
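import numpy as np
import pytest

from lfqpipe.ms1io import MS1Run, Scan


def make_run(rng, n_scans=None, max_peaks=20, replicate_id="r1"):
    """Random small chromatogram for oracle-equivalence tests."""
    if n_scans is None:
        n_scans = int(rng.integers(5, 51))
    scans = []
    for i in range(n_scans):
        k = int(rng.integers(0, max_peaks + 1))
        mz = np.sort(rng.uniform(300.0, 1500.0, size=k))
        inten = rng.uniform(0.0, 1000.0, size=k)
        scans.append(Scan(number=i + 1, retention_time=float(i), mz=mz, intensity=inten))
    return MS1Run(replicate_id=replicate_id, scans=scans)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
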
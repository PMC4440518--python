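import numpy as np
import pandas as pd
import pytest

from her2het.calling import StateProfile
from her2het.config import RunConfig
from her2het.io import ComponentLabel
from her2het.simulate import PROBE_BP


@pytest.fixture
def config():
    return RunConfig(seed=0)


def make_state_profile(sample_id, component, encoding, chrom=None, missing=None):
    """Build a StateProfile directly from arrays, on a 50 kb probe grid."""
    enc = np.asarray(encoding, dtype=np.int8)
    n = enc.size
    if chrom is None:
        chrom = np.array(["chr1"] * n)
    else:
        chrom = np.asarray(chrom)
    if missing is None:
        missing = np.zeros(n, dtype=bool)
    starts, pos = [], {}
    for c in chrom:
        j = pos.get(c, 0)
        starts.append(j * PROBE_BP + 1)
        pos[c] = j + 1
    probes = pd.DataFrame({
        "probe_id": [f"P{i:04d}" for i in range(n)],
        "chrom": chrom,
        "start": starts,
        "end": [s + PROBE_BP - 1 for s in starts],
    })
    return StateProfile(
        sample_id=sample_id,
        component_label=ComponentLabel(component),
        encoding=enc,
        chrom=chrom,
        missing=np.asarray(missing, dtype=bool),
        probes=probes,
    )
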
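"""Shared fixture builders for the test suite."""

import numpy as np
import pandas as pd

from fallowcast.features import METEO_INDICES


def planted_blocks(rng, n=200, block_r=0.9):
    """14 variables in 4 independent blocks (sizes 4/4/3/3), within-block r ~ 0.9."""
    sizes = [4, 4, 3, 3]
    cols = {}
    names = list(METEO_INDICES)
    k = 0
    blocks = []
    for size in sizes:
        factor = rng.normal(size=n)
        members = []
        for _ in range(size):
            noise = rng.normal(size=n)
            lam = np.sqrt(block_r)
            cols[names[k]] = lam * factor + np.sqrt(1 - lam**2) * noise
            members.append(names[k])
            k += 1
        blocks.append(members)
    return pd.DataFrame(cols), blocks
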
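import numpy as np
import pandas as pd
import pytest

from repscan.io_core import GenomeLayout


@pytest.fixture
def small_layout():
    """Two chromosomes, 100-kb windows: 10 windows + 3.5 windows."""
    return GenomeLayout((("chr1", 1_000_000), ("chr2", 350_000)), 100_000)


@pytest.fixture
def rng():
    return np.random.default_rng(20180315)


def random_window_table(layout, rng, stat="fst", missing_frac=0.0):
    win = layout.windows()
    win[stat] = rng.uniform(0, 1, len(win))
    if missing_frac:
        mask = rng.uniform(size=len(win)) < missing_frac
        win.loc[mask, stat] = np.nan
    return win
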
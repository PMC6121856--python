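"""Small bundled example datasets.

The repeatability matrix below is a published-style worked example:
correlation coefficients comparing 100-kb windowed estimates of
differentiation across eight sister pairs of temperate songbirds, with
F_ST coefficients below the diagonal and d_XY coefficients above it.
d_XY is absent for the greenish warbler pair, whose
reduced-representation data did not meet the callable-site filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["bird_pair_repeatability", "BIRD_PAIRS"]

BIRD_PAIRS = [
    "flycatchers", "crows", "willow_warblers", "blackcaps",
    "greenish_warblers", "stonechats", "thrushes", "blue_golden_wings",
]

_NA = np.nan

# rows in BIRD_PAIRS order; below diagonal F_ST, above diagonal d_XY
_MATRIX = [
    #  fly      crow     willow   blackcap greenish stonech  thrush   blue/gold
    [_NA,      0.17,    0.21,    0.23,    _NA,     0.51,    0.11,    0.17],
    [0.058,    _NA,     0.09,    0.14,    _NA,     0.21,    0.04,    0.22],
    [0.020,    0.028,   _NA,     0.29,    _NA,     0.12,    0.19,    0.24],
    [-0.017,   0.037,   0.029,   _NA,     _NA,     0.18,    0.44,    0.42],
    [0.11,     0.054,   -0.020,  0.021,   _NA,     _NA,     _NA,     _NA],
    [0.18,     0.099,   0.030,   0.045,   0.14,    _NA,     0.37,    0.11],
    [0.084,    0.024,   0.12,    0.0099,  0.11,    0.13,    _NA,     0.21],
    [0.0077,   0.036,   0.055,   0.052,   0.027,   0.032,   0.099,   _NA],
]


def bird_pair_repeatability() -> pd.DataFrame:
    """Cross-pair repeatability correlations for eight songbird sister pairs.

    Returns an 8x8 DataFrame holding two statistics in one square: windowed
    F_ST correlations below the diagonal and windowed d_XY correlations
    above it (diagonal NaN).  Use
    ``repeatability.variance_explained(m, "lower")`` / ``"upper"`` to read
    off the maximum coefficient of each statistic and the percent of
    variation it explains.
    """
    return pd.DataFrame(_MATRIX, index=BIRD_PAIRS, columns=BIRD_PAIRS,
                        dtype=float)
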
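"""Weighted immunohistochemistry histoscore.

Each cell's staining intensity is rated 0 (negative), 1 (low), 2 (moderate)
or 3 (high); the weighted histoscore of a specimen is

    score = sum_r r * P_r,

where P_r is the percentage of cells with rating r.  The score ranges from 0
(no cell stains) to 300 (every cell rated high).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RATINGS = (0, 1, 2, 3)


def weighted_histoscore(percentages, fractions: bool = False) -> float:
    """Weighted histoscore of a rating distribution.

    ``percentages`` maps ratings 0-3 (sequence or dict) to percentages of
    cells summing to 100.  With ``fractions=True`` the input sums to 1 and is
    rescaled.  Returns a score in [0, 300].
    """
    if isinstance(percentages, dict):
        p = np.array([percentages.get(r, 0.0) for r in RATINGS], dtype=float)
    else:
        p = np.asarray(percentages, dtype=float)
    if p.size != 4:
        raise ValueError("need percentages for the four ratings 0-3")
    if np.any(p < 0):
        raise ValueError("negative percentage")
    if fractions:
        p = 100.0 * p
    if abs(p.sum() - 100.0) > 1e-9:
        raise ValueError(f"percentages sum to {p.sum()}, expected 100")
    return float(np.dot(RATINGS, p))


def histoscore_from_cells(ratings) -> float:
    """Tabulate per-cell integer ratings 0-3 and apply the weighted formula."""
    r = np.asarray(pd.Series(ratings).to_numpy())
    if r.size == 0:
        raise ValueError("no cells")
    if np.any((r < 0) | (r > 3) | (r != np.round(r))):
        raise ValueError("ratings must be integers in 0..3")
    pct = np.array([(r == k).mean() * 100.0 for k in RATINGS])
    return weighted_histoscore(pct)
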
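"""Observed cluster-by-surgery contingency tables from the clinical cohort
that the synthetic generator emulates.

Rows are surgical groups (AVR, Ozaki, Ross, valve-sparing), columns are
the shape clusters found by correlation-distance WPGMA clustering of
that cohort's aortas, for the four study arms (pre-/post-operative x
ascending/whole aorta).  The pre-operative whole-aorta table has 46
subjects: one stented aorta was excluded from that arm.

These printed counts are inputs: the chi-squared layer can be exercised
on the real cohort's tables even though the underlying imaging is not
distributable.
"""

from __future__ import annotations

import numpy as np

from .clustering import ContingencyTable

__all__ = ["COHORT_TABLES", "cohort_table"]

_GROUPS = ("AVR", "Ozaki", "Ross", "VS")

_RAW = {
    "preop_ascending": [
        [3, 0, 8, 4],
        [2, 5, 4, 4],
        [0, 12, 0, 1],
        [1, 0, 1, 2],
    ],
    "preop_whole": [
        [3, 2, 3, 4, 2],
        [6, 1, 1, 4, 3],
        [2, 1, 0, 0, 10],
        [1, 0, 1, 2, 0],
    ],
    "postop_ascending": [
        [4, 5, 3],
        [2, 2, 6],
        [3, 1, 6],
        [1, 0, 2],
    ],
    "postop_whole": [
        [2, 5, 1, 2, 2],
        [1, 2, 4, 1, 2],
        [1, 8, 0, 1, 0],
        [0, 2, 1, 0, 0],
    ],
}


def cohort_table(arm: str) -> ContingencyTable:
    """One of the four observed cohort tables by arm name."""
    if arm not in _RAW:
        raise KeyError(f"unknown arm {arm!r}; choose from {sorted(_RAW)}")
    counts = np.asarray(_RAW[arm], dtype=np.int64)
    cols = tuple(f"cluster_{j + 1}" for j in range(counts.shape[1]))
    return ContingencyTable(counts, _GROUPS, cols)


COHORT_TABLES = {name: cohort_table(name) for name in _RAW}
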
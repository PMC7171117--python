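"""Published census and parentage bookkeeping for the Västerhus seed orchard.

The Västerhus Scots pine seed orchard (northern Sweden, established 1991)
holds 28 clonal parent genotypes deployed linearly — ramet numbers
proportional to breeding values, 35 to 332 ramets per genotype, 3782 ramets
in total across the tabulated parents. Per parent the table records the
number of sampled seedlings sired by internal pollination (IP counts each
parental gamete slot of a both-internal offspring, so they sum to
2 x 196 = 392) and by external pollination (EP: seedlings where the parent
is the sole internal parent; 98 in total).

These counts are the worked reference dataset for the mating-structure
statistics and double as the default ramet deployment of the simulator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ORCHARD_TABLE", "RAMET_COUNTS", "orchard_table"]

_ROWS = [
    # parent_id, ramets, IP, EP
    ("AC3056", 332, 30, 4),
    ("Y2005", 309, 28, 7),
    ("Y4016", 276, 24, 8),
    ("AC1006", 239, 9, 2),
    ("Y3012", 229, 11, 2),
    ("Z3007", 221, 27, 5),
    ("Y4507", 214, 48, 15),
    ("Z2081", 206, 39, 9),
    ("Y3014", 192, 36, 14),
    ("AC2064", 167, 15, 3),
    ("Y3001", 166, 14, 5),
    ("AC3040", 127, 18, 2),
    ("Z4022", 122, 7, 1),
    ("Z4003", 108, 7, 1),
    ("Y4508", 107, 15, 5),
    ("Z3029", 93, 7, 0),
    ("Z3009", 87, 4, 0),
    ("X4203", 67, 1, 0),
    ("AC4221", 65, 9, 3),
    ("Y2004", 64, 3, 1),
    ("Z4019", 60, 11, 5),
    ("AC1075", 58, 2, 0),
    ("AC2047", 55, 3, 0),
    ("AC3033", 49, 2, 0),
    ("AC3015", 47, 3, 1),
    ("AC3065", 46, 3, 0),
    ("Y4103", 41, 3, 1),
    ("Z4032", 35, 13, 4),
]

ORCHARD_TABLE = pd.DataFrame(
    _ROWS, columns=["parent_id", "ramets", "ip", "ep"]
).set_index("parent_id", drop=False)

RAMET_COUNTS = tuple(int(r) for _, r, _, _ in _ROWS)

# Integrity of the transcribed census
assert ORCHARD_TABLE["ramets"].sum() == 3782
assert ORCHARD_TABLE["ip"].sum() == 392
assert ORCHARD_TABLE["ep"].sum() == 98


def orchard_table() -> pd.DataFrame:
    """A fresh copy of the per-parent (ramets, IP, EP) census."""
    return ORCHARD_TABLE.copy()


def ramet_proportions() -> np.ndarray:
    counts = ORCHARD_TABLE["ramets"].to_numpy(dtype=float)
    return counts / counts.sum()
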
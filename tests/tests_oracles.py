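"""Independent brute-force oracles shared by the acceptance suite."""

from itertools import product

import numpy as np
import pandas as pd


def brute_force_ss_2x3(y):
    """Explicit mean-subtraction sums of squares for a subjects x 2 x 3 array."""
    n, a, b = y.shape
    gm = y.mean()
    ms = y.mean(axis=(1, 2))
    ma = y.mean(axis=(0, 2))
    mb = y.mean(axis=(0, 1))
    mab = y.mean(axis=0)
    msa = y.mean(axis=2)
    msb = y.mean(axis=1)
    ss = {
        "S": a * b * np.sum((ms - gm) ** 2),
        "A": n * b * np.sum((ma - gm) ** 2),
        "B": n * a * np.sum((mb - gm) ** 2),
        "AB": n * np.sum((mab - ma[:, None] - mb[None, :] + gm) ** 2),
        "SA": b * np.sum((msa - ms[:, None] - ma[None, :] + gm) ** 2),
        "SB": a * np.sum((msb - ms[:, None] - mb[None, :] + gm) ** 2),
    }
    resid = (
        y
        - mab[None]
        - msa[:, :, None]
        - msb[:, None, :]
        + ms[:, None, None]
        + ma[None, :, None]
        + mb[None, None, :]
        - gm
    )
    ss["SAB"] = np.sum(resid**2)
    return ss


def long_table_2x3(y):
    n, a, b = y.shape
    rows = [
        {"subj": s, "A": f"a{i}", "B": f"b{j}", "y": y[s, i, j]}
        for s, i, j in product(range(n), range(a), range(b))
    ]
    return pd.DataFrame(rows)
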
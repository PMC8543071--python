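"""Moving-window response-bias analysis.

Signed report errors are demeaned per participant (removing general
clockwise/anticlockwise response biases), then binned by the signed
target-to-interference angular difference ``delta`` with overlapping
windows (default: centers every 5 degrees, window width 45 degrees, with
circular wrap on the 180-degree period).  Signed areas under the curve
are integrated separately for negative and positive ``delta``; an
attractive bias has matching signs of bias and ``delta``, so the
attraction statistic (auc_pos - auc_neg)/2 is positive under attraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .circular import abs_dev, signed_diff
from .errors import DegenerateVarianceError, InsufficientDataError

__all__ = [
    "BiasCurve",
    "AucResult",
    "demean_signed_errors",
    "compute_bias_curve",
    "integrate_auc",
    "equated_bias",
    "attraction_test",
]


@dataclass
class BiasCurve:
    centers: np.ndarray  # degrees; empty windows dropped
    values: np.ndarray  # mean demeaned signed error per window
    counts: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"center": self.centers, "value": self.values, "count": self.counts})


class AucResult(NamedTuple):
    auc_neg: float
    auc_pos: float
    attraction_stat: float


def demean_signed_errors(records: pd.DataFrame) -> pd.DataFrame:
    """Attach signed, demeaned error and delta columns.

    ``signed_error`` is signed_diff(report, target); ``demeaned_error``
    subtracts each participant's mean signed error over all their trials
    (all conditions); ``delta`` is signed_diff(interference, target) on
    interference trials and NaN otherwise.
    """
    out = records.copy()
    out["signed_error"] = signed_diff(
        out["report_angle"].to_numpy(dtype=float), out["target_angle"].to_numpy(dtype=float)
    )
    out["demeaned_error"] = out["signed_error"] - out.groupby("participant_id")["signed_error"].transform("mean")
    delta = np.full(len(out), np.nan)
    m = out["interference_present"].to_numpy(dtype=bool)
    delta[m] = signed_diff(
        out.loc[m, "interference_angle"].to_numpy(dtype=float),
        out.loc[m, "target_angle"].to_numpy(dtype=float),
    )
    out["delta"] = delta
    return out


def compute_bias_curve(demeaned_errors, deltas, step: float = 5.0, width: float = 45.0) -> BiasCurve:
    """Overlapping-window bias curve over the 180-degree difference axis."""
    e = np.asarray(demeaned_errors, dtype=float)
    d = np.asarray(deltas, dtype=float)
    ok = np.isfinite(e) & np.isfinite(d)
    e, d = e[ok], d[ok]
    if e.size == 0:
        raise InsufficientDataError("no trials with defined delta")
    centers = np.arange(-90.0, 90.0, step)
    half = width / 2.0
    vals, counts, keep = [], [], []
    for c in centers:
        m = abs_dev(d, c) <= half
        if m.any():
            keep.append(c)
            vals.append(float(e[m].mean()))
            counts.append(int(m.sum()))
    return BiasCurve(np.array(keep), np.array(vals), np.array(counts, dtype=int))


def integrate_auc(curve: BiasCurve) -> AucResult:
    """Trapezoidal signed areas for negative and positive window centers.

    The 0-degree center, if present, contributes to neither side.
    """
    neg = curve.centers < 0
    pos = curve.centers > 0
    if neg.sum() < 2 or pos.sum() < 2:
        raise InsufficientDataError("bias curve must be populated on both sides of zero")
    auc_neg = float(np.trapezoid(curve.values[neg], curve.centers[neg]))
    auc_pos = float(np.trapezoid(curve.values[pos], curve.centers[pos]))
    return AucResult(auc_neg, auc_pos, (auc_pos - auc_neg) / 2.0)


def equated_bias(records: pd.DataFrame, cells: tuple[str, ...] = ("interference_type", "predictability")) -> pd.DataFrame:
    """Sign-equated attraction per participant x condition cell.

    For each cell: (mean demeaned error over trials with delta > 0 minus
    mean over trials with delta < 0) / 2; positive values = attraction.
    Input must carry ``demeaned_error`` and ``delta`` columns (see
    :func:`demean_signed_errors`); delta == 0 trials are uninformative for
    the sign split and are ignored.
    """
    df = records[np.isfinite(records["delta"].to_numpy(dtype=float))]
    rows = []
    for keys, sub in df.groupby(["participant_id", *cells], observed=True, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        d = sub["delta"].to_numpy(dtype=float)
        e = sub["demeaned_error"].to_numpy(dtype=float)
        if not (d > 0).any() or not (d < 0).any():
            raise InsufficientDataError(f"cell {keys} has no trials on one side of delta = 0")
        row = dict(zip(["participant_id", *cells], keys))
        row["equated_bias"] = (e[d > 0].mean() - e[d < 0].mean()) / 2.0
        rows.append(row)
    return pd.DataFrame(rows)


def attraction_test(values) -> dict:
    """One-sample two-tailed t test of per-participant attraction vs 0."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise InsufficientDataError("need at least 2 participants")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateVarianceError("zero variance across participants")
    t = v.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return {"t": float(t), "df": n - 1, "p": float(p), "cohen_d": float(v.mean() / sd), "n": n}
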
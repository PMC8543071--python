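"""Per-trial and per-condition performance measures.

The reproduction error of a trial is the absolute angular deviation
between the reported and the probed orientation (0..90 degrees); condition
summaries aggregate it per participant x design cell.  The within-subject
SEM removes per-participant offsets (recentre each participant on the
grand mean) and applies the M/(M-1) small-sample correction, M being the
number of cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .circular import abs_dev
from .errors import DegenerateVarianceError, IncompleteDesignError, InvalidInputError, MissingResponseError

__all__ = [
    "reproduction_error",
    "feedback_score",
    "condition_means",
    "paired_contrast",
    "within_subject_sem",
]


def reproduction_error(report_angle, target_angle):
    """Absolute deviation report vs. target on the orientation space, in [0, 90]."""
    r = np.asarray(report_angle, dtype=float)
    if np.any(np.isnan(r)):
        raise MissingResponseError("trial has no report_angle")
    return abs_dev(report_angle, target_angle)


def feedback_score(error):
    """Linear feedback: 100 at zero error, 0 at 90 degrees, rounded to integer."""
    e = np.asarray(error, dtype=float)
    if np.any((e < 0) | (e > 90) | ~np.isfinite(e)):
        raise InvalidInputError("error must lie in [0, 90]")
    score = np.rint(100.0 * (1.0 - e / 90.0))
    if score.ndim == 0:
        return int(score)
    return score.astype(int)


def add_errors(records: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``reproduction_error`` column (requires report_angle)."""
    out = records.copy()
    out["reproduction_error"] = reproduction_error(
        out["report_angle"].to_numpy(dtype=float), out["target_angle"].to_numpy(dtype=float)
    )
    return out


def condition_means(records: pd.DataFrame, cells: list[str]) -> pd.DataFrame:
    """Mean reproduction error per participant x cell (tidy frame).

    ``cells`` are column names defining the design cell.  Cells with zero
    trials are simply absent from the output.  Interrupter RT means are
    included where the cell contains interrupter responses.
    """
    df = records if "reproduction_error" in records.columns else add_errors(records)
    grouped = df.groupby(["participant_id", *cells], dropna=False, observed=True)
    out = grouped.agg(
        mean_abs_error=("reproduction_error", "mean"),
        n_trials=("reproduction_error", "size"),
        mean_interrupter_rt=("interrupter_rt_ms", "mean"),
    ).reset_index()
    return out


def paired_contrast(summaries: pd.DataFrame, cell_col: str, a, b, value: str = "mean_abs_error") -> pd.Series:
    """Per-participant difference value(a) - value(b) for one cell factor."""
    wide = summaries.pivot_table(index="participant_id", columns=cell_col, values=value, observed=True)
    for lvl in (a, b):
        if lvl not in wide.columns or wide[lvl].isna().any():
            raise IncompleteDesignError(f"cell {lvl!r} missing for some participant")
    return wide[a] - wide[b]


def within_subject_sem(matrix: pd.DataFrame) -> pd.Series:
    """Within-subject SEM per cell from a participants x cells matrix.

    Each participant's values are recentred (subtract the participant
    mean, add the grand mean); the per-cell SEM of the recentred values is
    then multiplied by sqrt(M / (M - 1)) where M is the number of cells.
    """
    if matrix.isna().any().any():
        raise IncompleteDesignError("participant x cell matrix has missing cells")
    m = matrix.shape[1]
    if m < 2:
        raise InvalidInputError("within-subject SEM needs at least 2 cells")
    n = matrix.shape[0]
    if n < 2:
        raise DegenerateVarianceError("need at least 2 participants")
    centred = matrix.sub(matrix.mean(axis=1), axis=0) + matrix.to_numpy().mean()
    sem = centred.std(axis=0, ddof=1) / np.sqrt(n)
    return sem * np.sqrt(m / (m - 1))
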
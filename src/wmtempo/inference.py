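"""Repeated-measures inference: fully within-subjects ANOVA with
generalized eta squared, paired t with Cohen's d (d_z variant), Bonferroni
adjustment, and exact paired-t power / sample-size via the noncentral t.

The ANOVA is the classical sums-of-squares decomposition for balanced,
fully within designs (1-3 factors): every effect is tested against its
own subject-by-effect interaction, no sphericity correction is applied,
and generalized eta squared scales an effect's SS against all
subject-related SS terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateVarianceError,
    IncompleteDesignError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "TTestResult",
    "rm_anova",
    "paired_t",
    "bonferroni",
    "power_paired_t",
    "required_sample_size",
]


@dataclass
class TTestResult:
    t: float
    df: int
    p_raw: float
    p_bonferroni: float
    cohen_d: float


def _effect_ss(y: np.ndarray, axes: tuple[int, ...]) -> float:
    """SS of the effect spanned by ``axes`` via inclusion-exclusion of marginal means."""
    all_axes = tuple(range(y.ndim))
    est = np.zeros_like(y)
    for r in range(len(axes) + 1):
        for sub in combinations(axes, r):
            reduce_over = tuple(a for a in all_axes if a not in sub)
            marg = y.mean(axis=reduce_over, keepdims=True)
            est = est + ((-1) ** (len(axes) - len(sub))) * marg
    return float(np.sum(np.broadcast_to(est, y.shape) ** 2))


def rm_anova(data: pd.DataFrame, dv: str, within: list[str], subject: str) -> pd.DataFrame:
    """Fully within-subjects ANOVA on a long table of cell means.

    Returns a table with one row per within effect: effect label, df_num,
    df_den, F, p, ges, plus the raw SS terms (ss_effect, ss_error).
    """
    if not 1 <= len(within) <= 3:
        raise InvalidInputError("supports 1-3 within factors")
    subjects = sorted(data[subject].unique())
    if len(subjects) < 2:
        raise InsufficientDataError("need at least 2 subjects")
    levels = {f: sorted(data[f].unique()) for f in within}

    cell = data.groupby([subject, *within], observed=True)[dv].agg(["mean", "size"])
    expected = len(subjects) * int(np.prod([len(levels[f]) for f in within]))
    if len(cell) != expected:
        raise IncompleteDesignError(
            f"design incomplete: {len(cell)} populated subject x cell combinations, expected {expected}"
        )

    shape = (len(subjects), *[len(levels[f]) for f in within])
    y = np.full(shape, np.nan)
    s_idx = {s: i for i, s in enumerate(subjects)}
    l_idx = [{lv: i for i, lv in enumerate(levels[f])} for f in within]
    for keys, row in cell.iterrows():
        idx = (s_idx[keys[0]], *[l_idx[k][keys[k + 1]] for k in range(len(within))])
        y[idx] = row["mean"]

    subj_axis = 0
    factor_axes = {f: i + 1 for i, f in enumerate(within)}
    ss: dict[tuple[int, ...], float] = {}
    dfree: dict[tuple[int, ...], int] = {}
    all_axes = [subj_axis, *factor_axes.values()]
    for r in range(1, len(all_axes) + 1):
        for axes in combinations(all_axes, r):
            ss[axes] = _effect_ss(y, axes)
            dfree[axes] = int(np.prod([shape[a] - 1 for a in axes]))

    subject_related = sum(v for k, v in ss.items() if subj_axis in k)

    rows = []
    for r in range(1, len(within) + 1):
        for combo in combinations(within, r):
            axes = tuple(sorted(factor_axes[f] for f in combo))
            err_axes = tuple(sorted((subj_axis, *axes)))
            ss_eff, ss_err = ss[axes], ss[err_axes]
            df_num, df_den = dfree[axes], dfree[err_axes]
            if ss_err <= 0:
                raise DegenerateVarianceError(f"zero error SS for effect {combo}")
            f_val = (ss_eff / df_num) / (ss_err / df_den)
            rows.append(
                {
                    "effect": " x ".join(combo),
                    "df_num": df_num,
                    "df_den": df_den,
                    "F": f_val,
                    "p": float(stats.f.sf(f_val, df_num, df_den)),
                    "ges": ss_eff / (ss_eff + subject_related),
                    "ss_effect": ss_eff,
                    "ss_error": ss_err,
                }
            )
    return pd.DataFrame(rows)


def paired_t(x, y, m: int = 1) -> TTestResult:
    """Paired-samples two-tailed t test; Cohen's d = mean(diff)/SD(diff)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise InvalidInputError("x and y must be equal-length with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateVarianceError("zero variance of paired differences")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TTestResult(
        t=float(t),
        df=n - 1,
        p_raw=float(p),
        p_bonferroni=float(min(1.0, p * m)),
        cohen_d=float(d.mean() / sd),
    )


def bonferroni(p_values, m: int | None = None, allow_smaller_family: bool = False):
    """Bonferroni adjustment: min(1, p * m) elementwise.

    ``m`` defaults to the number of p values; a family smaller than the
    number of tests requires ``allow_smaller_family=True``.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("p values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise InvalidInputError("family size must be >= 1")
    if m < p.size and not allow_smaller_family:
        raise InvalidInputError("family smaller than number of tests; pass allow_smaller_family=True to override")
    out = np.minimum(1.0, p * m)
    return float(out[0]) if np.ndim(p_values) == 0 else out


def power_paired_t(n: int, d: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Exact power of a paired t test via the noncentral t distribution."""
    if n < 2 or not 0 < alpha < 1 or tails not in (1, 2):
        raise InvalidInputError("need n >= 2, 0 < alpha < 1, tails in {1, 2}")
    df = n - 1
    nc = d * np.sqrt(n)
    if tails == 2:
        tc = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(tc, df, nc) + stats.nct.cdf(-tc, df, nc))
    tc = stats.t.ppf(1 - alpha, df)
    return float(stats.nct.sf(tc, df, nc))


def required_sample_size(d: float, alpha: float = 0.05, power: float = 0.95, tails: int = 2, n_max: int = 100000) -> int:
    """Smallest n whose paired-t power reaches ``power`` at effect size ``d``."""
    if d <= 0 or not 0 < power < 1:
        raise InvalidInputError("need d > 0 and 0 < power < 1")
    for n in range(2, n_max + 1):
        if power_paired_t(n, d, alpha, tails) >= power:
            return n
    raise InvalidInputError(f"target power not attainable with n <= {n_max}")
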
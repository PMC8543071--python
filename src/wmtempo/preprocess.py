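"""Trial-removal and participant-exclusion rules.

Rules are evaluated per trial in a fixed order and each rejected trial is
attributed exactly one reason (the first triggered):

1. ``probe_rt_gt_5000``        probe RT above the absolute 5000-ms cut
2. ``probe_rt_gt_2p5sd``       probe RT above the participant's mean + 2.5 SD
                               (statistic computed over that participant's
                               trials surviving rule 1, all conditions)
3. ``dial_timeout``            report not completed within 4000 ms
4. ``distractor_keypress``     keypress to the distractor (distraction blocks)
5. ``interrupter_no_response`` no response to the interrupter
6. ``interrupter_wrong_key``   response key opposite to the interrupter tilt
7. ``interrupter_rt_gt_1000``  interrupter response slower than 1000 ms

Participants with a rejected-trial fraction strictly above the threshold
(default 10%) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import DISTRACTION, INTERRUPTION
from .errors import SchemaError

__all__ = ["Thresholds", "RejectionLog", "filter_trials", "exclude_participants"]

REASONS = [
    "probe_rt_gt_5000",
    "probe_rt_gt_2p5sd",
    "dial_timeout",
    "distractor_keypress",
    "interrupter_no_response",
    "interrupter_wrong_key",
    "interrupter_rt_gt_1000",
]

_REQUIRED = [
    "participant_id", "trial_index", "interference_type", "interference_present",
    "interference_angle", "probe_rt_ms", "dial_time_ms",
    "interrupter_response", "interrupter_rt_ms", "distractor_keypress",
]


@dataclass(frozen=True)
class Thresholds:
    probe_rt_abs_ms: float = 5000.0
    probe_rt_sd: float = 2.5
    dial_ms: float = 4000.0
    interrupter_rt_ms: float = 1000.0
    exclusion_fraction: float = 0.10


@dataclass
class RejectionLog:
    """Per-trial rejections plus per-participant bookkeeping."""

    trials: pd.DataFrame  # columns: participant_id, trial_index, reason
    participants: pd.DataFrame  # participant_id, n_trials, n_rejected, fraction_rejected, excluded
    rt_cutoffs: dict[int, float] = field(default_factory=dict)  # frozen mean + 2.5 SD per participant

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)

    def summary_dict(self) -> dict:
        return {
            str(r.participant_id): {
                "n_trials": int(r.n_trials),
                "n_rejected": int(r.n_rejected),
                "fraction_rejected": float(r.fraction_rejected),
                "excluded": bool(r.excluded),
            }
            for r in self.participants.itertuples(index=False)
        }


def filter_trials(
    records: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    rt_cutoffs: dict[int, float] | None = None,
) -> tuple[pd.DataFrame, RejectionLog]:
    """Apply the trial-removal rules; return (kept records, log).

    ``rt_cutoffs`` lets a caller re-apply a previously frozen mean+2.5SD
    statistic (this makes filtering idempotent: feeding the kept records
    back with the logged cutoffs removes nothing).
    """
    missing = [c for c in _REQUIRED if c not in records.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df = records
    pid = df["participant_id"].to_numpy()
    probe_rt = df["probe_rt_ms"].to_numpy(dtype=float)
    dial = df["dial_time_ms"].to_numpy(dtype=float)
    itype = df["interference_type"].to_numpy()
    present = df["interference_present"].to_numpy(dtype=bool)
    inter_angle = df["interference_angle"].to_numpy(dtype=float)
    resp = df["interrupter_response"].to_numpy(dtype=object)
    irt = df["interrupter_rt_ms"].to_numpy(dtype=float)
    keypress = df["distractor_keypress"].to_numpy(dtype=object)

    r1 = probe_rt > thresholds.probe_rt_abs_ms

    cutoffs: dict[int, float] = {}
    r2 = np.zeros(len(df), dtype=bool)
    for p in np.unique(pid):
        m = pid == p
        if rt_cutoffs is not None and int(p) in rt_cutoffs:
            cut = rt_cutoffs[int(p)]
        else:
            surv = probe_rt[m & ~r1]
            if surv.size >= 2:
                cut = float(np.mean(surv) + thresholds.probe_rt_sd * np.std(surv, ddof=1))
            else:
                cut = np.inf
        cutoffs[int(p)] = cut
        r2[m] = ~r1[m] & (probe_rt[m] > cut)

    r3 = dial > thresholds.dial_ms
    r4 = (itype == DISTRACTION) & np.array(
        [isinstance(v, (bool, np.bool_)) and bool(v) for v in keypress]
    )
    is_intr = (itype == INTERRUPTION) & present
    r5 = is_intr & np.array([v is None or v == "none" for v in resp])
    resp_sign = np.where(np.array([v == "left" for v in resp]), -1.0, 1.0)
    r6 = is_intr & ~r5 & (resp_sign * inter_angle < 0)
    with np.errstate(invalid="ignore"):
        r7 = is_intr & (irt > thresholds.interrupter_rt_ms)

    reason = np.full(len(df), None, dtype=object)
    for name, mask in zip(REASONS, [r1, r2, r3, r4, r5, r6, r7]):
        reason[(reason == None) & mask] = name  # noqa: E711 -- elementwise None test

    rejected = reason != None  # noqa: E711
    trial_log = pd.DataFrame(
        {
            "participant_id": pid[rejected],
            "trial_index": df["trial_index"].to_numpy()[rejected],
            "reason": reason[rejected],
        }
    )
    rows = []
    for p in np.unique(pid):
        m = pid == p
        n, nr = int(m.sum()), int((m & rejected).sum())
        rows.append(
            {
                "participant_id": p,
                "n_trials": n,
                "n_rejected": nr,
                "fraction_rejected": nr / n,
                "excluded": nr / n > thresholds.exclusion_fraction,
            }
        )
    log = RejectionLog(trials=trial_log, participants=pd.DataFrame(rows), rt_cutoffs=cutoffs)
    return df.loc[~rejected].reset_index(drop=True), log


def exclude_participants(log: RejectionLog, threshold: float = 0.10) -> list[int]:
    """Participant ids whose rejected fraction is <= threshold (kept set).

    Exclusion uses a strict inequality: exactly 10% rejected is kept.
    """
    keep = log.participants.loc[log.participants["fraction_rejected"] <= threshold, "participant_id"]
    return [int(p) for p in keep]
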
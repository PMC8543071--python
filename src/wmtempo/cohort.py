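"""Synthetic behavioral cohorts for the dual-item continuous-report task.

Two responsibilities live here:

* :func:`build_schedule` emits the factorial trial schedule for one
  participant — 12 blocks x 32 trials by default, with interference type
  (distraction vs. interruption) nested within block pairs of constant
  temporal predictability (fixed vs. variable onset), 75% interference
  trials per block, and onset/tilt counterbalancing.
* :func:`simulate_responses` fills in behavioral responses under a
  generative model: a three-component report mixture (target / swap to
  the interfering item / uniform guess) with von Mises noise on the
  doubled circle, a sinusoidal attraction bias toward the interfering
  item, shifted-lognormal reaction times, and configurable contaminant
  trials that each violate exactly one preprocessing rule.

Trial tables are plain :class:`pandas.DataFrame` objects with the column
set in :data:`TRIAL_COLUMNS`; :func:`write_cohort` / :func:`read_cohort`
round-trip them through a CSV dialect where an empty cell means absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .circular import signed_diff, to_full_circle, from_full_circle
from .errors import ConfigurationError, ParseError

__all__ = [
    "DesignSpec",
    "GenerativeParams",
    "TrialRecord",
    "TRIAL_COLUMNS",
    "build_schedule",
    "simulate_responses",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

DISTRACTION = "distraction"
INTERRUPTION = "interruption"
FIXED = "fixed"
VARIABLE = "variable"

#: exact column order of the trial CSV dialect
TRIAL_COLUMNS = [
    "participant_id",
    "block_index",
    "trial_index",
    "interference_type",
    "predictability",
    "interference_present",
    "onset_ms",
    "target_angle",
    "nonprobed_angle",
    "interference_angle",
    "probed_side",
    "report_angle",
    "probe_rt_ms",
    "dial_time_ms",
    "interrupter_response",
    "interrupter_rt_ms",
    "distractor_keypress",
]

_STRING_COLUMNS = {"interference_type", "predictability", "probed_side", "interrupter_response"}
_BOOL_COLUMNS = {"interference_present", "distractor_keypress"}
_INT_COLUMNS = {"participant_id", "block_index", "trial_index"}


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the factorial trial schedule."""

    n_participants: int = 54
    n_blocks: int = 12
    trials_per_block: int = 32
    interference_proportion: float = 0.75
    onsets_ms: tuple[int, ...] = (500, 1250, 2000)
    angle_grid_min: int = 5
    angle_grid_max: int = 85
    angle_grid_step: int = 5
    delay_ms: int = 2750
    interference_duration_ms: int = 250
    rng_seed: int = 0

    @property
    def angle_grid(self) -> np.ndarray:
        """Positive tilt magnitudes, e.g. 5..85 in 5-degree steps."""
        return np.arange(self.angle_grid_min, self.angle_grid_max + 1, self.angle_grid_step, dtype=float)

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def interference_per_block(self) -> int:
        return round(self.trials_per_block * self.interference_proportion)

    def validate(self) -> None:
        k = len(self.onsets_ms)
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if abs(self.trials_per_block * self.interference_proportion - self.interference_per_block) > 1e-9:
            raise ConfigurationError("trials_per_block x interference_proportion must be an integer")
        if self.n_blocks != 4 * k:
            raise ConfigurationError(
                f"n_blocks must be 4 x number of onsets ({4 * k}) so each onset gets one "
                f"fixed-onset block per interference type; got {self.n_blocks}"
            )
        if self.interference_per_block % k != 0:
            raise ConfigurationError("interference trials per block must split equally across onsets")
        if self.interference_per_block % 2 != 0:
            raise ConfigurationError("interference trials per block must be even for tilt counterbalancing")
        if len(self.angle_grid) == 0:
            raise ConfigurationError("empty angle grid")


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the generative response model.

    ``kappa_base`` is the von Mises concentration of report noise on the
    doubled circle.  Condition effects enter as multiplicative kappa
    deflation: interruption blocks and variable-onset blocks multiply the
    concentration by factors < 1, which monotonically inflates the mean
    absolute error in those cells.  The attraction bias toward the
    interfering item is ``bias_amplitude * sin(2 * delta)`` degrees with
    ``delta = signed_diff(interference, target)``.
    """

    kappa_base: float = 12.0
    p_swap: float = 0.05
    p_guess: float = 0.08
    bias_amplitude: float = 2.0
    interruption_kappa_factor: float = 0.72
    variable_onset_kappa_factor: float = 0.85
    # shifted lognormals: (shift_ms, mu_log, sigma_log)
    rt_probe_params: tuple[float, float, float] = (250.0, 6.5, 0.40)
    rt_dial_params: tuple[float, float, float] = (500.0, 7.2, 0.30)
    rt_interrupter_params: tuple[float, float, float] = (150.0, 6.0, 0.30)
    # additive ms offsets on the interrupter RT shift, keyed (predictability, onset)
    interrupter_rt_offsets_ms: Mapping[tuple[str, int], float] = field(
        default_factory=lambda: {
            (FIXED, 500): 0.0,
            (FIXED, 1250): 0.0,
            (FIXED, 2000): 0.0,
            (VARIABLE, 500): 90.0,
            (VARIABLE, 1250): 10.0,
            (VARIABLE, 2000): 0.0,
        }
    )
    contamination_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "slow_probe_rt": 0.010,
            "slow_dial": 0.010,
            "distractor_keypress": 0.020,
            "interrupter_miss": 0.015,
            "interrupter_wrong_key": 0.015,
            "interrupter_slow": 0.020,
        }
    )

    def validate(self) -> None:
        if not (0.0 <= self.p_swap <= 1.0 and 0.0 <= self.p_guess <= 1.0):
            raise ConfigurationError("p_swap and p_guess must lie in [0, 1]")
        if self.p_swap + self.p_guess > 1.0:
            raise ConfigurationError("p_swap + p_guess must not exceed 1")
        if self.kappa_base <= 0:
            raise ConfigurationError("kappa_base must be positive")
        if not np.isfinite(self.bias_amplitude):
            raise ConfigurationError("bias_amplitude must be finite")
        for k in (self.interruption_kappa_factor, self.variable_onset_kappa_factor):
            if k <= 0:
                raise ConfigurationError("kappa factors must be positive")
        for name, r in self.contamination_rates.items():
            if not (0.0 <= r <= 1.0):
                raise ConfigurationError(f"contamination rate {name!r} outside [0, 1]")


@dataclass
class TrialRecord:
    """One behavioral trial; ``None`` marks an absent (empty-cell) field."""

    participant_id: int
    block_index: int
    trial_index: int
    interference_type: str
    predictability: str
    interference_present: bool
    onset_ms: float | None
    target_angle: float
    nonprobed_angle: float
    interference_angle: float | None
    probed_side: str
    report_angle: float | None = None
    probe_rt_ms: float | None = None
    dial_time_ms: float | None = None
    interrupter_response: str | None = None
    interrupter_rt_ms: float | None = None
    distractor_keypress: bool | None = None


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records], columns=TRIAL_COLUMNS)
    return _normalise_frame(df)


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    out = []
    for row in df.itertuples(index=False):
        d = {c: getattr(row, c) for c in TRIAL_COLUMNS}
        for c, v in d.items():
            if v is pd.NA or (isinstance(v, float) and np.isnan(v)):
                d[c] = None
        out.append(TrialRecord(**d))
    return out


def _participant_rng(seed: int, participant_id: int, stream: int) -> np.random.Generator:
    """Stable per-participant substream: SeedSequence(seed, spawn_key=(pid, stream))."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(participant_id, stream)))


def build_schedule(spec: DesignSpec, participant_id: int) -> pd.DataFrame:
    """Build the stimulus-side trial schedule for one participant.

    Block ordering follows the nesting rule: blocks come in pairs of the
    same temporal predictability, each pair containing both interference
    types in random order; fixed- and variable-onset pairs alternate,
    with the starting predictability counterbalanced across participants
    (even participant ids start fixed); the onset order of the fixed-onset
    blocks is randomised independently per interference type.
    """
    spec.validate()
    rng = _participant_rng(spec.rng_seed, participant_id, 0)
    onsets = list(spec.onsets_ms)
    k = len(onsets)
    n_pairs_per_pred = spec.n_blocks // 4  # = k

    # onset order of fixed-onset blocks, independent per interference type
    fixed_onsets = {
        DISTRACTION: list(rng.permutation(onsets)),
        INTERRUPTION: list(rng.permutation(onsets)),
    }

    start_fixed = participant_id % 2 == 0
    pred_seq: list[str] = []
    for i in range(2 * n_pairs_per_pred):
        fixed_turn = (i % 2 == 0) == start_fixed
        pred_seq.append(FIXED if fixed_turn else VARIABLE)

    blocks: list[tuple[str, str, int | None]] = []  # (predictability, type, fixed onset)
    fixed_count = {DISTRACTION: 0, INTERRUPTION: 0}
    for pred in pred_seq:
        types = [DISTRACTION, INTERRUPTION]
        rng.shuffle(types)
        for t in types:
            if pred == FIXED:
                blocks.append((pred, t, fixed_onsets[t][fixed_count[t]]))
                fixed_count[t] += 1
            else:
                blocks.append((pred, t, None))

    n_int = spec.interference_per_block
    n_no = spec.trials_per_block - n_int
    grid = spec.angle_grid
    n_trials = spec.n_trials

    # participant-level counterbalancing of probed side and probed tilt sign
    probed_side = np.array(["left", "right"]).repeat(n_trials // 2)
    if probed_side.size < n_trials:
        probed_side = np.append(probed_side, rng.choice(["left", "right"]))
    rng.shuffle(probed_side)
    probed_sign = np.repeat([1.0, -1.0], n_trials // 2)
    if probed_sign.size < n_trials:
        probed_sign = np.append(probed_sign, rng.choice([1.0, -1.0]))
    rng.shuffle(probed_sign)

    rows: list[dict] = []
    trial_index = 0
    for block_index, (pred, itype, fixed_onset) in enumerate(blocks):
        present = np.zeros(spec.trials_per_block, dtype=bool)
        present[rng.choice(spec.trials_per_block, size=n_int, replace=False)] = True

        if pred == FIXED:
            onset_pool = np.full(n_int, fixed_onset, dtype=float)
        else:
            onset_pool = np.repeat(np.array(onsets, dtype=float), n_int // k)
            rng.shuffle(onset_pool)
        int_sign = np.repeat([1.0, -1.0], n_int // 2)
        rng.shuffle(int_sign)
        int_mag = rng.choice(grid, size=n_int)
        pool_pos = 0

        for j in range(spec.trials_per_block):
            sign_t = probed_sign[trial_index]
            target = sign_t * rng.choice(grid)
            nonprobed = -sign_t * rng.choice(grid)
            row = {
                "participant_id": participant_id,
                "block_index": block_index,
                "trial_index": trial_index,
                "interference_type": itype,
                "predictability": pred,
                "interference_present": bool(present[j]),
                "onset_ms": None,
                "target_angle": target,
                "nonprobed_angle": nonprobed,
                "interference_angle": None,
                "probed_side": probed_side[trial_index],
            }
            if present[j]:
                row["onset_ms"] = float(onset_pool[pool_pos])
                row["interference_angle"] = float(int_sign[pool_pos] * int_mag[pool_pos])
                pool_pos += 1
            rows.append(row)
            trial_index += 1

    df = pd.DataFrame(rows)
    for c in TRIAL_COLUMNS:
        if c not in df.columns:
            df[c] = None
    return _normalise_frame(df[TRIAL_COLUMNS])


def _shifted_lognormal(rng: np.random.Generator, params: tuple[float, float, float], size: int) -> np.ndarray:
    shift, mu, sigma = params
    return shift + rng.lognormal(mean=mu, sigma=sigma, size=size)


def simulate_responses(schedule: pd.DataFrame, params: GenerativeParams, seed: int) -> pd.DataFrame:
    """Simulate responses for a (possibly multi-participant) schedule.

    Deterministic given (schedule, params, seed): each participant uses a
    substream keyed by their id.
    """
    params.validate()
    if params.p_swap > 0 and not schedule["interference_present"].any():
        raise ConfigurationError("p_swap > 0 requested but schedule has no interference trials")
    parts = []
    for pid, sub in schedule.groupby("participant_id", sort=True):
        parts.append(_simulate_participant(sub.reset_index(drop=True), params, _participant_rng(seed, int(pid), 1)))
    out = pd.concat(parts, ignore_index=True)
    return _normalise_frame(out)


def _simulate_participant(df: pd.DataFrame, p: GenerativeParams, rng: np.random.Generator) -> pd.DataFrame:
    df = df.copy()
    n = len(df)
    present = df["interference_present"].to_numpy(dtype=bool)
    itype = df["interference_type"].to_numpy()
    pred = df["predictability"].to_numpy()
    target = df["target_angle"].to_numpy(dtype=float)
    inter = df["interference_angle"].to_numpy(dtype=float)  # NaN where absent

    kappa = np.full(n, p.kappa_base)
    kappa[itype == INTERRUPTION] *= p.interruption_kappa_factor
    kappa[pred == VARIABLE] *= p.variable_onset_kappa_factor

    u_guess = rng.random(n)
    u_swap = rng.random(n)
    is_guess = u_guess < p.p_guess
    is_swap = ~is_guess & present & (u_swap < p.p_swap)
    is_target = ~is_guess & ~is_swap

    centre = target.copy()
    delta = np.zeros(n)
    delta[present] = signed_diff(inter[present], target[present])
    bias = p.bias_amplitude * np.sin(2.0 * np.deg2rad(delta))
    centre[is_target & present] = target[is_target & present] + bias[is_target & present]
    centre[is_swap] = inter[is_swap]

    noise = np.empty(n)
    for k in np.unique(kappa):  # few distinct condition kappas; draw each block vectorised
        m = kappa == k
        noise[m] = rng.vonmises(0.0, k, size=int(m.sum()))
    report = from_full_circle(to_full_circle(centre) + noise)
    report[is_guess] = from_full_circle(rng.uniform(-np.pi, np.pi, size=int(is_guess.sum())))

    probe_rt = _shifted_lognormal(rng, p.rt_probe_params, n)
    dial_time = np.minimum(_shifted_lognormal(rng, p.rt_dial_params, n), 3999.0)

    interrupter_resp = np.full(n, None, dtype=object)
    interrupter_rt = np.full(n, np.nan)
    is_interrupt = present & (itype == INTERRUPTION)
    idx = np.flatnonzero(is_interrupt)
    if idx.size:
        shift, mu, sigma = p.rt_interrupter_params
        offs = np.array(
            [p.interrupter_rt_offsets_ms.get((pred[i], int(df["onset_ms"].iloc[i])), 0.0) for i in idx]
        )
        interrupter_rt[idx] = np.minimum(
            shift + offs + rng.lognormal(mu, sigma, size=idx.size), 999.0
        )
        interrupter_resp[idx] = np.where(inter[idx] < 0, "left", "right")

    keypress = np.full(n, None, dtype=object)
    keypress[itype == DISTRACTION] = False

    # contaminants: at most one per trial, each violating exactly one exclusion rule
    rates = p.contamination_rates
    u = rng.random(n)
    taken = np.zeros(n, dtype=bool)

    def _claim(mask: np.ndarray, rate: float) -> np.ndarray:
        nonlocal u
        hit = mask & ~taken & (u < rate)
        taken[hit] = True
        u = rng.random(n)
        return hit

    hit = _claim(np.ones(n, dtype=bool), rates.get("slow_probe_rt", 0.0))
    probe_rt[hit] = rng.uniform(5200.0, 8000.0, size=int(hit.sum()))
    hit = _claim(np.ones(n, dtype=bool), rates.get("slow_dial", 0.0))
    dial_time[hit] = rng.uniform(4100.0, 6000.0, size=int(hit.sum()))
    hit = _claim(present & (itype == DISTRACTION), rates.get("distractor_keypress", 0.0))
    keypress[hit] = True
    hit = _claim(is_interrupt, rates.get("interrupter_miss", 0.0))
    interrupter_resp[hit] = "none"
    interrupter_rt[hit] = np.nan
    hit = _claim(is_interrupt, rates.get("interrupter_wrong_key", 0.0))
    interrupter_resp[hit] = np.where(inter[hit] < 0, "right", "left")
    hit = _claim(is_interrupt, rates.get("interrupter_slow", 0.0))
    interrupter_rt[hit] = rng.uniform(1050.0, 2000.0, size=int(hit.sum()))

    df["report_angle"] = report
    df["probe_rt_ms"] = np.round(probe_rt, 3)
    df["dial_time_ms"] = np.round(dial_time, 3)
    df["interrupter_response"] = interrupter_resp
    df["interrupter_rt_ms"] = np.round(interrupter_rt, 3)
    df["distractor_keypress"] = keypress
    return df


def generate_cohort(spec: DesignSpec, params: GenerativeParams) -> pd.DataFrame:
    """Schedules + simulated responses for all participants in the design."""
    frames = [build_schedule(spec, pid) for pid in range(spec.n_participants)]
    return simulate_responses(pd.concat(frames, ignore_index=True), params, spec.rng_seed)


def _normalise_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for c in _INT_COLUMNS:
        df[c] = df[c].astype(int)
    for c in ("onset_ms", "target_angle", "nonprobed_angle", "interference_angle",
              "report_angle", "probe_rt_ms", "dial_time_ms", "interrupter_rt_ms"):
        df[c] = pd.to_numeric(df[c], errors="raise")
    df["interference_present"] = df["interference_present"].astype(bool)
    df["distractor_keypress"] = df["distractor_keypress"].astype("boolean")
    for c in _STRING_COLUMNS:
        df[c] = df[c].astype(object).where(df[c].notna(), None)
    return df[TRIAL_COLUMNS]


def write_cohort(df: pd.DataFrame, path) -> None:
    """Serialise a trial table to the CSV dialect (empty cell = absent)."""
    out = df[TRIAL_COLUMNS].copy()
    for c in _BOOL_COLUMNS:
        out[c] = out[c].map(lambda v: "" if v is None or v is pd.NA else ("true" if v else "false"))
    out.to_csv(path, index=False, na_rep="")


def _parse_bool(col: pd.Series, name: str) -> pd.Series:
    def conv(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return pd.NA
        if v == "true":
            return True
        if v == "false":
            return False
        raise ParseError(f"column {name!r}: cannot parse boolean value {v!r}")

    return col.map(conv).astype("boolean")


def read_cohort(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_cohort`.

    Raises :class:`ParseError` naming the missing column or the first
    malformed row (1-based data row numbers).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required column(s): {', '.join(missing)}")
    df = df.replace({"": None})
    out = pd.DataFrame(index=df.index)
    for c in TRIAL_COLUMNS:
        col = df[c]
        if c in _INT_COLUMNS:
            num = pd.to_numeric(col, errors="coerce")
            bad = num.isna()
            if bad.any():
                raise ParseError(f"row {int(bad.idxmax()) + 1}: column {c!r} has non-integer value {col[bad.idxmax()]!r}")
            out[c] = num.astype(int)
        elif c in _BOOL_COLUMNS:
            out[c] = _parse_bool(col, c)
        elif c in _STRING_COLUMNS:
            out[c] = col.astype(object).where(col.notna(), None)
        else:
            num = pd.to_numeric(col, errors="coerce")
            bad = num.isna() & col.notna()
            if bad.any():
                raise ParseError(f"row {int(bad.idxmax()) + 1}: column {c!r} has non-numeric value {col[bad.idxmax()]!r}")
            out[c] = num
    if out["interference_present"].isna().any():
        raise ParseError("column 'interference_present' has empty cells")
    out["interference_present"] = out["interference_present"].astype(bool)
    return _normalise_frame(out)
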
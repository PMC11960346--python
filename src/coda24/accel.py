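"""Epoch-level accelerometer preprocessing.

Turns per-epoch tri-axial vector-magnitude (VM3) count streams into daily
behaviour minutes and one time-use composition per participant:

1. non-wear detection (run-length rule over zero-count minutes),
2. sleep/wake scoring (weighted moving-window score classifier),
3. cut-point classification of waking wear epochs into SB / LPA / MVPA,
4. calendar-day summaries with the 10-h waking-wear validity rule,
5. averaging of valid days and closure to a 1440-min composition,
   with participants excluded below a minimum number of valid days.

The study protocol this mirrors used wrist-worn devices for 6 consecutive
days; wear-time, sleep and cut-point algorithm parameters are configuration
because vendor defaults vary — the values shipped in the default config are
illustrative, not the vendor's.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
from scipy.ndimage import correlate1d

from .coda import CompositionError, closure

#: Behaviour labels assigned to epochs.
LABELS = ("TST", "SB", "LPA", "MVPA", "NONWEAR")

#: Minimum waking wear time (minutes) for a valid day: the 10-h rule.
MIN_WAKING_WEAR_MIN = 600.0

#: Minimum number of valid days for participant inclusion.
MIN_VALID_DAYS = 4


class GapError(ValueError):
    """Raised when epoch timestamps are not contiguous at the epoch length."""


class ConfigError(ValueError):
    """Raised for invalid algorithm configuration."""


@dataclass(frozen=True)
class CutPointConfig:
    """VM3 cut-points (counts/epoch): SB if vm3 <= sb_upper, LPA if
    sb_upper < vm3 <= lpa_upper, MVPA above."""

    epoch_length_s: int = 60
    sb_upper: float = 2860.0
    lpa_upper: float = 3940.0

    def __post_init__(self) -> None:
        if not 0 <= self.sb_upper < self.lpa_upper:
            raise ConfigError("require 0 <= sb_upper < lpa_upper")
        if self.epoch_length_s <= 0 or 86400 % self.epoch_length_s:
            raise ConfigError("epoch_length_s must divide a day")


@dataclass(frozen=True)
class DailySummary:
    """Behaviour minutes and validity for one participant-day."""

    participant_id: str
    date: date
    tst_min: float
    sb_min: float
    lpa_min: float
    mvpa_min: float
    waking_wear_min: float
    is_valid: bool

    def minutes(self) -> np.ndarray:
        return np.array([self.tst_min, self.sb_min, self.lpa_min, self.mvpa_min])


def _check_contiguous(timestamps: pd.Series, epoch_length_s: int) -> None:
    ts = pd.to_datetime(timestamps)
    deltas = ts.diff().dropna().dt.total_seconds().to_numpy()
    bad = np.nonzero(deltas != epoch_length_s)[0]
    if bad.size:
        i = int(bad[0])
        raise GapError(
            f"non-contiguous epochs: gap of {deltas[i]:.0f}s after {ts.iloc[i]}"
        )


def detect_nonwear(
    vm3: np.ndarray,
    epoch_length_s: int = 60,
    window_min: float = 90.0,
    spike_tolerance_min: float = 2.0,
) -> np.ndarray:
    """Label epochs as non-wear by a run-length rule over zero counts.

    An epoch is non-wear iff it lies in a run of at least ``window_min``
    minutes of zero counts, where zero-runs may be bridged by non-zero
    interruptions of at most ``spike_tolerance_min`` minutes each (the
    bridged spike epochs are then also non-wear).

    Returns a boolean array, True = non-wear.
    """
    x = np.asarray(vm3, dtype=float)
    n = x.size
    nonwear = np.zeros(n, dtype=bool)
    if n == 0:
        return nonwear
    per_min = 60.0 / epoch_length_s
    window = int(round(window_min * per_min))
    tol = int(round(spike_tolerance_min * per_min))

    # Run-length encode the zero/non-zero pattern, then merge zero runs
    # across non-zero gaps of length <= tol (gaps at the ends never bridge).
    is_zero = x == 0
    boundaries = np.nonzero(np.diff(is_zero))[0] + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    runs = [(int(s), int(e), bool(is_zero[s])) for s, e in zip(starts, ends)]

    i = 0
    while i < len(runs):
        s, e, zero = runs[i]
        if not zero:
            i += 1
            continue
        j = i  # extend the merged run over bridgeable spikes
        end = e
        while (
            j + 2 < len(runs)
            and runs[j + 1][1] - runs[j + 1][0] <= tol  # spike short enough
            and runs[j + 2][2]  # followed by another zero run
        ):
            j += 2
            end = runs[j][1]
        if end - s >= window:
            nonwear[s:end] = True
        i = j + 1
    return nonwear


def score_sleep(
    vm3: np.ndarray,
    weights: np.ndarray,
    threshold: float,
) -> np.ndarray:
    """Sleep/wake classification by a weighted moving-window count score.

    Epoch i is scored sum_k w[k] * vm3[i + k - centre]; it is labelled
    sleep iff the score is strictly below ``threshold``.  Edges are padded
    by repeating the boundary epochs.  ``weights`` must have odd length so
    the window has a centre.

    Returns a boolean array, True = sleep.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size % 2 == 0:
        raise ConfigError("sleep-score weight vector must be 1-d with odd length")
    x = np.asarray(vm3, dtype=float)
    scores = correlate1d(x, w, mode="nearest")
    return scores < threshold


def classify_waking_epochs(
    vm3: np.ndarray,
    wear: np.ndarray,
    sleep: np.ndarray,
    cfg: CutPointConfig,
) -> np.ndarray:
    """Assign each epoch one label in {TST, SB, LPA, MVPA, NONWEAR}.

    Non-wear dominates; wear epochs scored asleep are TST; remaining waking
    wear epochs are classified by VM3 cut-points with the boundary
    convention vm3 <= sb_upper -> SB, vm3 <= lpa_upper -> LPA, else MVPA.
    """
    x = np.asarray(vm3, dtype=float)
    wear = np.asarray(wear, dtype=bool)
    sleep = np.asarray(sleep, dtype=bool)
    labels = np.empty(x.size, dtype=object)
    labels[:] = "MVPA"
    labels[x <= cfg.lpa_upper] = "LPA"
    labels[x <= cfg.sb_upper] = "SB"
    labels[sleep] = "TST"
    labels[~wear] = "NONWEAR"
    return labels


def summarize_day(
    labels: np.ndarray,
    epoch_length_s: int,
    participant_id: str,
    day: date,
) -> DailySummary:
    """Aggregate one calendar day of epoch labels into behaviour minutes.

    Waking wear time is SB + LPA + MVPA; sleep minutes do not count toward
    the validity rule (a day is valid iff waking wear >= 10 h).
    """
    labels = np.asarray(labels)
    mins = epoch_length_s / 60.0
    totals = {lab: float((labels == lab).sum()) * mins for lab in LABELS}
    waking = totals["SB"] + totals["LPA"] + totals["MVPA"]
    return DailySummary(
        participant_id=participant_id,
        date=day,
        tst_min=totals["TST"],
        sb_min=totals["SB"],
        lpa_min=totals["LPA"],
        mvpa_min=totals["MVPA"],
        waking_wear_min=waking,
        is_valid=waking >= MIN_WAKING_WEAR_MIN,
    )


def participant_composition(
    days: list[DailySummary],
    min_valid_days: int = MIN_VALID_DAYS,
) -> np.ndarray | None:
    """Average valid days into one 4-part composition, or exclude.

    Returns the arithmetic mean of (tst, sb, lpa, mvpa) minutes across
    valid days closed to 1440 min, or None if the participant has fewer
    than ``min_valid_days`` valid days (the study inclusion rule).
    """
    valid = [d for d in days if d.is_valid]
    if len(valid) < min_valid_days:
        return None
    means = np.mean([d.minutes() for d in valid], axis=0)
    if np.all(means == 0):
        raise CompositionError(
            f"degenerate participant {valid[0].participant_id}: all behaviour means zero"
        )
    return closure(means)


def process_participant(
    epochs: pd.DataFrame,
    cfg: CutPointConfig,
    *,
    window_min: float = 90.0,
    spike_tolerance_min: float = 2.0,
    sleep_weights=(0.04, 0.04, 0.2, 1.0, 0.2, 0.04, 0.04),
    sleep_threshold: float = 100.0,
) -> list[DailySummary]:
    """Run the full epoch pipeline for one participant.

    ``epochs`` must have columns timestamp (ISO-8601 or datetime) and vm3,
    contiguous at the epoch length.  Days are calendar-aligned (midnight to
    midnight); partial first/last days are dropped.
    """
    pid = str(epochs["participant_id"].iloc[0]) if "participant_id" in epochs else ""
    ts = pd.to_datetime(epochs["timestamp"])
    _check_contiguous(ts, cfg.epoch_length_s)
    vm3 = epochs["vm3"].to_numpy(dtype=float)
    if np.any(vm3 < 0):
        raise ValueError("vm3 counts must be non-negative")

    wear = ~detect_nonwear(
        vm3, cfg.epoch_length_s, window_min, spike_tolerance_min
    )
    sleep = score_sleep(vm3, np.asarray(sleep_weights), sleep_threshold)
    labels = classify_waking_epochs(vm3, wear, sleep, cfg)

    per_day = 86400 // cfg.epoch_length_s
    days: list[DailySummary] = []
    for day, idx in pd.Series(np.arange(len(ts)), index=ts.dt.date).groupby(level=0):
        if len(idx) != per_day:  # partial first/last day
            continue
        days.append(summarize_day(labels[idx.to_numpy()], cfg.epoch_length_s, pid, day))
    return days


def preprocess_cohort(
    epochs: pd.DataFrame,
    cfg: CutPointConfig,
    min_valid_days: int = MIN_VALID_DAYS,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Preprocess a multi-participant epoch table.

    Returns (daily_df, composition_df): per-day behaviour minutes with
    validity flags, and per-participant compositions (participants with
    fewer than ``min_valid_days`` valid days are excluded from the latter).
    """
    daily_rows, comp_rows = [], []
    for pid, grp in epochs.groupby("participant_id", sort=True):
        days = process_participant(grp.reset_index(drop=True), cfg, **kwargs)
        daily_rows.extend(vars(d) for d in days)
        comp = participant_composition(days, min_valid_days)
        if comp is not None:
            comp_rows.append(
                {"participant_id": str(pid), **dict(zip(("tst", "sb", "lpa", "mvpa"), comp))}
            )
    return pd.DataFrame(daily_rows), pd.DataFrame(comp_rows)
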
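"""Episode detection on hypnograms.

NREMS episodes are runs of N longer than 1 min (>= 16 ts), tolerating
interruptions of at most 4 ts at a time; long NREMS episodes last >= 3 min
(45 ts).  Long wake bouts are consolidated wake-dominated periods (defaults
are configuration, not fixed by the source protocol).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from somno.epoch_data import EpochSeries, _runs

#: Minimum NREMS episode span: strictly more than 1 min = 15 ts.
NREM_MIN_LEN = 16

#: Maximum single interruption inside an NREMS episode.
NREM_MAX_GAP = 4

#: Long NREMS episode: at least 3 min.
LONG_NREM_MIN_LEN = 45

#: Epochs per 24-h day.
DAY_TS = 21_600


@dataclass(frozen=True, order=True)
class Episode:
    """Half-open epoch interval ``[start, end)`` of one detected episode."""

    start: int
    end: int
    kind: str = "nrem_episode"
    phase: str = "L"

    @property
    def duration(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid episode interval [{self.start}, {self.end})")


def _merge_runs(
    runs: list[tuple[int, int]], max_gap: int
) -> list[tuple[int, int]]:
    """Merge consecutive [start, end) runs whenever the gap between them is <= max_gap."""
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def detect_nrem_episodes(
    series: EpochSeries,
    min_len: int = NREM_MIN_LEN,
    max_gap: int = NREM_MAX_GAP,
) -> list[Episode]:
    """Detect NREMS episodes.

    Maximal runs of N are merged across non-N gaps of at most ``max_gap`` ts
    (each gap individually), trimmed so both endpoints are N, and kept if the
    merged span is at least ``min_len`` ts.  Episode phase is the phase of
    the start epoch.
    """
    runs = _runs(series.state == "N")
    merged = _merge_runs(runs, max_gap)
    return [
        Episode(s, e, "nrem_episode", str(series.phase[s]))
        for s, e in merged
        if e - s >= min_len
    ]


def detect_long_nrem_episodes(
    series: EpochSeries,
    min_len: int = LONG_NREM_MIN_LEN,
    max_gap: int = NREM_MAX_GAP,
) -> list[Episode]:
    """NREMS episodes of at least 3 min (45 ts), re-tagged ``long_nrem_episode``."""
    return [
        Episode(ep.start, ep.end, "long_nrem_episode", ep.phase)
        for ep in detect_nrem_episodes(series, min_len=min_len, max_gap=max_gap)
    ]


def detect_long_wake_bouts(
    series: EpochSeries,
    min_len: int = 900,
    max_sleep_gap: int = 75,
    ba_as_wake: bool = True,
) -> list[Episode]:
    """Detect at most one consolidated long wake bout per 24-h day.

    Wake-like runs (W, and BA when ``ba_as_wake``) are merged across sleep
    gaps of at most ``max_sleep_gap`` ts; merged periods of at least
    ``min_len`` ts are candidates, and per 24-h day only the longest is
    returned.  Defaults (1 h minimum, 5 min sleep tolerance) are
    configuration, not protocol values.
    """
    wakelike = series.state == "W"
    if ba_as_wake:
        wakelike |= series.state == "BA"
    merged = _merge_runs(_runs(wakelike), max_sleep_gap)
    candidates = [(s, e) for s, e in merged if e - s >= min_len]
    best_per_day: dict[int, tuple[int, int]] = {}
    for s, e in candidates:
        day = s // DAY_TS
        if day not in best_per_day or e - s > best_per_day[day][1] - best_per_day[day][0]:
            best_per_day[day] = (s, e)
    return [
        Episode(s, e, "long_wake_bout", str(series.phase[s]))
        for s, e in sorted(best_per_day.values())
    ]


def episode_mean_swa(
    ep: Episode,
    series: EpochSeries,
    derivation: str,
    smoothed: np.ndarray | None = None,
) -> float:
    """Mean SWA over the usable (N-state, non-artifact) epochs of an episode.

    Uses ``smoothed`` values in place of the stored SWA when supplied.
    Returns NaN when the episode has no usable epoch.
    """
    if ep.end > series.n_ts:
        raise ValueError(f"episode [{ep.start}, {ep.end}) exceeds series length {series.n_ts}")
    values = smoothed if smoothed is not None else series.swa[derivation]
    sl = slice(ep.start, ep.end)
    usable = (series.state[sl] == "N") & ~series.artifact[sl]
    vals = np.asarray(values[sl])[usable]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def episodes_to_table(episodes: list[Episode]) -> str:
    """BED-like TSV dump: start_ts, end_ts, kind, phase."""
    lines = ["start_ts\tend_ts\tkind\tphase"]
    lines += [f"{ep.start}\t{ep.end}\t{ep.kind}\t{ep.phase}" for ep in episodes]
    return "\n".join(lines) + "\n"
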
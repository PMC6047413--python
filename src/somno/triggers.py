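"""Binary trigger functions that anticipate and outlast scored states.

A trigger interval extends each maximal run of the target state by
``advance`` epochs before its onset and ``prolong`` epochs after its offset;
overlapping extensions merge (union semantics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from somno.epoch_data import EpochSeries, _runs


@dataclass
class TriggerSeries:
    """REM trigger and wake trigger vectors with their offsets (in ts)."""

    remt: np.ndarray
    wt: np.ndarray
    t_a: int = 8
    t_p: int = 6
    t_aw: int = 8
    t_pw: int = 4

    @property
    def n_ts(self) -> int:
        return int(self.remt.shape[0])


def build_trigger(
    series: EpochSeries,
    target_state: str,
    advance: int,
    prolong: int,
    extra_states: tuple[str, ...] = (),
) -> np.ndarray:
    """Binary vector: union of [max(0, a-advance), min(n, b+prolong)) over target runs.

    Every maximal run of ``target_state`` (or of the union with
    ``extra_states``) generates a trigger interval regardless of length.
    """
    if advance < 0 or prolong < 0:
        raise ValueError("advance and prolong must be >= 0")
    mask = series.state == target_state
    for st in extra_states:
        mask |= series.state == st
    n = series.n_ts
    out = np.zeros(n, dtype=np.uint8)
    for a, b in _runs(mask):
        out[max(0, a - advance) : min(n, b + prolong)] = 1
    return out


def build_triggers(
    series: EpochSeries,
    t_a: int = 8,
    t_p: int = 6,
    t_aw: int = 8,
    t_pw: int = 4,
    ba_as_wake: bool = False,
) -> TriggerSeries:
    """REMT from R runs and WT from W runs (optionally including BA) with the given offsets."""
    remt = build_trigger(series, "R", t_a, t_p)
    wt = build_trigger(series, "W", t_aw, t_pw, extra_states=("BA",) if ba_as_wake else ())
    return TriggerSeries(remt=remt, wt=wt, t_a=t_a, t_p=t_p, t_aw=t_aw, t_pw=t_pw)
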
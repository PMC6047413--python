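"""Light/dark-balanced squared-error objective and error diagnostics.

For each NREMS episode i, d(i) = m_empirical(i) - m_simulation(i), both means
taken over the same usable (N, non-artifact) epochs.  The objective is
Err = (M_light + M_dark) / 2 with M_phase the mean of d(i)^2 over that
phase's episodes.  Window diagnostics use the opposite sign convention
(simulation - empirical: positive = model overestimates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from somno.epoch_data import EpochSeries
from somno.episodes import Episode
from somno.model import SimulationResult

log = logging.getLogger(__name__)

#: Default moving-median smoothing window (ts) applied to empirical SWA.
SMOOTH_WINDOW = 35

#: Default post-wake evaluation window: 40 min in 10-min bins.
POST_WAKE_WINDOW = 600
POST_WAKE_BIN = 150


def smooth_moving_median(
    series: np.ndarray,
    window: int = SMOOTH_WINDOW,
    artifact: np.ndarray | None = None,
) -> np.ndarray:
    """Centred moving-median filter with truncated windows at the edges.

    The window around index i is ``[max(0, i-h), min(n, i+h+1))`` with
    ``h = window // 2``.  Artifact epochs are excluded from every window's
    median and their own output is NaN.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    h = window // 2
    out = np.empty(n)
    if artifact is None or not np.any(artifact):
        if n >= window:
            from numpy.lib.stride_tricks import sliding_window_view

            out[h : n - h] = np.median(sliding_window_view(x, window), axis=1)
            edge = range(h)
        else:
            edge = range(n)
        for i in edge:
            out[i] = np.median(x[max(0, i - h) : i + h + 1])
        for i in range(max(n - h, h), n):
            out[i] = np.median(x[max(0, i - h) : min(n, i + h + 1)])
        return out
    art = np.asarray(artifact, dtype=bool)
    for i in range(n):
        if art[i]:
            out[i] = np.nan
            continue
        lo, hi = max(0, i - h), min(n, i + h + 1)
        vals = x[lo:hi][~art[lo:hi]]
        out[i] = np.median(vals) if vals.size else np.nan
    return out


@dataclass
class ObjectiveReport:
    """Per-episode deviations and the light/dark-balanced squared error."""

    d: np.ndarray
    phases: np.ndarray
    M_light: float
    M_dark: float
    Err: float
    n_light: int = 0
    n_dark: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "M_light": self.M_light,
            "M_dark": self.M_dark,
            "Err": self.Err,
            "n_light": self.n_light,
            "n_dark": self.n_dark,
            "d": self.d.tolist(),
            "phases": self.phases.tolist(),
            "warnings": list(self.warnings),
        }


def episode_deviations(
    episodes: list[Episode],
    emp: EpochSeries,
    sim: SimulationResult,
    derivation: str,
    smoothed: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """d(i) = m_empirical(i) - m_simulation(i) per episode, with episode phases.

    Both means run over the identical usable epoch set (N-state,
    non-artifact, finite empirical value); episodes with no usable epoch are
    skipped.
    """
    emp_vals = smoothed if smoothed is not None else emp.swa[derivation]
    devs: list[float] = []
    phases: list[str] = []
    for ep in episodes:
        sl = slice(ep.start, ep.end)
        usable = (emp.state[sl] == "N") & ~emp.artifact[sl]
        e = np.asarray(emp_vals[sl])[usable]
        s = sim.swa_sim[sl][usable]
        keep = np.isfinite(e)
        if not keep.any():
            continue
        devs.append(float(e[keep].mean() - s[keep].mean()))
        phases.append(ep.phase)
    return np.asarray(devs, dtype=float), np.asarray(phases, dtype="<U1")


def squared_error(devs: np.ndarray, phases: np.ndarray) -> ObjectiveReport:
    """Err = (M_light + M_dark)/2; falls back to the populated phase when one is empty."""
    devs = np.asarray(devs, dtype=float)
    phases = np.asarray(phases, dtype="<U1")
    light = devs[phases == "L"]
    dark = devs[phases == "D"]
    warnings: list[str] = []
    m_light = float(np.mean(light**2)) if light.size else float("nan")
    m_dark = float(np.mean(dark**2)) if dark.size else float("nan")
    if light.size and dark.size:
        err = 0.5 * (m_light + m_dark)
    elif light.size:
        err = m_light
        warnings.append("no dark-phase episodes; Err falls back to M_light")
    elif dark.size:
        err = m_dark
        warnings.append("no light-phase episodes; Err falls back to M_dark")
    else:
        raise ValueError("no episodes in either phase")
    for w in warnings:
        log.warning(w)
    return ObjectiveReport(
        d=devs, phases=phases, M_light=m_light, M_dark=m_dark, Err=err,
        n_light=int(light.size), n_dark=int(dark.size), warnings=warnings,
    )


def objective_from_simulation(
    episodes: list[Episode],
    emp: EpochSeries,
    sim: SimulationResult,
    derivation: str,
    smoothed: np.ndarray | None = None,
) -> ObjectiveReport:
    """Convenience composition of episode_deviations and squared_error."""
    devs, phases = episode_deviations(episodes, emp, sim, derivation, smoothed)
    return squared_error(devs, phases)


def window_errors(
    emp: EpochSeries,
    sim: SimulationResult,
    derivation: str,
    window: tuple[int, int],
    bin_ts: int = POST_WAKE_BIN,
    smoothed: np.ndarray | None = None,
) -> dict:
    """Signed and absolute per-epoch errors over a ts window, binned.

    Signed error is mean(sim - emp): positive means the model overestimates.
    Only N-state non-artifact epochs contribute; an empty bin yields NaN.
    """
    a, b = window
    a = max(0, a)
    b = min(emp.n_ts, b)
    emp_vals = smoothed if smoothed is not None else emp.swa[derivation]
    edges = list(range(a, b, bin_ts)) + [b]
    signed, absolute, counts, starts = [], [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sl = slice(lo, hi)
        usable = (emp.state[sl] == "N") & ~emp.artifact[sl]
        e = np.asarray(emp_vals[sl])[usable]
        s = sim.swa_sim[sl][usable]
        keep = np.isfinite(e)
        diff = s[keep] - e[keep]
        starts.append(lo)
        counts.append(int(diff.size))
        if diff.size:
            signed.append(float(diff.mean()))
            absolute.append(float(np.abs(diff).mean()))
        else:
            signed.append(float("nan"))
            absolute.append(float("nan"))
    return {
        "bin_start_ts": starts,
        "bin_ts": bin_ts,
        "signed_error": signed,
        "absolute_error": absolute,
        "n_epochs": counts,
    }
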
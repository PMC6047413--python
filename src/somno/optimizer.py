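"""Two-stage multi-start estimation of (gc, rs, S_U).

Stage 1 runs nine simplex (Nelder-Mead) searches from a 3x3 grid of
(gc, rs) starting values with a fixed S_U start; the winner seeds a second
nine-start grid offset by +/-0.0002 (gc) and +/-0.00002 (rs).  Every search
re-runs the full forward simulation at each objective evaluation.  S_U is
free in every search; only its starting value is pinned.

Starting grids (per derivation):

* frontal:   gc0 in {0.0005, 0.0010, 0.0020}, rs0 in {0.0001, 0.0002, 0.0004}, S_U0 = 400
* occipital: gc0 in {0.0002, 0.0004, 0.0008}, rs0 in {0.0001, 0.0002, 0.0004}, S_U0 = 450
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize

from somno.epoch_data import EpochSeries, normalize_swa
from somno.episodes import Episode, detect_nrem_episodes
from somno.model import ModelParams, SimulationError, simulate
from somno.objective import SMOOTH_WINDOW, squared_error
from somno.triggers import TriggerSeries, build_triggers

log = logging.getLogger(__name__)

DAY_TS = 21_600

STAGE1_GRIDS = {
    "frontal": {"gc": (0.0005, 0.0010, 0.0020), "rs": (0.0001, 0.0002, 0.0004), "S_U": 400.0},
    "occipital": {"gc": (0.0002, 0.0004, 0.0008), "rs": (0.0001, 0.0002, 0.0004), "S_U": 450.0},
}

STAGE2_GC_OFFSET = 0.0002
STAGE2_RS_OFFSET = 0.00002

#: Floor applied to stage-2 starting values that would otherwise be <= 0.
PARAM_FLOOR = 1e-6

#: Simplex settings emulating classic fminsearch defaults.
SIMPLEX_XTOL = 1e-4
SIMPLEX_FTOL = 1e-4
SIMPLEX_MAXITER = 600  # 200 * n free parameters


def stage1_grid(derivation: str) -> list[tuple[float, float, float]]:
    """The nine (gc0, rs0, S_U0) stage-1 starting points for a derivation."""
    g = STAGE1_GRIDS[derivation]
    return [(gc, rs, g["S_U"]) for gc, rs in itertools.product(g["gc"], g["rs"])]


def stage2_grid(winner: tuple[float, float, float]) -> list[tuple[float, float, float]]:
    """Nine stage-2 starts offset around the stage-1 winner (S_U start reused)."""
    g, r, su = winner
    gcs = [max(PARAM_FLOOR, g + k * STAGE2_GC_OFFSET) for k in (-1, 0, 1)]
    rss = [max(PARAM_FLOOR, r + k * STAGE2_RS_OFFSET) for k in (-1, 0, 1)]
    return [(gc, rs, su) for gc, rs in itertools.product(gcs, rss)]


def initial_conditions(series: EpochSeries, derivation: str) -> tuple[float, float]:
    """(S_0, SWA_0) from the data.

    S_0 is the mean SWA over the first NREMS episode of at least 45 ts
    (3 min); SWA_0 is the SWA of the first non-artifact epoch.
    """
    episodes = detect_nrem_episodes(series)
    first_long = next((ep for ep in episodes if ep.duration >= 45), None)
    if first_long is None:
        raise ValueError("no NREMS episode of >= 45 ts found for S_0")
    sl = slice(first_long.start, first_long.end)
    usable = (series.state[sl] == "N") & ~series.artifact[sl]
    vals = series.swa[derivation][sl][usable]
    if vals.size == 0:
        raise ValueError("first long NREMS episode has no usable epoch")
    s0 = float(vals.mean())
    ok = np.flatnonzero(~series.artifact)
    if ok.size == 0:
        raise ValueError("all epochs artifactual; cannot set SWA_0")
    swa0 = float(series.swa[derivation][ok[0]])
    return s0, swa0


@njit(cache=True)
def _smooth_segment_means(flat, offsets, counts, window):
    """Mean of the truncated-window moving median per segment of ``flat``.

    Segments are ``flat[offsets[j] : offsets[j] + counts[j]]`` — the usable
    epochs of one NREMS episode each.  The window around position i is
    [max(0, i-h), min(c, i+h+1)) with h = window // 2, matching the edge
    behaviour of the full moving-median filter.
    """
    h = window // 2
    m = offsets.shape[0]
    out = np.empty(m)
    buf = np.empty(window)
    for j in range(m):
        o = offsets[j]
        c = counts[j]
        acc = 0.0
        for i in range(c):
            lo = i - h if i - h > 0 else 0
            hi = i + h + 1 if i + h + 1 < c else c
            k = hi - lo
            for q in range(k):
                buf[q] = flat[o + lo + q]
            for a in range(1, k):  # insertion sort: windows are tiny
                key = buf[a]
                b = a - 1
                while b >= 0 and buf[b] > key:
                    buf[b + 1] = buf[b]
                    b -= 1
                buf[b + 1] = key
            if k % 2 == 1:
                acc += buf[k // 2]
            else:
                acc += 0.5 * (buf[k // 2 - 1] + buf[k // 2])
        out[j] = acc / c
    return out


@dataclass
class FitData:
    """Precomputed inputs of one fit: series, episodes, triggers and cached indices.

    The objective compares per-episode means of the moving-median-smoothed
    SWA time course, computed identically for the empirical and the
    simulated series (symmetric estimands), over the same usable epochs.
    """

    series: EpochSeries
    derivation: str
    episodes: list[Episode]
    triggers: TriggerSeries
    fixed: ModelParams
    smooth_window: int = 35
    # flattened usable-epoch indices per episode for fast simulated means
    _flat_idx: np.ndarray = field(repr=False, default=None)
    _offsets: np.ndarray = field(repr=False, default=None)
    _counts: np.ndarray = field(repr=False, default=None)
    _emp_means: np.ndarray = field(repr=False, default=None)
    _phases: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self._flat_idx is None:
            self._build_cache()

    def _build_cache(self) -> None:
        raw = self.series.swa[self.derivation]
        flat, offsets, counts, phases = [], [], [], []
        pos = 0
        usable_all = (self.series.state == "N") & ~self.series.artifact & np.isfinite(raw)
        for ep in self.episodes:
            idx = np.flatnonzero(usable_all[ep.start : ep.end]) + ep.start
            if idx.size == 0:
                continue
            flat.append(idx)
            offsets.append(pos)
            counts.append(idx.size)
            pos += idx.size
            phases.append(ep.phase)
        if not flat:
            raise ValueError("no usable NREMS episodes for fitting")
        self._flat_idx = np.concatenate(flat)
        self._offsets = np.asarray(offsets, dtype=np.int64)
        self._counts = np.asarray(counts, dtype=np.int64)
        self._phases = np.asarray(phases, dtype="<U1")
        self._emp_means = _smooth_segment_means(
            raw[self._flat_idx], self._offsets, self._counts, self.smooth_window
        )

    def episode_sim_means(self, swa_sim: np.ndarray) -> np.ndarray:
        """Per-episode smoothed means of a simulated SWA trace."""
        return _smooth_segment_means(
            swa_sim[self._flat_idx], self._offsets, self._counts, self.smooth_window
        )

    @property
    def emp_means(self) -> np.ndarray:
        return self._emp_means

    @property
    def phases(self) -> np.ndarray:
        return self._phases

    def objective(self, gc: float, rs: float, s_u: float) -> float:
        """Err at candidate (gc, rs, S_U); +inf on invalid params or solver failure."""
        if gc <= 0 or rs <= 0 or s_u <= max(self.fixed.SWA_L, 0):
            return float("inf")
        # S_0 comes from the data; cap it at the candidate S_U so the
        # candidate stays inside the admissible parameter region.
        p = self.fixed.replace(gc=gc, rs=rs, S_U=s_u, S_0=min(self.fixed.S_0, s_u))
        try:
            p.validate()
            sim = simulate(self.series.n_ts, self.triggers, p)
        except (ValueError, SimulationError):
            return float("inf")
        devs = self._emp_means - self.episode_sim_means(sim.swa_sim)
        return squared_error(devs, self._phases).Err


@dataclass
class StartResult:
    start: tuple[float, float, float]
    params: tuple[float, float, float]
    err: float
    nfev: int
    nit: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "start": list(self.start),
            "params": list(self.params),
            "err": self.err,
            "nfev": self.nfev,
            "nit": self.nit,
            "converged": self.converged,
        }


@dataclass
class FitResult:
    """Outcome of the two-stage fit for one derivation."""

    gc: float
    rs: float
    S_U: float
    err: float
    stage1: list[StartResult]
    stage2: list[StartResult]
    spread: float
    derivation: str
    S_0: float = float("nan")
    SWA_0: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "derivation": self.derivation,
            "gc": self.gc,
            "rs": self.rs,
            "S_U": self.S_U,
            "err": self.err,
            "spread": self.spread,
            "S_0": self.S_0,
            "SWA_0": self.SWA_0,
            "stage1": [r.to_dict() for r in self.stage1],
            "stage2": [r.to_dict() for r in self.stage2],
        }


def _minimize_one(fit_data: FitData, start: tuple[float, float, float]) -> StartResult:
    """One Nelder-Mead search from ``start``, in start-normalised coordinates."""
    x0 = np.asarray(start, dtype=float)

    def f(z: np.ndarray) -> float:
        gc, rs, s_u = z * x0
        return fit_data.objective(gc, rs, s_u)

    f0 = f(np.ones(3))
    fatol = max(1e-12, SIMPLEX_FTOL * (f0 if np.isfinite(f0) else 1.0))
    res = minimize(
        f,
        np.ones(3),
        method="Nelder-Mead",
        options={
            "xatol": SIMPLEX_XTOL,
            "fatol": fatol,
            "maxiter": SIMPLEX_MAXITER,
            "maxfev": 2 * SIMPLEX_MAXITER,
            "adaptive": False,
        },
    )
    params = tuple(float(v) for v in res.x * x0)
    return StartResult(
        start=tuple(float(v) for v in start),
        params=params,
        err=float(res.fun),
        nfev=int(res.nfev),
        nit=int(res.nit),
        converged=bool(res.success),
    )


def run_stage(
    starts: list[tuple[float, float, float]],
    fit_data: FitData,
) -> list[StartResult]:
    """Run one simplex search per starting point; failures score +inf and are kept."""
    results = []
    for st in starts:
        r = _minimize_one(fit_data, st)
        log.debug("start %s -> %s err=%.6g nfev=%d", st, r.params, r.err, r.nfev)
        results.append(r)
    return results


def two_stage_fit(fit_data: FitData, derivation: str | None = None) -> FitResult:
    """Full two-stage multi-start fit; ties broken by lowest start index."""
    deriv = derivation or fit_data.derivation
    stage1 = run_stage(stage1_grid(deriv), fit_data)
    errs1 = [r.err for r in stage1]
    winner = stage1[int(np.argmin(errs1))]
    stage2 = run_stage(stage2_grid(winner.params), fit_data)
    errs2 = np.asarray([r.err for r in stage2])
    best = stage2[int(np.argmin(errs2))]
    finite = errs2[np.isfinite(errs2)]
    if finite.size and finite.min() > 0:
        spread = float((finite.max() - finite.min()) / finite.min())
    else:
        spread = float("nan")
    gc, rs, s_u = best.params
    return FitResult(
        gc=gc, rs=rs, S_U=s_u, err=best.err,
        stage1=stage1, stage2=stage2, spread=spread, derivation=deriv,
        S_0=fit_data.fixed.S_0, SWA_0=fit_data.fixed.SWA_0,
    )


def prepare_fit_window(
    series: EpochSeries,
    protocol: str,
    exchange_ts: int | None = None,
) -> EpochSeries:
    """Extract (and for EW, duplicate) the optimisation window.

    * RW: the first 48 h.
    * CW: the 48 h of baseline ending at ``exchange_ts`` (default: 48 h mark).
    * EW: the first 24 h concatenated with itself (states, artifacts, phases
      and SWA all duplicated) to give a 48-h fit window.
    """
    protocol = protocol.upper()
    if protocol == "RW":
        if series.n_ts < 2 * DAY_TS:
            raise ValueError("RW protocol requires >= 48 h of data")
        return series.slice(0, 2 * DAY_TS)
    if protocol == "CW":
        end = exchange_ts if exchange_ts is not None else 2 * DAY_TS
        if end < 2 * DAY_TS or end > series.n_ts:
            raise ValueError("CW protocol requires >= 48 h of baseline before the exchange")
        return series.slice(end - 2 * DAY_TS, end)
    if protocol == "EW":
        if series.n_ts < DAY_TS:
            raise ValueError("EW protocol requires >= 24 h of baseline")
        day = series.slice(0, DAY_TS)
        return EpochSeries(
            state=np.concatenate([day.state, day.state]),
            artifact=np.concatenate([day.artifact, day.artifact]),
            phase=np.concatenate([day.phase, day.phase]),
            swa={d: np.concatenate([v, v]) for d, v in day.swa.items()},
        )
    raise ValueError(f"unknown protocol {protocol!r}")


def prepare_fit_data(
    series: EpochSeries,
    derivation: str,
    protocol: str = "RW",
    fixed: ModelParams | None = None,
    exchange_ts: int | None = None,
    smooth_window: int | None = None,
    ba_as_wake: bool = False,
    already_normalized: bool = False,
) -> FitData:
    """Build a :class:`FitData`: window, normalisation, smoothing, episodes, triggers, S_0/SWA_0."""
    window = prepare_fit_window(series, protocol, exchange_ts=exchange_ts)
    if not already_normalized:
        window = normalize_swa(window)
    fixed = fixed or ModelParams()
    w = smooth_window if smooth_window is not None else SMOOTH_WINDOW
    episodes = detect_nrem_episodes(window)
    s0, swa0 = initial_conditions(window, derivation)
    swa0 = max(swa0, fixed.SWA_L)  # SWA below the lower asymptote cannot be a model state
    fixed = fixed.replace(S_0=min(s0, fixed.S_U), SWA_0=swa0)
    triggers = build_triggers(
        window, t_a=fixed.t_a, t_p=fixed.t_p, t_aw=fixed.t_aw, t_pw=fixed.t_pw,
        ba_as_wake=ba_as_wake,
    )
    return FitData(
        series=window, derivation=derivation, episodes=episodes,
        triggers=triggers, fixed=fixed, smooth_window=w,
    )
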
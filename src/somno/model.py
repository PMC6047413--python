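"""Coupled SWA / Process-S dynamics at 4-s epoch resolution.

State variables (both in % of the baseline NREMS SWA mean):

* ``SWA`` follows a logistic build-up gated off by the wake and REM triggers,
  plus two exponential fall terms towards the lower asymptote ``SWA_L`` that
  are active while the corresponding trigger is on::

      dSWA/dt = rc * SWA * (S/S_U) * (1 - SWA/S) * (1 - WT) * (1 - REMT)
                - fc_R * (SWA - SWA_L) * REMT
                - fc_W * (SWA - SWA_L) * WT

* ``S`` (homeostatic sleep pressure) declines in proportion to SWA and rises
  towards its upper asymptote ``S_U``::

      dS/dt = -gc * SWA + (S_U - S) * rs

Time unit is ts (= 4 s) throughout; triggers are piecewise-constant within
each ts.  The default integrator is a fixed-substep RK4 (0.1 ts substeps,
well inside the stability region for the stiff fall terms at fc ~ 0.2/ts);
an adaptive stiff-capable integrator restarted at every trigger change is
available for cross-checks.  Per-ts output is the time-average of the
continuous solution over that epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from somno.epoch_data import EpochSeries
from somno.triggers import TriggerSeries


class SimulationError(RuntimeError):
    """Non-finite or invalid state encountered during integration."""

    def __init__(self, message: str, ts_index: int | None = None):
        super().__init__(message)
        self.ts_index = ts_index


@dataclass
class ModelParams:
    """All model constants; rates in ts^-1, offsets in ts, levels in % of baseline NREMS SWA."""

    rc: float = 0.5          # SWA rise constant
    fc_R: float = 0.2        # fall constant under REM trigger (0.1 / 0.2 / 0.3)
    fc_W: float = 0.2        # fall constant under wake trigger
    SWA_L: float = 20.0      # lower asymptote of SWA
    t_a: int = 8             # REMT advance
    t_p: int = 6             # REMT prolongation
    t_aw: int = 8            # WT advance
    t_pw: int = 4            # WT prolongation
    gc: float = 0.0010       # gain constant of S (fitted)
    rs: float = 0.0002       # rise rate of S (fitted)
    S_U: float = 400.0       # upper asymptote of S (fitted)
    S_0: float = 300.0       # initial S
    SWA_0: float = 150.0     # initial SWA

    def validate(self) -> None:
        for name in ("rc", "fc_R", "fc_W", "gc", "rs"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")
        for name in ("t_a", "t_p", "t_aw", "t_pw"):
            if getattr(self, name) < 0:
                raise ValueError(f"offset {name} must be >= 0")
        if not self.SWA_L < self.S_U:
            raise ValueError("require SWA_L < S_U")
        if self.SWA_0 < self.SWA_L:
            raise ValueError("require SWA_0 >= SWA_L")
        if not (self.SWA_L < self.S_0 <= self.S_U):
            raise ValueError("require S_0 in (SWA_L, S_U]")

    def replace(self, **kwargs) -> "ModelParams":
        d = asdict(self)
        d.update(kwargs)
        return ModelParams(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: d[k] for k in asdict(cls()) if k in d})


@dataclass
class SimulationResult:
    """Per-ts epoch-averaged SWA(t) and S(t) plus solver diagnostics."""

    swa_sim: np.ndarray
    s_sim: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_ts(self) -> int:
        return int(self.swa_sim.shape[0])

    def to_table(self) -> str:
        lines = ["epoch_index\tswa_sim\ts_sim"]
        lines += [
            f"{t}\t{self.swa_sim[t]:.6f}\t{self.s_sim[t]:.6f}" for t in range(self.n_ts)
        ]
        return "\n".join(lines) + "\n"


def rhs(swa: float, s: float, wt: float, remt: float, p: ModelParams) -> tuple[float, float]:
    """Instantaneous derivatives (dSWA/dt, dS/dt) in % per ts."""
    if s <= 0:
        raise ValueError("Process S must be positive (division by S)")
    build = p.rc * swa * (s / p.S_U) * (1.0 - swa / s) * (1.0 - wt) * (1.0 - remt)
    fall = p.fc_R * (swa - p.SWA_L) * remt + p.fc_W * (swa - p.SWA_L) * wt
    dswa = build - fall
    ds = -p.gc * swa + (p.S_U - s) * p.rs
    return dswa, ds


@njit(cache=True, fastmath=True)
def _rk4_kernel(wt, remt, n_sub, rc, fc_r, fc_w, swa_l, gc, rs, s_u, swa0, s0):
    """Fixed-substep RK4 over all epochs; returns epoch-averaged SWA, S and failure index."""
    n = wt.shape[0]
    swa_out = np.empty(n)
    s_out = np.empty(n)
    swa = swa0
    s = s0
    h = 1.0 / n_sub
    for t in range(n):
        w = 1.0 - float(wt[t])
        r = 1.0 - float(remt[t])
        gate = w * r
        f_r = fc_r * float(remt[t])
        f_w = fc_w * float(wt[t])
        acc_swa = 0.0
        acc_s = 0.0
        for _ in range(n_sub):
            acc_swa += 0.5 * swa
            acc_s += 0.5 * s
            # k1
            k1a = rc * swa * (s / s_u) * (1.0 - swa / s) * gate - (f_r + f_w) * (swa - swa_l)
            k1b = -gc * swa + (s_u - s) * rs
            ya = swa + 0.5 * h * k1a
            yb = s + 0.5 * h * k1b
            # k2
            k2a = rc * ya * (yb / s_u) * (1.0 - ya / yb) * gate - (f_r + f_w) * (ya - swa_l)
            k2b = -gc * ya + (s_u - yb) * rs
            ya = swa + 0.5 * h * k2a
            yb = s + 0.5 * h * k2b
            # k3
            k3a = rc * ya * (yb / s_u) * (1.0 - ya / yb) * gate - (f_r + f_w) * (ya - swa_l)
            k3b = -gc * ya + (s_u - yb) * rs
            ya = swa + h * k3a
            yb = s + h * k3b
            # k4
            k4a = rc * ya * (yb / s_u) * (1.0 - ya / yb) * gate - (f_r + f_w) * (ya - swa_l)
            k4b = -gc * ya + (s_u - yb) * rs
            swa = swa + (h / 6.0) * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
            s = s + (h / 6.0) * (k1b + 2.0 * k2b + 2.0 * k3b + k4b)
            # divergence guard written as plain comparisons (robust under fastmath)
            if not (s > 1e-12 and s < 1e12 and swa > -1e12 and swa < 1e12):
                return swa_out, s_out, t
            acc_swa += 0.5 * swa
            acc_s += 0.5 * s
        swa_out[t] = acc_swa / n_sub
        s_out[t] = acc_s / n_sub
    return swa_out, s_out, -1


def _simulate_adaptive(wt, remt, p: ModelParams, points_per_ts: int = 8):
    """Segment-wise adaptive integration (LSODA), restarted at trigger changes.

    Slower cross-check path for the RK4 kernel; epoch averages are trapezoid
    means of the dense solution at ``points_per_ts`` points per ts.
    """
    from scipy.integrate import solve_ivp

    n = wt.shape[0]
    swa_out = np.empty(n)
    s_out = np.empty(n)
    y = np.array([p.SWA_0, p.S_0], dtype=float)
    change = np.flatnonzero(np.diff(wt.astype(np.int8)) | np.diff(remt.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [n]))
    nfev = 0
    for a, b in zip(bounds[:-1], bounds[1:]):
        w, r = float(wt[a]), float(remt[a])

        def f(_t, yy, w=w, r=r):
            swa, s = yy
            build = p.rc * swa * (s / p.S_U) * (1.0 - swa / s) * (1.0 - w) * (1.0 - r)
            fall = p.fc_R * (swa - p.SWA_L) * r + p.fc_W * (swa - p.SWA_L) * w
            return [build - fall, -p.gc * swa + (p.S_U - s) * p.rs]

        sol = solve_ivp(
            f, (a, b), y, method="LSODA", max_step=1.0, dense_output=True,
            rtol=1e-8, atol=1e-10,
        )
        if not sol.success:
            raise SimulationError(f"adaptive solver failed in segment [{a}, {b})", ts_index=int(a))
        nfev += sol.nfev
        for t in range(a, b):
            grid = np.linspace(t, t + 1, points_per_ts + 1)
            vals = sol.sol(grid)
            swa_out[t] = np.trapezoid(vals[0], grid)
            s_out[t] = np.trapezoid(vals[1], grid)
        y = sol.y[:, -1]
    if not np.all(np.isfinite(swa_out)):
        bad = int(np.flatnonzero(~np.isfinite(swa_out))[0])
        raise SimulationError("non-finite state during integration", ts_index=bad)
    return swa_out, s_out, {"solver": "adaptive-lsoda", "nfev": nfev, "segments": len(bounds) - 1}


def simulate(
    series: EpochSeries | int,
    trig: TriggerSeries,
    p: ModelParams,
    solver: str = "rk4",
    substeps: int = 10,
) -> SimulationResult:
    """Integrate the model over the recording driven by the trigger series.

    Parameters
    ----------
    series
        The epoch series (only its length is used) or the epoch count itself.
    trig
        Trigger vectors, piecewise-constant per ts.
    solver
        ``"rk4"`` (fixed substeps, default 0.1 ts) or ``"adaptive"``
        (stiff-capable LSODA restarted at trigger changes).
    substeps
        Substeps per ts for the RK4 path (must give step <= 0.1 ts is not
        required, but >= 8 dense points per ts are used for averaging).
    """
    n = series if isinstance(series, int) else series.n_ts
    if trig.n_ts != n:
        raise ValueError(f"trigger length {trig.n_ts} != series length {n}")
    p.validate()
    wt = np.ascontiguousarray(trig.wt, dtype=np.uint8)
    remt = np.ascontiguousarray(trig.remt, dtype=np.uint8)
    if solver == "rk4":
        if substeps < 8:
            raise ValueError("need >= 8 substeps per ts")
        swa, s, fail = _rk4_kernel(
            wt, remt, substeps, p.rc, p.fc_R, p.fc_W, p.SWA_L,
            p.gc, p.rs, p.S_U, p.SWA_0, p.S_0,
        )
        if fail >= 0:
            raise SimulationError(f"non-finite or non-positive state at ts {fail}", ts_index=int(fail))
        diag = {"solver": "rk4", "substeps": substeps, "steps": n * substeps}
    elif solver == "adaptive":
        swa, s, diag = _simulate_adaptive(wt, remt, p)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    return SimulationResult(swa_sim=swa, s_sim=s, diagnostics=diag)
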
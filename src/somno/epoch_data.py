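"""Epoch-resolution data model and I/O.

The canonical interchange format is a tab-separated table with one row per
4-s scoring epoch (1 ts): vigilance state, artifact flag, light/dark phase
and one SWA column per EEG derivation.  Raw per-epoch EEG blocks can be
reduced to band power spectra (Hann-tapered FFT, 0-20 Hz at 0.25 Hz) and to
slow-wave activity (0.5-4 Hz power).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Recognised vigilance-state codes: wake, NREM sleep, REM sleep, brief awakening.
STATES = ("W", "N", "R", "BA")

#: Light/dark phase codes.
PHASES = ("L", "D")

#: Scoring epoch length in seconds.
EPOCH_SECONDS = 4.0

#: Number of epochs in one 12-h light or dark phase.
PHASE_TS = 10_800

#: Maximum run length (ts) for a brief awakening.
BA_MAX_RUN = 5


class EpochTableError(ValueError):
    """Raised when an epoch table violates the format contract."""


def phase_from_index(n_ts: int) -> np.ndarray:
    """Light/dark labels for ``n_ts`` epochs of a recording starting at light onset.

    Phases alternate in 12-h (10,800 ts) blocks beginning with light (ZT0).
    """
    idx = np.arange(n_ts)
    return np.where((idx // PHASE_TS) % 2 == 0, "L", "D").astype("<U1")


@dataclass
class EpochSeries:
    """Aligned per-epoch vigilance states, artifact mask, phase labels and SWA.

    Parameters
    ----------
    state
        Array of state codes drawn from :data:`STATES`.
    artifact
        Boolean mask; artifactual epochs keep their state label but their SWA
        is excluded from every mean downstream.
    phase
        ``"L"``/``"D"`` per epoch.
    swa
        Mapping of derivation name to per-epoch SWA (raw power or % of the
        baseline NREMS mean).  May be empty for a bare hypnogram.
    """

    state: np.ndarray
    artifact: np.ndarray
    phase: np.ndarray
    swa: dict[str, np.ndarray] = field(default_factory=dict)
    epoch_duration: float = EPOCH_SECONDS

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype="<U2")
        self.artifact = np.asarray(self.artifact, dtype=bool)
        self.phase = np.asarray(self.phase, dtype="<U1")
        self.swa = {k: np.asarray(v, dtype=float) for k, v in self.swa.items()}

    @property
    def n_ts(self) -> int:
        return int(self.state.shape[0])

    @property
    def derivations(self) -> tuple[str, ...]:
        return tuple(self.swa)

    def copy(self) -> "EpochSeries":
        return EpochSeries(
            state=self.state.copy(),
            artifact=self.artifact.copy(),
            phase=self.phase.copy(),
            swa={k: v.copy() for k, v in self.swa.items()},
            epoch_duration=self.epoch_duration,
        )

    def slice(self, start: int, end: int) -> "EpochSeries":
        """Half-open epoch-index slice ``[start, end)``."""
        return EpochSeries(
            state=self.state[start:end].copy(),
            artifact=self.artifact[start:end].copy(),
            phase=self.phase[start:end].copy(),
            swa={k: v[start:end].copy() for k, v in self.swa.items()},
            epoch_duration=self.epoch_duration,
        )

    def validate(self, strict_phase: bool = False) -> None:
        """Check internal consistency; raise :class:`EpochTableError` on violation.

        With ``strict_phase`` the phase labels must follow the canonical
        12:12 light/dark grid anchored at light onset.
        """
        n = self.n_ts
        for name, arr in (("artifact", self.artifact), ("phase", self.phase)):
            if arr.shape[0] != n:
                raise EpochTableError(f"column '{name}' has length {arr.shape[0]}, expected {n}")
        for d, v in self.swa.items():
            if v.shape[0] != n:
                raise EpochTableError(f"SWA column '{d}' has length {v.shape[0]}, expected {n}")
        bad = ~np.isin(self.state, STATES)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise EpochTableError(f"unknown state code {self.state[row]!r} at row {row}")
        bad = ~np.isin(self.phase, PHASES)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise EpochTableError(f"unknown phase code {self.phase[row]!r} at row {row}")
        if strict_phase and not np.array_equal(self.phase, phase_from_index(n)):
            row = int(np.flatnonzero(self.phase != phase_from_index(n))[0])
            raise EpochTableError(f"phase label at row {row} off the 12:12 grid starting with light")
        # BA runs may not exceed 5 consecutive epochs
        for start, end in _runs(self.state == "BA"):
            if end - start > BA_MAX_RUN:
                raise EpochTableError(
                    f"brief-awakening run of {end - start} ts starting at row {start} exceeds {BA_MAX_RUN} ts"
                )
        for d, v in self.swa.items():
            usable = ~self.artifact
            vals = v[usable]
            if not np.all(np.isfinite(vals)):
                row = int(np.flatnonzero(usable)[np.flatnonzero(~np.isfinite(vals))[0]])
                raise EpochTableError(f"non-finite SWA in '{d}' at non-artifact row {row}")
            if np.any(vals < 0):
                row = int(np.flatnonzero(usable)[np.flatnonzero(vals < 0)[0]])
                raise EpochTableError(f"negative SWA in '{d}' at non-artifact row {row}")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) intervals of the maximal True runs of ``mask``."""
    if mask.size == 0:
        return []
    m = mask.astype(np.int8)
    diff = np.diff(np.concatenate(([0], m, [0])))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def load_epoch_table(path, sep: str = "\t", strict_phase: bool = False) -> EpochSeries:
    """Read an epoch TSV/CSV into a validated :class:`EpochSeries`.

    Required columns: ``epoch_index, state, artifact, phase`` plus one
    ``swa_<derivation>`` column per derivation.  ``epoch_index`` must be
    contiguous from 0.
    """
    df = pd.read_csv(path, sep=sep, dtype={"state": str, "phase": str},
                     float_precision="round_trip")
    required = ["epoch_index", "state", "artifact", "phase"]
    for col in required:
        if col not in df.columns:
            raise EpochTableError(f"missing required column '{col}'")
    idx = df["epoch_index"].to_numpy()
    expected = np.arange(len(df))
    if not np.array_equal(idx, expected):
        row = int(np.flatnonzero(idx != expected)[0])
        raise EpochTableError(f"epoch_index not contiguous from 0: row {row} has {idx[row]}")
    swa_cols = [c for c in df.columns if c.startswith("swa_")]
    series = EpochSeries(
        state=df["state"].to_numpy(),
        artifact=df["artifact"].to_numpy().astype(bool),
        phase=df["phase"].to_numpy(),
        swa={c[len("swa_"):]: df[c].to_numpy(dtype=float) for c in swa_cols},
    )
    series.validate(strict_phase=strict_phase)
    return series


def write_epoch_table(series: EpochSeries, path, sep: str = "\t") -> None:
    """Write the epoch table; ``load(write(x)) == x`` and the text round-trips."""
    cols: dict[str, Sequence] = {
        "epoch_index": np.arange(series.n_ts),
        "state": series.state,
        "artifact": series.artifact.astype(int),
        "phase": series.phase,
    }
    lines = [sep.join(list(cols) + [f"swa_{d}" for d in series.swa])]
    swa_arrays = list(series.swa.values())
    for t in range(series.n_ts):
        row = [str(t), series.state[t], str(int(series.artifact[t])), series.phase[t]]
        # str() of a float is its shortest round-trip representation
        row += [str(float(a[t])) for a in swa_arrays]
        lines.append(sep.join(row))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Spectral reduction of raw per-epoch EEG
# ---------------------------------------------------------------------------

#: Spectral bin width (Hz) and top frequency retained.
BIN_HZ = 0.25
TOP_HZ = 20.0
N_BINS = int(round(TOP_HZ / BIN_HZ)) + 1  # 81

#: Raw sampling assumptions: 4 s blocks at 256 Hz.
SAMPLE_RATE = 256
BLOCK_SAMPLES = 1024


@dataclass
class SpectrumTable:
    """Per-epoch power spectra on the fixed 0-20 Hz grid at 0.25 Hz.

    ``power[t, f]`` is one-sided periodogram power so that the sum over the
    *full* one-sided spectrum equals the windowed time-domain energy
    (Parseval); only bins up to 20 Hz are retained here.
    """

    power: np.ndarray
    bins: np.ndarray
    artifact: np.ndarray

    @property
    def n_epochs(self) -> int:
        return int(self.power.shape[0])


def spectral_bins() -> np.ndarray:
    """The fixed frequency grid {0, 0.25, ..., 20.0} (81 bins)."""
    return np.round(np.arange(N_BINS) * BIN_HZ, 10)


def epoch_band_power(raw_epochs: np.ndarray, window: str = "hann") -> SpectrumTable:
    """Hann-tapered FFT band power per 4-s epoch block.

    Parameters
    ----------
    raw_epochs
        Array of shape ``(n_epochs, 1024)``: 4 s of samples at 256 Hz per epoch.
    window
        Taper; only ``"hann"`` and ``"boxcar"`` are supported.

    Returns
    -------
    SpectrumTable
        81 bins per epoch (0-20 Hz); epochs containing NaN samples are
        flagged artifactual and their power set to NaN.

    Notes
    -----
    Power is normalised so that summing the full one-sided spectrum
    reproduces ``sum((w * x)**2)`` exactly (Parseval identity); the table
    keeps only the 0-20 Hz bins.
    """
    x = np.asarray(raw_epochs, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != BLOCK_SAMPLES:
        raise ValueError(
            f"epoch blocks must have {BLOCK_SAMPLES} samples (4 s at {SAMPLE_RATE} Hz), got {x.shape[1]}"
        )
    if window == "hann":
        w = np.hanning(BLOCK_SAMPLES)
    elif window == "boxcar":
        w = np.ones(BLOCK_SAMPLES)
    else:
        raise ValueError(f"unsupported window {window!r}")
    bad = ~np.all(np.isfinite(x), axis=1)
    xw = np.where(bad[:, None], 0.0, x) * w
    spec = np.fft.rfft(xw, axis=1)
    n = BLOCK_SAMPLES
    power = np.abs(spec) ** 2 / n
    power[:, 1:-1] *= 2.0  # fold negative frequencies; DC and Nyquist are unique
    power = power[:, :N_BINS].copy()
    power[bad] = np.nan
    return SpectrumTable(power=power, bins=spectral_bins(), artifact=bad)


def full_band_energy(raw_epochs: np.ndarray, window: str = "hann") -> np.ndarray:
    """Total one-sided spectral power per epoch over the full 0-128 Hz grid.

    Companion to :func:`epoch_band_power` for Parseval checks: equals the
    windowed time-domain energy of each block.
    """
    x = np.asarray(raw_epochs, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if window == "hann":
        w = np.hanning(BLOCK_SAMPLES)
    else:
        w = np.ones(BLOCK_SAMPLES)
    spec = np.fft.rfft(x * w, axis=1)
    power = np.abs(spec) ** 2 / BLOCK_SAMPLES
    power[:, 1:-1] *= 2.0
    return power.sum(axis=1)


def swa_from_spectra(spec: SpectrumTable, band: tuple[float, float] = (0.5, 4.0)) -> np.ndarray:
    """Per-epoch SWA: sum of spectral power over bins in ``band`` (inclusive)."""
    lo, hi = band
    bins = spec.bins
    on_grid = np.isclose(bins[:, None], [lo, hi], atol=1e-9).any(axis=0)
    if not on_grid.all():
        raise ValueError(f"band endpoints {band} must lie on the {BIN_HZ} Hz bin grid within 0-{TOP_HZ} Hz")
    sel = (bins >= lo - 1e-9) & (bins <= hi + 1e-9)
    return spec.power[:, sel].sum(axis=1)


def normalize_swa(
    series: EpochSeries,
    baseline_window: tuple[int, int] | None = None,
) -> EpochSeries:
    """Express SWA as % of the mean over non-artifact NREMS epochs in the baseline window.

    Per derivation, SWA is rescaled so that this baseline NREMS mean equals
    100 exactly.  Raises if a derivation has no usable baseline NREMS epoch.
    """
    if baseline_window is None:
        baseline_window = (0, series.n_ts)
    a, b = baseline_window
    out = series.copy()
    in_win = np.zeros(series.n_ts, dtype=bool)
    in_win[a:b] = True
    usable = in_win & (series.state == "N") & ~series.artifact
    if not usable.any():
        raise ValueError(f"no usable NREMS epoch in baseline window [{a}, {b})")
    for d, v in series.swa.items():
        mean = float(v[usable].mean())
        if mean <= 0:
            raise ValueError(f"baseline NREMS mean for derivation '{d}' is not positive")
        out.swa[d] = v * (100.0 / mean)
    return out
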
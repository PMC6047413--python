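"""Seeded synthetic mouse datasets with known ground truth.

Hypnograms come from a semi-Markov chain over {W, N, R, BA} with per-phase
dwell means and occupancy targets (light: ~60% NREMS; dark: ~79% wake), plus
one injected consolidated dark-phase wake bout per day.  SWA is generated by
the forward model itself (with the true parameters), perturbed by
multiplicative lognormal epoch noise on NREMS epochs, and renormalised to
its own baseline NREMS mean, so the recorded ground truth stays on the
percent-of-baseline scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from somno.epoch_data import EpochSeries, PHASE_TS, normalize_swa, phase_from_index, write_epoch_table
from somno.model import ModelParams, simulate
from somno.triggers import build_triggers

DEFAULT_LIGHT_TARGETS = {"N": 0.60, "R": 0.11, "W": 0.25, "BA": 0.04}
DEFAULT_DARK_TARGETS = {"N": 0.17, "R": 0.02, "W": 0.79, "BA": 0.01}

#: Mean dwell times (ts) of N runs, R bouts and BA bouts; wake-bout length is
#: derived from the occupancy targets.  BA bouts are uniform on 1..5 ts.
DEFAULT_DWELL = {"N": 25.0, "R": 20.0, "BA": 3.0}


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic dataset generator."""

    n_days: int = 2
    seed: int = 0
    light_targets: dict = field(default_factory=lambda: dict(DEFAULT_LIGHT_TARGETS))
    dark_targets: dict = field(default_factory=lambda: dict(DEFAULT_DARK_TARGETS))
    dwell_means: dict = field(default_factory=lambda: dict(DEFAULT_DWELL))
    # consolidated dark-phase wake bout (ts); ~6 h mean as in mice with wheels
    bout_mean: float = 5400.0
    bout_sd: float = 700.0
    bout_min: float = 2700.0
    bout_max: float = 8100.0
    noise_sigma: float = 0.15       # lognormal sigma on NREMS SWA
    noise_sigma_off: float = 4.0    # additive SD around SWA_L off-NREMS (%)
    artifact_rate: float = 0.028
    truth: ModelParams = field(default_factory=lambda: ModelParams(
        gc=0.0010, rs=0.0002, S_U=400.0, S_0=300.0, SWA_0=150.0,
    ))
    derivations: tuple[str, ...] = ("frontal",)
    ba_as_wake: bool = False

    def validate(self) -> None:
        # printed occupancy tables may sum to 0.99 from rounding; they are
        # renormalised internally, so only gross errors are rejected
        for targets in (self.light_targets, self.dark_targets):
            if abs(sum(targets.values()) - 1.0) > 0.05:
                raise ValueError("occupancy targets must sum to ~1")
        if any(v <= 0 for v in self.dwell_means.values()):
            raise ValueError("dwell means must be positive")
        if self.dwell_means["BA"] > 5:
            raise ValueError("BA dwell mean must be <= 5 ts")
        if not 0 <= self.artifact_rate <= 0.1:
            raise ValueError("artifact rate must be in [0, 0.1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["derivations"] = list(self.derivations)
        return d


def _chain_segment(
    rng: np.random.Generator,
    length: int,
    targets: dict,
    dwell: dict,
) -> np.ndarray:
    """Semi-Markov sequence of ``length`` epochs aimed at the occupancy targets.

    The chain alternates wake bouts with sleep periods.  A sleep period is a
    chain of N runs (geometric, mean ``dwell['N']``); after each N run the
    period either ends (wake follows), continues through an R bout, or
    through a brief awakening.  The branch probabilities and the wake-bout
    mean are solved from the occupancy targets, so realised fractions track
    the targets in expectation:

        p_R  = (f_R / f_N) * d_N / d_R
        p_BA = (f_BA / f_N) * d_N / d_BA
        wake-bout mean = (f_W / f_N) * d_N / p_W
    """
    tot = sum(targets.values())
    f = {s: max(targets[s], 1e-9) / tot for s in targets}
    d_n, d_r, d_b = dwell["N"], dwell["R"], dwell["BA"]
    p_r = (f["R"] / f["N"]) * d_n / d_r
    p_ba = (f["BA"] / f["N"]) * d_n / d_b
    if p_r + p_ba >= 0.95:  # keep a real chance of ending the sleep period
        import warnings

        warnings.warn("occupancy targets unreachable with these dwell means; rescaling branches")
        scale = 0.95 / (p_r + p_ba)
        p_r, p_ba = p_r * scale, p_ba * scale
    p_w = 1.0 - p_r - p_ba
    d_w = (f["W"] / f["N"]) * d_n / p_w
    seq = np.empty(length, dtype="<U2")
    pos = 0
    cur = "W" if rng.random() < f["W"] else "N"
    while pos < length:
        if cur == "W":
            d = int(rng.geometric(min(1.0, 1.0 / d_w)))
            nxt = "N"
        elif cur == "N":
            d = int(rng.geometric(min(1.0, 1.0 / d_n)))
            u = rng.random()
            nxt = "W" if u < p_w else ("R" if u < p_w + p_r else "BA")
        elif cur == "R":
            d = int(rng.geometric(min(1.0, 1.0 / d_r)))
            nxt = "N"
        else:  # BA: uniform 1..5 ts, mean 3, always back to N
            d = int(rng.integers(1, 6))
            nxt = "N"
        d = min(d, length - pos)
        seq[pos : pos + d] = cur
        pos += d
        cur = nxt
    return seq


def generate_hypnogram(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> EpochSeries:
    """Seeded hypnogram with 12:12 LD structure and one dark-phase long wake bout per day."""
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    n_ts = cfg.n_days * 2 * PHASE_TS
    state = np.empty(n_ts, dtype="<U2")
    for day in range(cfg.n_days):
        l0 = day * 2 * PHASE_TS
        d0 = l0 + PHASE_TS
        state[l0:d0] = _chain_segment(rng, PHASE_TS, cfg.light_targets, cfg.dwell_means)
        # consolidated wake bout: draw duration, then rebalance the background
        # dark targets so total dark wake still approaches the configured target
        dur = int(np.clip(rng.normal(cfg.bout_mean, cfg.bout_sd), cfg.bout_min, cfg.bout_max))
        dur = min(dur, PHASE_TS - 600)
        start = d0 + int(rng.integers(0, PHASE_TS - dur + 1))
        w_target = cfg.dark_targets["W"]
        bg_w = (w_target * PHASE_TS - dur) / max(1, PHASE_TS - dur)
        bg_w = float(np.clip(bg_w, 0.05, 0.95))
        other = {s: v for s, v in cfg.dark_targets.items() if s != "W"}
        scale = (1.0 - bg_w) / max(sum(other.values()), 1e-12)
        bg_targets = {"W": bg_w, **{s: v * scale for s, v in other.items()}}
        state[d0 : d0 + PHASE_TS] = _chain_segment(rng, PHASE_TS, bg_targets, cfg.dwell_means)
        state[start : start + dur] = "W"
    series = EpochSeries(
        state=state,
        artifact=np.zeros(n_ts, dtype=bool),
        phase=phase_from_index(n_ts),
        swa={},
    )
    series.validate(strict_phase=True)
    return series


def _calibrate_truth(hyp: EpochSeries, truth: ModelParams, ba_as_wake: bool, tol: float = 1e-3, max_iter: int = 20):
    """Make the ground truth self-consistent with the percent-of-baseline scale.

    Two coupled fixed points are iterated: (a) S_U is rescaled so the
    simulated NREMS SWA mean is 100 (fixed SWA_L breaks exact scale
    invariance, hence the loop) and (b) S_0 / SWA_0 are re-derived from the
    simulation itself with the same rule the estimator applies to data
    (mean over the first >= 45-ts NREMS episode; first-epoch SWA), so that a
    noise-free dataset reproduces its own truth exactly.
    """
    from somno.episodes import detect_nrem_episodes

    trig = build_triggers(hyp, t_a=truth.t_a, t_p=truth.t_p, t_aw=truth.t_aw,
                          t_pw=truth.t_pw, ba_as_wake=ba_as_wake)
    p = truth
    n_mask = hyp.state == "N"
    if not n_mask.any():
        raise ValueError("hypnogram has no NREMS epochs")
    episodes = detect_nrem_episodes(hyp)
    first_long = next((ep for ep in episodes if ep.duration >= 45), None)
    sim = simulate(hyp.n_ts, trig, p)
    for _ in range(max_iter):
        m = float(sim.swa_sim[n_mask].mean())
        k = 100.0 / m
        s_u = p.S_U * k
        if first_long is not None:
            sl = slice(first_long.start, first_long.end)
            usable = hyp.state[sl] == "N"
            s_0 = float(sim.swa_sim[sl][usable].mean()) * k
        else:
            s_0 = p.S_0 * k
        swa_0 = max(float(sim.swa_sim[0]) * k, p.SWA_L)
        new = p.replace(S_U=s_u, S_0=min(max(s_0, p.SWA_L * 1.01), s_u), SWA_0=swa_0)
        moved = max(abs(m - 100.0), abs(new.S_0 - p.S_0), abs(new.SWA_0 - p.SWA_0))
        p = new
        sim = simulate(hyp.n_ts, trig, p)
        if moved < tol:
            break
    return p, trig, sim


def generate_swa(
    hyp: EpochSeries,
    truth: ModelParams,
    noise_sigma: float = 0.15,
    noise_sigma_off: float = 4.0,
    artifact_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    derivation: str = "frontal",
    ba_as_wake: bool = False,
    calibrate: bool = True,
) -> tuple[EpochSeries, ModelParams]:
    """Attach model-generated noisy SWA to a hypnogram.

    Returns the populated series and the (possibly calibrated) ground-truth
    parameters valid on the renormalised percent scale.
    """
    rng = rng or np.random.default_rng(0)
    if calibrate:
        p, trig, sim = _calibrate_truth(hyp, truth, ba_as_wake)
    else:
        p = truth
        trig = build_triggers(hyp, t_a=p.t_a, t_p=p.t_p, t_aw=p.t_aw, t_pw=p.t_pw,
                              ba_as_wake=ba_as_wake)
        sim = simulate(hyp.n_ts, trig, p)
    n_mask = hyp.state == "N"
    swa = np.empty(hyp.n_ts)
    if noise_sigma > 0:
        factor = rng.lognormal(mean=0.0, sigma=noise_sigma, size=int(n_mask.sum()))
    else:
        factor = 1.0
    swa[n_mask] = sim.swa_sim[n_mask] * factor
    n_off = int((~n_mask).sum())
    off_noise = rng.normal(0.0, noise_sigma_off, size=n_off) if noise_sigma_off > 0 else 0.0
    swa[~n_mask] = np.maximum(0.0, p.SWA_L + off_noise)
    artifact = rng.random(hyp.n_ts) < artifact_rate
    out = EpochSeries(
        state=hyp.state.copy(),
        artifact=hyp.artifact | artifact,
        phase=hyp.phase.copy(),
        swa={derivation: swa},
    )
    out = normalize_swa(out)
    return out, p


def make_dataset(
    cfg: GeneratorConfig,
    out_dir: str | Path | None = None,
) -> tuple[EpochSeries, dict[str, ModelParams], dict]:
    """Generate a complete dataset: hypnogram + SWA per derivation + manifest.

    When ``out_dir`` is given, writes ``epochs.tsv``, ``truth.json`` and
    ``manifest.json``.  Deterministic given the config (seed included).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    hyp = generate_hypnogram(cfg, rng)
    # one artifact mask shared by all derivations, as in a real recording
    hyp.artifact |= rng.random(hyp.n_ts) < cfg.artifact_rate
    series = hyp
    truths: dict[str, ModelParams] = {}
    for d in cfg.derivations:
        with_swa, truth = generate_swa(
            hyp,
            cfg.truth,
            noise_sigma=cfg.noise_sigma,
            noise_sigma_off=cfg.noise_sigma_off,
            artifact_rate=0.0,
            rng=rng,
            derivation=d,
            ba_as_wake=cfg.ba_as_wake,
        )
        series = EpochSeries(
            state=hyp.state,
            artifact=hyp.artifact,
            phase=hyp.phase,
            swa={**series.swa, d: with_swa.swa[d]},
        )
        truths[d] = truth
    series.validate()
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "seed": cfg.seed,
        "n_ts": series.n_ts,
        "derivations": list(cfg.derivations),
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_epoch_table(series, out_dir / "epochs.tsv")
        with open(out_dir / "truth.json", "w") as fh:
            json.dump({d: t.to_dict() for d, t in truths.items()}, fh, indent=2)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return series, truths, manifest
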
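"""Seeded synthetic dyadic cohorts.

Generates cohorts with the structure the analysis assumes: ``n_dyads`` pairs
of subjects, ``days`` recording days, ``trials_per_condition_per_day`` trials
in each of the two conditions (collaborative / individual), 120-s trials,
R-peak event times plus respiration/EDA traces at 10 Hz, ball/target pixel
trajectories, and integer ratings on a 1-9 scale.

A per-subject-trial latent "arousal" drives both the physiological
generator parameters and (through ``coupling_autonomic``) the ratings;
``coupling_error`` couples ratings to the realised tracking error instead.
Ground truth (latents, SCR events, error scales) is attached to each trial
record under ``ground_truth`` strictly for testing — the analysis path never
reads it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .behavior import TrackingTrace, error_for_rating, tracking_errors
from .errors import ConfigError
from .resp_eda import scr_from_driver

__all__ = [
    "CohortConfig",
    "LatentState",
    "TrialRecord",
    "generate_cohort",
    "generate_nn_series",
    "generate_eda_trace",
    "generate_tracking_trace",
    "generate_ratings",
    "CONDITIONS",
]

CONDITIONS = ("collaborative", "individual")


@dataclass(frozen=True)
class CohortConfig:
    n_dyads: int = 14
    days: int = 2
    trials_per_condition_per_day: int = 7
    trial_duration: float = 120.0
    fs_resp_eda: float = 10.0
    rating_scale: tuple = (1, 9)
    coupling_autonomic: float = 0.5
    coupling_error: float = 0.3
    subject_heterogeneity: float = 0.0
    rating_noise_sd: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_dyads", "days", "trials_per_condition_per_day"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {v!r}")
        if self.trial_duration <= 0:
            raise ConfigError(f"trial_duration must be > 0, got {self.trial_duration}")
        if self.fs_resp_eda <= 0:
            raise ConfigError(f"fs_resp_eda must be > 0, got {self.fs_resp_eda}")
        for name in ("coupling_autonomic", "coupling_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.subject_heterogeneity < 0:
            raise ConfigError(
                f"subject_heterogeneity must be >= 0, got {self.subject_heterogeneity}")
        if self.rating_noise_sd < 0:
            raise ConfigError(f"rating_noise_sd must be >= 0, got {self.rating_noise_sd}")
        lo, hi = self.rating_scale
        if not (isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer))
                and lo < hi):
            raise ConfigError(f"rating_scale must be an integer range, got {self.rating_scale}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class LatentState:
    """Generative latent for one subject-trial."""

    arousal: float
    subject_offset: float


@dataclass
class TrialRecord:
    """One subject-trial with signals, tracking trace and ratings."""

    dyad_id: int
    subject_id: int
    day: int
    condition: str
    trial_index: int
    axis: str                       # which tablet axis this subject controls
    rpeaks: np.ndarray              # R-peak event times, seconds
    resp: np.ndarray
    eda: np.ndarray
    fs: float
    tracking: TrackingTrace
    ratings: dict                   # {"R1": int, "R2": int?, "R3": int?}
    ground_truth: dict = field(default_factory=dict, repr=False)


def generate_nn_series(mean_nn: float, sdnn_target: float, lf_frac: float,
                       hf_frac: float, resp_rate: float, duration: float,
                       rng: np.random.Generator) -> np.ndarray:
    """R-peak times whose NN process is mean + LF/HF sinusoids + white noise.

    A sinusoid of amplitude A contributes variance A^2/2, so amplitudes are
    chosen as ``sdnn*sqrt(2*frac)`` and the white-noise share takes the rest;
    the realised SDNN then approximates ``sdnn_target``.
    """
    if mean_nn <= 0:
        raise ConfigError(f"mean_nn must be > 0, got {mean_nn}")
    if sdnn_target < 0:
        raise ConfigError(f"sdnn_target must be >= 0, got {sdnn_target}")
    if lf_frac < 0 or hf_frac < 0 or lf_frac + hf_frac > 1.0 + 1e-12:
        raise ConfigError("lf_frac/hf_frac must be >= 0 and sum to <= 1")
    if duration < mean_nn / 1000.0:
        raise ConfigError("duration shorter than one mean NN interval")
    a_lf = sdnn_target * np.sqrt(2.0 * lf_frac)
    a_hf = sdnn_target * np.sqrt(2.0 * hf_frac)
    noise_sd = sdnn_target * np.sqrt(max(0.0, 1.0 - lf_frac - hf_frac))
    phi_lf = rng.uniform(0, 2 * np.pi)
    phi_hf = rng.uniform(0, 2 * np.pi)
    peaks = []
    t = 0.0
    floor_ms = 0.3 * mean_nn
    while True:
        nn = (mean_nn
              + a_lf * np.sin(2 * np.pi * 0.1 * t + phi_lf)
              + a_hf * np.sin(2 * np.pi * resp_rate * t + phi_hf)
              + noise_sd * rng.standard_normal())
        nn = max(nn, floor_ms)
        t += nn / 1000.0
        if t >= duration:
            break
        peaks.append(t)
    return np.asarray(peaks)


def generate_eda_trace(tonic_level: float, drift: float, scr_rate: float,
                       scr_amp: float, duration: float, fs: float,
                       rng: np.random.Generator, noise_sd: float = 0.0) -> tuple:
    """Tonic level + linear drift + Poisson-timed SCR events (Bateman kernel).

    Returns ``(trace, ground_truth)`` where the ground truth holds event
    times, amplitudes and the tonic component for recovery tests.
    """
    if fs <= 0:
        raise ConfigError(f"fs must be > 0, got {fs}")
    if scr_rate < 0:
        raise ConfigError(f"scr_rate must be >= 0, got {scr_rate}")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    tonic = tonic_level + drift * t / 60.0
    driver = np.zeros(n)
    n_events = rng.poisson(scr_rate * duration / 60.0) if scr_rate > 0 else 0
    times = np.sort(rng.uniform(0.0, max(duration - 5.0, 0.0), size=n_events))
    amps = scr_amp * rng.uniform(0.5, 1.5, size=n_events)
    for ev_t, a in zip(times, amps):
        driver[int(ev_t * fs)] += a
    scr = scr_from_driver(driver, fs)
    trace = tonic + scr
    if noise_sd > 0:
        trace = trace + noise_sd * rng.standard_normal(n)
    gt = {"event_times": times, "amplitudes": amps, "tonic": tonic, "scr": scr}
    return trace, gt


def generate_tracking_trace(skill: float, duration: float, fs_track: float,
                            rng: np.random.Generator,
                            error_scale: float | None = None,
                            speed: float = 60.0) -> tuple:
    """Constant-speed target with random reversals plus AR(1) ball error.

    ``error_scale`` (pixels) defaults to ``40 / (1 + skill)``; as skill grows
    the ball converges to the target.  Returns ``(trace, ground_truth)``.
    """
    if skill < 0:
        raise ConfigError(f"skill must be >= 0, got {skill}")
    if error_scale is None:
        error_scale = 40.0 / (1.0 + skill)
    n = int(round(duration * fs_track))
    dt = 1.0 / fs_track
    t = np.arange(n) * dt

    def target_axis() -> np.ndarray:
        pos = np.empty(n)
        x, direction = 384.0, 1.0
        next_flip = rng.exponential(3.0)
        for i in range(n):
            pos[i] = x
            x += direction * speed * dt
            next_flip -= dt
            if next_flip <= 0.0 or not (0.0 <= x <= 768.0):
                direction = -direction
                x = float(np.clip(x, 0.0, 768.0))
                next_flip = rng.exponential(3.0)
        return pos

    def ar1_error() -> np.ndarray:
        rho = 0.95
        innov_sd = error_scale * np.sqrt(1.0 - rho**2)
        e = np.empty(n)
        e[0] = error_scale * rng.standard_normal()
        for i in range(1, n):
            e[i] = rho * e[i - 1] + innov_sd * rng.standard_normal()
        return e

    tx, ty = target_axis(), target_axis()
    ex, ey = ar1_error(), ar1_error()
    trace = TrackingTrace(times=t, ball_x=tx + ex, ball_y=ty + ey,
                          target_x=tx, target_y=ty)
    return trace, {"error_scale": error_scale}


def generate_ratings(latent: LatentState, std_errors: dict, config: CohortConfig,
                     rng: np.random.Generator, condition: str,
                     gain: float = 1.8, base: float = 6.0) -> dict:
    """Integer ratings mixing the autonomic latent and the tracking error.

    ``std_errors`` maps rating kind to the standardised (zero-mean,
    unit-variance across the cohort) tracking error relevant for that kind.
    rating = round(base + gain*ca*arousal - gain*ce*std_error
                   + subject_offset + noise), clipped to the scale.
    """
    lo, hi = config.rating_scale
    kinds = ("R1", "R2", "R3") if condition == "collaborative" else ("R1",)
    out = {}
    for kind in kinds:
        val = (base
               + gain * config.coupling_autonomic * latent.arousal
               - gain * config.coupling_error * std_errors[kind]
               + latent.subject_offset
               + config.rating_noise_sd * rng.standard_normal())
        out[kind] = int(np.clip(np.rint(val), lo, hi))
    return out


def _trial_error_inputs(record_axis: str, trace: TrackingTrace) -> dict:
    err = tracking_errors(trace)
    return {
        "R1": error_for_rating("R1", record_axis, err),
        "R2": error_for_rating("R2", record_axis, err),
        "R3": error_for_rating("R3", record_axis, err),
    }


def generate_cohort(config: CohortConfig) -> list:
    """Generate all subject-trial records for one cohort.

    Deterministic: identical config (including seed) yields identical
    cohorts.  Two subjects per dyad; subject 0 of a dyad controls the x
    axis, subject 1 the y axis.  In the collaborative condition the two
    partners share one ball/target trace; in the individual condition each
    subject tracks their own target.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h = config.subject_heterogeneity
    fs = config.fs_resp_eda
    dur = config.trial_duration

    n_subjects = config.n_dyads * 2
    rating_offsets = h * rng.standard_normal(n_subjects)
    nn_offsets = 60.0 * h * rng.standard_normal(n_subjects)
    eda_offsets = 1.0 * h * rng.standard_normal(n_subjects)
    skill_base = np.exp(0.3 * rng.standard_normal(n_subjects))

    # first pass: signals, traces, latents
    pending = []
    for dyad in range(config.n_dyads):
        for day in range(1, config.days + 1):
            for condition in CONDITIONS:
                for trial in range(config.trials_per_condition_per_day):
                    shared_trace = None
                    if condition == "collaborative":
                        shared_trace, shared_gt = generate_tracking_trace(
                            skill=float(np.mean(skill_base[2 * dyad:2 * dyad + 2])),
                            duration=dur, fs_track=fs, rng=rng)
                    for local in range(2):
                        sid = 2 * dyad + local
                        axis = "x" if local == 0 else "y"
                        z = float(rng.standard_normal())
                        mean_nn = 850.0 - 70.0 * np.tanh(z) + nn_offsets[sid]
                        hf_frac = float(np.clip(0.45 + 0.20 * np.tanh(z), 0.05, 0.85))
                        lf_frac = float(np.clip(0.35 - 0.15 * np.tanh(z), 0.05,
                                                0.95 - hf_frac))
                        resp_rate = float(np.clip(0.25 + 0.03 * z, 0.15, 0.38))
                        rpeaks = generate_nn_series(
                            mean_nn=max(mean_nn, 400.0), sdnn_target=50.0,
                            lf_frac=lf_frac, hf_frac=hf_frac,
                            resp_rate=resp_rate, duration=dur, rng=rng)
                        t = np.arange(int(round(dur * fs))) / fs
                        resp = (np.sin(2 * np.pi * resp_rate * t
                                       + rng.uniform(0, 2 * np.pi))
                                + 0.05 * rng.standard_normal(t.size))
                        eda, eda_gt = generate_eda_trace(
                            tonic_level=5.0 + eda_offsets[sid] + 0.5 * z,
                            drift=0.2, scr_rate=float(np.clip(4.0 + 2.0 * z, 0.2, 10.0)),
                            scr_amp=0.6, duration=dur, fs=fs, rng=rng)
                        if condition == "collaborative":
                            trace, track_gt = shared_trace, shared_gt
                        else:
                            trace, track_gt = generate_tracking_trace(
                                skill=skill_base[sid], duration=dur,
                                fs_track=fs, rng=rng)
                        latent = LatentState(arousal=z,
                                             subject_offset=float(rating_offsets[sid]))
                        rec = TrialRecord(
                            dyad_id=dyad, subject_id=sid, day=day,
                            condition=condition, trial_index=trial, axis=axis,
                            rpeaks=rpeaks, resp=resp, eda=eda, fs=fs,
                            tracking=trace, ratings={},
                            ground_truth={"latent": latent, "eda": eda_gt,
                                          "tracking": track_gt})
                        pending.append(rec)

    # second pass: standardise errors cohort-wide, then draw ratings
    raw_errors = [_trial_error_inputs(r.axis, r.tracking) for r in pending]
    stats = {}
    for kind in ("R1", "R2", "R3"):
        vals = np.array([e[kind] for e in raw_errors])
        mu, sd = float(vals.mean()), float(vals.std())
        stats[kind] = (mu, sd if sd > 0 else 1.0)
    for rec, errs in zip(pending, raw_errors):
        std_errors = {k: (errs[k] - stats[k][0]) / stats[k][1] for k in errs}
        latent = rec.ground_truth["latent"]
        rec.ratings = generate_ratings(latent, std_errors, config, rng,
                                       rec.condition)
        rec.ground_truth["std_errors"] = std_errors
    return pending
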
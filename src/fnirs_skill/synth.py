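"""Forward simulation of fNIRS training studies with known ground truth.

The hemodynamic generator mirrors the signal decomposition the analysis
assumes: long channels carry a task-locked cortical response (canonical
double-gamma HRF convolved with the block drive, with slow within-block
adaptation), a shared superficial/scalp signal scaled by a per-channel
gain, physiological oscillations (cardiac, respiration, Mayer waves),
linear drift, optional motion artifacts and white noise; short channels
carry the superficial/physiological part only.  The canonical HRF is
deliberately *not* the Gaussian estimation basis, so recovery tests do
not fit with the generating basis.

The behavioral generator draws exponentially improving completion times
and penalties per trainee; cohort presets are calibrated so the day-1
and day-15 summaries of a simulated 21-trainee cohort match the training
study they emulate (day-1 time ≈ 483 s / score ≈ 49; day-15 time ≈
114 s / score ≈ 440), with distinct good/weak learner classes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as _signal

from . import performance as perf
from .preprocess import (
    DEFAULT_EXTINCTION,
    ExtinctionTable,
    mbll_forward,
)
from .probe import (
    STAGE_CONCENTRATION,
    STAGE_INTENSITY,
    ProbeLayout,
    Recording,
    SessionSpec,
    StimDesign,
    session_schedule,
    session_stim,
    write_recording,
)

# ---------------------------------------------------------------------------
# Montage generator
# ---------------------------------------------------------------------------

def make_layout(
    n_long: int = 24,
    n_short: int = 8,
    long_separation_mm: float = 30.0,
    short_separation_mm: float = 8.0,
) -> ProbeLayout:
    """Synthetic montage with realistic source–detector separations.

    Long channels sit at 30 mm (a standard adult separation; the study
    montage does not print one) and short channels at 8 mm (the optimum
    adult short separation).  Sources are laid on a grid; each long
    channel gets its own detector and ``n_short`` short detectors are
    spread evenly across the sources.  The montage emulates channel
    *separations*, not the exact 16×16 optode count of the real cap.
    """
    if n_long < 1 or n_short < 0:
        raise ValueError("need at least one long channel")
    cols = 8
    src = np.array(
        [[40.0 * (i % cols), 40.0 * (i // cols), 0.0] for i in range(n_long)]
    )
    det_long = src + np.array([long_separation_mm, 0.0, 0.0])
    short_sources = np.unique(
        np.round(np.linspace(0, n_long - 1, max(n_short, 1))).astype(int)
    )[:n_short]
    det_short = src[short_sources] + np.array([0.0, short_separation_mm, 0.0])
    detectors = np.vstack([det_long, det_short]) if n_short else det_long
    channels = [(i, i) for i in range(n_long)]
    channels += [(int(s), n_long + j) for j, s in enumerate(short_sources)]
    return ProbeLayout(src, detectors, tuple(channels))


# ---------------------------------------------------------------------------
# Hemodynamic ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationTruth:
    """Everything the hemodynamic forward model needs, per long channel.

    Amplitudes are HbO in μM; HbR is −``hbr_ratio`` × the HbO task
    component with its own nuisance draws.  Scalar fields broadcast over
    channels.  ``seed`` fully determines the generated recording.
    """

    hrf_amplitude: np.ndarray | float = 1.0  # μM, per long channel
    hrf_peak_time: float = 6.0  # s
    hbr_ratio: float = 1.0 / 3.0
    superficial_gain: np.ndarray | float = 1.0  # per long channel
    physio: tuple[tuple[float, float, float], ...] = (
        (1.1, 0.20, 0.0),  # cardiac: Hz, μM, rad
        (0.25, 0.15, 1.0),  # respiration
        (0.10, 0.30, 2.0),  # Mayer waves — at the filter edge on purpose
    )
    superficial_slow_sd: float = 0.5  # μM, sub-0.05 Hz scalp fluctuation
    drift_slope_sd: float = 0.002  # μM/s, per-channel linear drift scale
    motion_events: tuple[tuple[float, str, float], ...] = ()
    sustain_tau_s: float = 30.0  # within-block adaptation time constant
    sustain_floor: float = 0.3  # plateau fraction of the initial drive
    noise_sd: float = 0.15  # μM white measurement noise
    seed: int = 0

    def amplitudes(self, n_long: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.hrf_amplitude, float), (n_long,)).copy()

    def gains(self, n_long: int) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.superficial_gain, float), (n_long,)
        ).copy()


def canonical_hrf(t: np.ndarray, peak_time: float = 6.0) -> np.ndarray:
    """Unit-peak double-gamma HRF (peak ``peak_time`` s, undershoot at 16 s,
    undershoot ratio 1/6)."""
    t = np.asarray(t, dtype=float)
    h = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    # gamma bumps with mode = shape-1 (scale 1), time-scaled to the peak
    shape_peak, shape_under = 7.0, 17.0
    scale = peak_time / (shape_peak - 1.0)
    g1 = tp ** (shape_peak - 1) * np.exp(-tp / scale)
    g2 = tp ** (shape_under - 1) * np.exp(-tp / scale)
    g1 /= g1.max() if g1.size and g1.max() > 0 else 1.0
    g2 /= g2.max() if g2.size and g2.max() > 0 else 1.0
    h[pos] = g1 - g2 / 6.0
    m = np.abs(h).max()
    return h / m if m > 0 else h


def task_drive(stim: StimDesign, t: np.ndarray, truth: SimulationTruth) -> np.ndarray:
    """Neural drive: block boxcars with exponential within-block adaptation."""
    drive = np.zeros_like(t)
    for onset, dur in zip(stim.onsets, stim.durations):
        inblock = (t >= onset) & (t < onset + dur)
        tau = max(truth.sustain_tau_s, 1e-6)
        env = truth.sustain_floor + (1.0 - truth.sustain_floor) * np.exp(
            -(t[inblock] - onset) / tau
        )
        drive[inblock] += env
    return drive


def task_waveform(
    stim: StimDesign, fs: float, n_samples: int, truth: SimulationTruth
) -> np.ndarray:
    """Noiseless unit-peak task response: drive ⊛ canonical HRF.

    Normalized so a channel of amplitude a peaks at a μM; the generator
    and all recovery oracles share this definition.
    """
    t = np.arange(n_samples) / fs
    drive = task_drive(stim, t, truth)
    kt = np.arange(0.0, 40.0, 1.0 / fs)
    kernel = canonical_hrf(kt, truth.hrf_peak_time)
    resp = _signal.fftconvolve(drive, kernel)[:n_samples] / fs
    m = np.abs(resp).max()
    return resp / m if m > 0 else resp


def _superficial(
    n_samples: int, fs: float, truth: SimulationTruth, rng: np.random.Generator
) -> np.ndarray:
    """Shared scalp signal: physiological sinusoids + slow fluctuation."""
    t = np.arange(n_samples) / fs
    s = np.zeros(n_samples)
    for f, a, ph in truth.physio:
        if not (0.0 < f < fs / 2.0):
            raise ValueError(f"physio frequency {f} Hz outside (0, Nyquist)")
        s += a * np.sin(2 * np.pi * f * t + ph)
    if truth.superficial_slow_sd > 0 and n_samples > 30:
        sos = _signal.butter(2, 0.05, btype="lowpass", fs=fs, output="sos")
        slow = _signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
        sd = slow.std()
        if sd > 0:
            s += truth.superficial_slow_sd * slow / sd
    return s


def _apply_motion(
    data: np.ndarray, fs: float, events, rng: np.random.Generator
) -> None:
    """Add spike (0.5 s Gaussian transient) / shift (step) artifacts in place."""
    n = data.shape[-1]
    t = np.arange(n) / fs
    for when, kind, mag in events:
        if kind == "spike":
            data += mag * np.exp(-((t - when) ** 2) / (2 * 0.25**2 / 4))
        elif kind == "shift":
            data += mag * (t >= when)
        else:
            raise ValueError(f"unknown motion event kind {kind!r}")


def simulate_hemodynamics(
    truth: SimulationTruth,
    stim: StimDesign,
    layout: ProbeLayout,
    duration: float,
    fs: float = 5.0,
) -> tuple[Recording, dict]:
    """Concentration-stage recording for the full montage (shorts embedded).

    Returns the recording and a components dict holding the noiseless
    pieces (``task`` per long channel, ``superficial`` series, per-channel
    amplitudes/gains) for use as recovery oracles.
    """
    if stim.n_blocks and stim.end_time() > duration + 1e-9:
        raise ValueError("stimulus blocks extend past the recording duration")
    n = int(round(duration * fs))
    rng = np.random.default_rng(truth.seed)
    long_idx = layout.long_indices
    short_idx = layout.short_indices
    amps = truth.amplitudes(len(long_idx))
    gains = truth.gains(len(long_idx))
    wave = task_waveform(stim, fs, n, truth)
    sup = _superficial(n, fs, truth, rng)
    t = np.arange(n) / fs
    data = np.zeros((layout.n_channels, 2, n))
    task_hbo = amps[:, None] * wave[None, :]
    for li, ci in enumerate(long_idx):
        drift = rng.normal(0.0, truth.drift_slope_sd) * t
        drift_r = rng.normal(0.0, truth.drift_slope_sd) * t
        data[ci, 0] = (
            task_hbo[li]
            + gains[li] * sup
            + drift
            + truth.noise_sd * rng.standard_normal(n)
        )
        data[ci, 1] = (
            -truth.hbr_ratio * task_hbo[li]
            + 0.25 * gains[li] * sup
            + drift_r
            + truth.noise_sd * rng.standard_normal(n)
        )
    for ci in short_idx:
        data[ci, 0] = sup + truth.noise_sd * rng.standard_normal(n)
        data[ci, 1] = 0.25 * sup + truth.noise_sd * rng.standard_normal(n)
    if truth.motion_events:
        # motion affects the optical coupling, hence every component alike
        for ci in range(layout.n_channels):
            for wi in range(2):
                _apply_motion(data[ci, wi], fs, truth.motion_events, rng)
    rec = Recording(
        sample_rate=fs, data=data, stage=STAGE_CONCENTRATION, layout=layout, stim=stim
    )
    components = {
        "task": task_hbo,
        "waveform": wave,
        "superficial": sup,
        "amplitudes": amps,
        "gains": gains,
    }
    return rec, components


def to_intensity(
    conc: Recording,
    i0: float = 1.0,
    ext: ExtinctionTable = DEFAULT_EXTINCTION,
    ppf: tuple[float, float] = (1.0, 1.0),
) -> Recording:
    """Forward MBLL then I = I₀·10^(−ΔOD): concentration → raw intensity.

    Exact inverse of the preprocessing chain's MBLL step (up to the OD
    reference, which removes the temporal mean).
    """
    if conc.stage != STAGE_CONCENTRATION:
        raise ValueError(f"expected concentration stage, got {conc.stage}")
    od = mbll_forward(conc.data, conc.layout.channel_distances_mm, ext, ppf)
    return Recording(
        sample_rate=conc.sample_rate,
        data=i0 * 10.0 ** (-od),
        stage=STAGE_INTENSITY,
        layout=conc.layout,
        stim=conc.stim,
        meta=dict(conc.meta),
    )


# ---------------------------------------------------------------------------
# Behavioral ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehavioralTruth:
    """Exponential learning curves for one trainee.

    completion_time(r) = t_inf + (t0 − t_inf)·exp(−r/tau) + noise with r
    the 0-based repetition index; penalties follow the same law.  The
    cohort presets below are calibrated so simulated day-1 / day-15
    summaries land on the published training-cohort means.
    """

    t0: float = 502.0  # s — day-1 mean of reps 1–3 comes out ≈ 483 s
    t_inf: float = 103.0  # s
    tau: float = 20.0  # repetitions
    penalty0: float = 69.0
    penalty_inf: float = 45.0
    penalty_tau: float = 25.0
    noise_sd_time: float = 30.0  # s
    noise_sd_penalty: float = 18.0  # score units
    learner_class: str = "good"
    seed: int = 0
    min_time: float = 30.0  # positive floor on completion times

    def __post_init__(self) -> None:
        if not (self.t_inf < self.t0):
            raise ValueError("need t_inf < t0")
        if self.penalty_inf > self.penalty0:
            raise ValueError("need penalty_inf <= penalty0")
        if self.tau <= 0 or self.penalty_tau <= 0:
            raise ValueError("learning rates must be positive")

    def mean_time(self, r: np.ndarray | float) -> np.ndarray | float:
        return self.t_inf + (self.t0 - self.t_inf) * np.exp(-np.asarray(r) / self.tau)

    def mean_penalty(self, r: np.ndarray | float) -> np.ndarray | float:
        return self.penalty_inf + (self.penalty0 - self.penalty_inf) * np.exp(
            -np.asarray(r) / self.penalty_tau
        )


#: Learner-class presets.  Good learners asymptote near score ≈ 468
#: (above the cohort mean), weak learners near ≈ 378 (below it); both
#: classes share the novice starting point.
GOOD_PRESET = BehavioralTruth(t_inf=90.0, penalty_inf=30.0, learner_class="good")
WEAK_PRESET = BehavioralTruth(
    t_inf=125.0, penalty_inf=70.0, penalty0=90.0, tau=28.0, learner_class="weak"
)
PRESETS = {"good": GOOD_PRESET, "weak": WEAK_PRESET}


def draw_behavioral_truth(
    preset: BehavioralTruth, rng: np.random.Generator, seed: int
) -> BehavioralTruth:
    """Subject-level draw around a class preset (between-subject variation)."""
    t_inf = max(45.0, rng.normal(preset.t_inf, 15.0))
    return replace(
        preset,
        t0=max(t_inf + 60.0, rng.normal(preset.t0, 100.0)),
        t_inf=t_inf,
        tau=float(np.clip(rng.normal(preset.tau, 4.0), 8.0, 40.0)),
        penalty_inf=float(
            np.clip(rng.normal(preset.penalty_inf, 10.0), 5.0, preset.penalty0 - 5.0)
        ),
        seed=seed,
    )


def simulate_trials(
    truth: BehavioralTruth,
    n_reps: int,
    subject: str = "P01",
    schedule: Sequence[SessionSpec] | None = None,
    scoring: perf.ScoringConfig = perf.ScoringConfig(),
    deviation0: float = 1.5,
    deviation_inf: float = 0.55,
) -> list[perf.TrialRecord]:
    """Simulate ``n_reps`` task repetitions for one trainee.

    Deviations (mm) shadow the penalty learning curve for the trial log;
    the score is computed from time and penalty via the scoring rule.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(truth.seed)
    r = np.arange(n_reps)
    times = np.maximum(
        truth.min_time,
        truth.mean_time(r) + truth.noise_sd_time * rng.standard_normal(n_reps),
    )
    pens = np.maximum(
        0.0,
        truth.mean_penalty(r) + truth.noise_sd_penalty * rng.standard_normal(n_reps),
    )
    devs = np.maximum(
        0.05,
        deviation_inf
        + (deviation0 - deviation_inf) * np.exp(-r / truth.penalty_tau)
        + 0.4 * rng.standard_normal(n_reps),
    )
    sessions = np.ones(n_reps, dtype=int)
    if schedule is not None:
        sess = []
        for spec in schedule:
            sess += [spec.session_index] * spec.repetitions
        if len(sess) < n_reps:
            raise ValueError("schedule provides fewer repetitions than n_reps")
        sessions = np.asarray(sess[:n_reps])
    return [
        perf.TrialRecord(
            subject=subject,
            session=int(sessions[i]),
            repetition=i + 1,
            completion_time=float(times[i]),
            deviation=float(devs[i]),
            penalty=float(pens[i]),
            score=perf.score_trial(float(times[i]), float(pens[i]), scoring),
        )
        for i in range(n_reps)
    ]


# ---------------------------------------------------------------------------
# Whole-study generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """The simulated training study (defaults = the emulated cohort).

    21 trainees (12 good / 9 weak learners) × 15 training sessions plus
    one retention session; designated "sensorimotor" channels ramp their
    HbO task amplitude from ``amp_day1`` to ``amp_day15`` across
    training, matching the effect structure the day-15-vs-day-1 contrast
    must detect; a further set is boosted for good learners only.
    """

    n_subjects: int = 21
    n_good: int = 12
    n_sessions: int = 15
    include_retention: bool = True
    retention_reps: int = 3
    n_long: int = 24
    n_short: int = 8
    elevated_channels: tuple[int, ...] = (4, 5, 6, 10, 11, 12)
    good_boost_channels: tuple[int, ...] = (5, 11, 18)
    amp_day1: float = 0.4  # μM
    amp_day15: float = 1.2  # μM
    good_boost: float = 0.4  # μM added for good learners late in training
    amp_subject_sd: float = 0.15  # multiplicative, lognormal-ish
    rest_duration_s: float = 120.0
    block_duration_s: float | None = None  # None → schedule minutes
    fs: float = 5.0
    recording_format: str = "csv_bundle"
    motion_rate_per_session: float = 1.0
    hemo: SimulationTruth = field(default_factory=SimulationTruth)

    def schedule(self) -> list[SessionSpec]:
        bands = [b for b in session_schedule() if b.session_index <= self.n_sessions]
        if len(bands) < self.n_sessions:
            raise ValueError("n_sessions exceeds the default 15-session schedule")
        if self.include_retention:
            block_min = bands[-1].block_duration_min
            bands.append(SessionSpec(self.n_sessions + 1, self.retention_reps, block_min))
        return bands

    def session_amplitude(self, session_index: int, channel_pos: int, good: bool) -> float:
        """True HbO amplitude (μM) for one long channel in one session."""
        frac = (
            0.0
            if self.n_sessions == 1
            else (min(session_index, self.n_sessions) - 1) / (self.n_sessions - 1)
        )
        a = self.amp_day1
        if channel_pos in self.elevated_channels:
            a += (self.amp_day15 - self.amp_day1) * frac
        if good and channel_pos in self.good_boost_channels:
            a += self.good_boost * frac
        return a


def simulate_study(config: StudyConfig, seed: int, out_dir: str | Path) -> Path:
    """Write a full study bundle: per-subject/session recordings (intensity
    stage), ``trials.csv`` and ``truth.json``.

    Deterministic in (config, seed); recordings are written in
    ``config.recording_format`` under ``<out>/<subject>/session<k>``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    layout = make_layout(config.n_long, config.n_short)
    schedule = config.schedule()
    n_train_reps = sum(
        s.repetitions for s in schedule if s.session_index <= config.n_sessions
    )
    classes = ["good"] * config.n_good + ["weak"] * (
        config.n_subjects - config.n_good
    )
    truth_doc: dict = {
        "seed": seed,
        "elevated_channels": list(config.elevated_channels),
        "good_boost_channels": list(config.good_boost_channels),
        "subjects": {},
    }
    all_trials: list[perf.TrialRecord] = []
    for si in range(config.n_subjects):
        subject = f"P{si + 1:02d}"
        cls = classes[si]
        sub_seed = int(rng.integers(2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        btruth = draw_behavioral_truth(
            PRESETS[cls], sub_rng, seed=int(sub_rng.integers(2**31 - 1))
        )
        amp_mult = float(
            np.exp(sub_rng.normal(0.0, config.amp_subject_sd))
        )
        trials = simulate_trials(
            btruth, n_train_reps, subject=subject, schedule=schedule
        )
        if config.include_retention:
            ret = simulate_trials(
                replace(btruth, t0=btruth.t_inf + 60.0, tau=1e6,
                        penalty0=btruth.penalty_inf + 1.0, penalty_tau=1e6,
                        seed=btruth.seed + 1),
                config.retention_reps,
                subject=subject,
            )
            last = config.n_sessions + 1
            ret = [
                replace(t, session=last, repetition=n_train_reps + t.repetition)
                for t in ret
            ]
            trials += ret
        all_trials += trials
        amp_matrix = []
        subj_dir = out / subject
        for spec in schedule:
            stim, duration = session_stim(
                spec, config.rest_duration_s, config.block_duration_s
            )
            amps = amp_mult * np.array(
                [
                    config.session_amplitude(spec.session_index, p, cls == "good")
                    for p in range(config.n_long)
                ]
            )
            amp_matrix.append(amps.tolist())
            n_events = sub_rng.poisson(config.motion_rate_per_session)
            events = tuple(
                (
                    float(sub_rng.uniform(10.0, duration - 10.0)),
                    ("spike", "shift")[int(sub_rng.integers(2))],
                    float(sub_rng.uniform(0.5, 2.0) * (-1) ** sub_rng.integers(2)),
                )
                for _ in range(n_events)
            )
            struth = replace(
                config.hemo,
                hrf_amplitude=amps,
                superficial_gain=sub_rng.uniform(0.5, 1.5, config.n_long),
                motion_events=events,
                seed=int(sub_rng.integers(2**31 - 1)),
            )
            conc, _ = simulate_hemodynamics(struth, stim, layout, duration, config.fs)
            inten = to_intensity(conc)
            name = f"session{spec.session_index:02d}"
            path = subj_dir / (
                name + (".snirf" if config.recording_format == "snirf" else "")
            )
            subj_dir.mkdir(parents=True, exist_ok=True)
            write_recording(inten, path, config.recording_format)
        truth_doc["subjects"][subject] = {
            "learner_class": cls,
            "amp_multiplier": amp_mult,
            "behavioral": {
                "t0": btruth.t0, "t_inf": btruth.t_inf, "tau": btruth.tau,
                "penalty0": btruth.penalty0, "penalty_inf": btruth.penalty_inf,
            },
            "session_amplitudes": amp_matrix,
        }
    perf.trials_to_frame(all_trials).to_csv(out / "trials.csv", index=False)
    (out / "truth.json").write_text(json.dumps(truth_doc, indent=1))
    return out


def bundle_digest(path: str | Path) -> str:
    """SHA-256 over every file in a study bundle (stable order)."""
    h = hashlib.sha256()
    for f in sorted(Path(path).rglob("*")):
        if f.is_file():
            h.update(str(f.relative_to(path)).encode())
            h.update(f.read_bytes())
    return h.hexdigest()
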
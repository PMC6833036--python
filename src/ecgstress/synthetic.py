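"""Synthetic stress-modulated ECG sessions.

Beat timing is drawn from a Gaussian RR-interval model with sinusoidal
respiratory modulation; beat morphology is a sum-of-Gaussians P-QRS-T
template placed at each R time plus white noise.  Rest and stress
segments differ in mean heart rate and RR variability, which is exactly
the contrast the downstream classifier must learn.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import EcgRecord, Marker


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class BeatParams:
    """Condition-level beat statistics and morphology scale."""

    mean_hr: float          # beats/min
    sdnn: float             # RR standard deviation, ms
    respiratory_mod_hz: float = 0.25
    amplitude_mv: float = 1.0
    noise_sd_mv: float = 0.05

    def __post_init__(self):
        if not 30.0 <= self.mean_hr <= 220.0:
            raise ValidationError(f"mean_hr {self.mean_hr} outside [30, 220]")
        if self.sdnn < 0:
            raise ValidationError("sdnn must be >= 0")
        if self.amplitude_mv <= 0:
            raise ValidationError("amplitude_mv must be > 0")
        if self.noise_sd_mv < 0:
            raise ValidationError("noise_sd_mv must be >= 0")


REST_PARAMS = BeatParams(mean_hr=65.0, sdnn=50.0, respiratory_mod_hz=0.25)
STRESS_PARAMS = BeatParams(mean_hr=85.0, sdnn=25.0, respiratory_mod_hz=0.35)


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered (condition, duration) segments at a fixed sampling rate."""

    name: str
    segments: tuple[tuple[str, float], ...]
    fs: int

    def __post_init__(self):
        if self.fs not in (256, 496):
            raise ValidationError(f"fs must be 256 or 496, got {self.fs}")
        if not self.segments:
            raise ValidationError("protocol needs at least one segment")
        for cond, dur in self.segments:
            if cond not in ("rest", "stress"):
                raise ValidationError(f"unknown condition {cond!r}")
            if dur <= 0:
                raise ValidationError("segment durations must be > 0")

    @property
    def total_s(self) -> float:
        return sum(d for _, d in self.segments)

    @property
    def stressor(self) -> str:
        return "driving" if self.name.startswith("driving") \
            else "mental_arithmetic"


def mental_arithmetic_protocol(segment_s: float = 300.0,
                               fs: int = 256) -> ProtocolSpec:
    """Rest/task/rest/task alternation (default 5 min per segment)."""
    spec = ProtocolSpec(
        name="mental_arithmetic",
        segments=(("rest", segment_s), ("stress", segment_s),
                  ("rest", segment_s), ("stress", segment_s)),
        fs=fs)
    if segment_s == 300.0:
        assert sum(d for c, d in spec.segments if c == "rest") == 600.0
        assert sum(d for c, d in spec.segments if c == "stress") == 600.0
    return spec


def driving_protocol(stress_min: float = 45.0, rest_min: float = 15.0,
                     fs: int = 496) -> ProtocolSpec:
    """Rest, one continuous driving (stress) block, rest."""
    if rest_min < 15.0:
        raise ValidationError("driving protocol requires >= 15 min rest "
                              "before and after the stress block")
    return ProtocolSpec(
        name="driving",
        segments=(("rest", rest_min * 60.0), ("stress", stress_min * 60.0),
                  ("rest", rest_min * 60.0)),
        fs=fs)


@dataclass
class SyntheticCohort:
    records: list[EcgRecord]
    cohort_seed: int
    protocol: ProtocolSpec


# -- beat timing -----------------------------------------------------------


def simulate_rr_series(params: BeatParams, duration: float,
                       seed: int | np.random.Generator) -> np.ndarray:
    """RR intervals (s) whose cumulative sum just reaches ``duration``.

    Total RR variance splits between white Gaussian jitter and a
    sinusoidal respiratory component so the sample SD tracks ``sdnn``.
    """
    if duration <= 0:
        raise ValidationError("duration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    mean_rr = 60.0 / params.mean_hr
    sd = params.sdnn / 1000.0
    resp_amp = 0.5 * sd                      # variance a^2/2 from the sine
    white_sd = np.sqrt(max(sd ** 2 - resp_amp ** 2 / 2.0, 0.0))
    rr: list[float] = []
    t = 0.0
    floor_rr = max(0.2, mean_rr - 4.0 * sd) if sd > 0 else mean_rr
    while t < duration:
        x = mean_rr \
            + resp_amp * np.sin(2.0 * np.pi * params.respiratory_mod_hz * t) \
            + (white_sd * rng.standard_normal() if sd > 0 else 0.0)
        x = max(x, floor_rr)
        rr.append(x)
        t += x
    out = np.asarray(rr)
    if sd > 0:
        # beats sample the respiratory sine non-uniformly (long intervals
        # under-sampled), biasing the realized rate; rescale so the mean
        # RR is exactly nominal, then re-apply the stopping rule so the
        # beat count is rate-faithful as well
        out = out * (mean_rr / out.mean())
        while out.sum() < duration:
            out = np.append(out, mean_rr)
        cum = np.cumsum(out)
        out = out[:int(np.searchsorted(cum, duration - 1e-12) + 1)]
    return out


# P, Q, R, S, T as (amplitude, offset from R time in s, width in s);
# amplitudes are relative to BeatParams.amplitude_mv
_TEMPLATE = (
    (0.12, -0.22, 0.050),
    (-0.10, -0.030, 0.012),
    (1.00, 0.0, 0.018),
    (-0.15, 0.035, 0.014),
    (0.30, 0.25, 0.070),
)


def synthesize_ecg(rr: np.ndarray, fs: float, params: BeatParams,
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample vector (mV) for a beat train: template at each R time + noise.

    The R time of beat ``k`` sits at the centre of its RR interval, so a
    single 1 s interval yields one QRS apex near 0.5 s.
    """
    if fs <= 0:
        raise ValidationError("fs must be > 0")
    rr = np.asarray(rr, float)
    if rr.size == 0:
        return np.zeros(0)
    if np.any(rr <= 0):
        raise ValidationError("RR intervals must be positive")
    total = float(rr.sum())
    n = int(round(total * fs))
    t_beats = np.cumsum(rr) - rr / 2.0
    signal = np.zeros(n)
    half = 0.6  # template support half-width, s
    for tb in t_beats:
        lo = max(int(np.floor((tb - half) * fs)), 0)
        hi = min(int(np.ceil((tb + half) * fs)) + 1, n)
        if lo >= hi:
            continue
        tt = np.arange(lo, hi) / fs - tb
        seg = np.zeros(hi - lo)
        for amp, mu, width in _TEMPLATE:
            seg += amp * np.exp(-0.5 * ((tt - mu) / width) ** 2)
        signal[lo:hi] += params.amplitude_mv * seg
    if params.noise_sd_mv > 0:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, params.noise_sd_mv, size=n)
    return signal


def count_r_peaks(signal: np.ndarray, fs: float,
                  threshold_frac: float = 0.6,
                  refractory_s: float = 0.2) -> int:
    """Count local maxima above a relative threshold (rate oracle)."""
    x = np.asarray(signal, float)
    if x.size < 3:
        return 0
    thr = threshold_frac * np.max(x)
    is_peak = (x[1:-1] >= x[:-2]) & (x[1:-1] > x[2:]) & (x[1:-1] > thr)
    idx = np.flatnonzero(is_peak) + 1
    if idx.size == 0:
        return 0
    min_gap = int(refractory_s * fs)
    kept = [idx[0]]
    for i in idx[1:]:
        if i - kept[-1] >= min_gap:
            kept.append(i)
    return len(kept)


def estimate_mean_hr(window: np.ndarray, fs: float) -> float:
    """Mean heart rate (bpm) of a window via threshold peak counting."""
    n = count_r_peaks(window, fs)
    return 60.0 * n / (len(window) / fs)


# -- cohorts ---------------------------------------------------------------


def _jitter(params: BeatParams, rng: np.random.Generator,
            frac: float = 0.10) -> BeatParams:
    """Per-subject +/-10% uniform jitter on mean_hr and sdnn."""
    return replace(params,
                   mean_hr=params.mean_hr * (1 + rng.uniform(-frac, frac)),
                   sdnn=params.sdnn * (1 + rng.uniform(-frac, frac)))


def simulate_record(protocol: ProtocolSpec, subject_id: str,
                    rest_params: BeatParams, stress_params: BeatParams,
                    seed: np.random.SeedSequence) -> EcgRecord:
    rng = np.random.default_rng(seed)
    cond_params = {"rest": _jitter(rest_params, rng),
                   "stress": _jitter(stress_params, rng)}
    fs = protocol.fs
    chunks = []
    markers = []
    t0 = 0.0
    for cond, dur in protocol.segments:
        p = cond_params[cond]
        rr = simulate_rr_series(p, dur, rng)
        seg = synthesize_ecg(rr, fs, p, rng)
        n_target = int(round(dur * fs))
        if seg.size >= n_target:
            seg = seg[:n_target]
        else:  # pad with trailing noise floor (never expected in practice)
            seg = np.pad(seg, (0, n_target - seg.size))
        chunks.append(seg)
        label = "rest" if cond == "rest" else (
            "stress_task" if protocol.stressor == "mental_arithmetic"
            else "stress_highway")
        markers.append(Marker(label, t0, t0 + dur))
        t0 += dur
    return EcgRecord(subject_id=subject_id,
                     samples=np.concatenate(chunks),
                     fs=fs,
                     markers=markers,
                     stressor=protocol.stressor)


def simulate_cohort(protocol: ProtocolSpec, n_subjects: int,
                    rest_params: BeatParams = REST_PARAMS,
                    stress_params: BeatParams = STRESS_PARAMS,
                    cohort_seed: int = 0) -> SyntheticCohort:
    """One record per subject; per-subject seeds spawned from the cohort seed."""
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    root = np.random.SeedSequence(cohort_seed)
    subject_seeds = root.spawn(n_subjects)
    records = [
        simulate_record(protocol, f"S{i:03d}", rest_params, stress_params,
                        subject_seeds[i])
        for i in range(n_subjects)
    ]
    return SyntheticCohort(records=records, cohort_seed=cohort_seed,
                           protocol=protocol)
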
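"""Seeded synthetic-data generators: tachograms, rendered ECGs and
two-class patient cohorts.

These generators make the full pipeline testable without any recorded
patient data:

* :func:`make_tachogram` — an NN-interval series with controllable LF/HF
  sinusoidal modulation, Gaussian jitter, premature ectopic beats and
  artifact spans, plus the ground truth needed to score detectors.
* :func:`render_ecg` — places a QRS-like template at each beat time on top
  of baseline wander and white noise, producing a single-lead ECG at a
  defibrillator-monitor-like 125 Hz.
* :func:`make_cohort` — class-conditional Gaussian feature matrices whose
  per-class means/SDs default to the published case-mix of a critically
  ill ED cohort (event prevalence 4.6%), in the exact order of the
  model's feature vector.

Every generator is a pure function of its spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ecg import ARTIFACT, ECTOPIC, SINUS, BeatAnnotations, EcgRecord, RrSeries
from .mlscore import FEATURE_NAMES


class SpecError(ValueError):
    """Raised when a generator spec violates its invariants."""


# ----------------------------------------------------------------------
# tachograms
# ----------------------------------------------------------------------

@dataclass
class TachogramSpec:
    """Two-sinusoid + jitter model of a sinus-rhythm tachogram.

    NN(t) = mean_rr + lf_amp sin(2π lf_freq t) + hf_amp sin(2π hf_freq t)
    + N(0, jitter_sd). Defaults give a 0.8 s mean interval with mixed
    0.1 Hz / 0.25 Hz modulation, typical of a resting short-term recording.
    """

    duration_s: float = 300.0
    mean_rr_s: float = 0.8
    lf_amp_s: float = 0.03
    lf_freq_hz: float = 0.1
    hf_amp_s: float = 0.03
    hf_freq_hz: float = 0.25
    jitter_sd_s: float = 0.005
    ectopic_prob: float = 0.0
    artifact_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lf_amp_s < 0 or self.hf_amp_s < 0 or self.jitter_sd_s < 0:
            raise SpecError("amplitudes must be non-negative")
        if self.mean_rr_s - (self.lf_amp_s + self.hf_amp_s) <= 0.25:
            raise SpecError("mean_rr minus total modulation must exceed 0.25 s")
        if not (0 <= self.ectopic_prob <= 1 and 0 <= self.artifact_fraction <= 1):
            raise SpecError("ectopic_prob and artifact_fraction must lie in [0, 1]")
        if self.duration_s <= 0:
            raise SpecError("duration must be positive")


@dataclass
class TachogramTruth:
    """Ground truth accompanying a generated tachogram."""

    beat_times: np.ndarray              # all beat times incl. ectopics (s)
    beat_labels: list[str]              # sinus/ectopic per beat
    artifact_spans: list[tuple[float, float]]
    spec: TachogramSpec


def make_tachogram(spec: TachogramSpec) -> tuple[RrSeries, TachogramTruth]:
    """Generate an NN series plus ground-truth annotations.

    The returned :class:`RrSeries` contains the *clean* sinus-to-sinus
    intervals only (what a perfect preprocessor would deliver); ectopic
    insertions and artifact spans live in the truth object so detector
    tests can compare against them.
    """
    rng = np.random.default_rng(spec.seed)
    times = []
    t = 0.0
    while True:
        nn = (spec.mean_rr_s
              + spec.lf_amp_s * np.sin(2 * np.pi * spec.lf_freq_hz * t)
              + spec.hf_amp_s * np.sin(2 * np.pi * spec.hf_freq_hz * t)
              + rng.normal(0.0, spec.jitter_sd_s))
        nn = max(nn, 0.25)
        if t + nn > spec.duration_s:
            break
        t += nn
        times.append(t)
    times = np.asarray(times)

    labels = [SINUS] * times.size
    if spec.ectopic_prob > 0 and times.size > 2:
        # a premature ectopic splits an RR interval at ~55% prematurity
        out_t, out_l = [], []
        for i, bt in enumerate(times):
            out_t.append(bt)
            out_l.append(SINUS)
            if i + 1 < times.size and rng.random() < spec.ectopic_prob:
                out_t.append(bt + 0.45 * (times[i + 1] - bt))
                out_l.append(ECTOPIC)
        times = np.asarray(out_t)
        labels = out_l

    artifact_spans: list[tuple[float, float]] = []
    if spec.artifact_fraction > 0:
        span_len = 5.0
        n_spans = max(1, int(round(spec.artifact_fraction * spec.duration_s / span_len)))
        total_bad = spec.artifact_fraction * spec.duration_s
        span_len = total_bad / n_spans
        starts = rng.uniform(0, spec.duration_s - span_len, size=n_spans)
        artifact_spans = sorted((s, s + span_len) for s in starts)

    # clean NN series: consecutive sinus pairs outside artifact spans
    nn_t, nn_v = [], []
    for i in range(1, times.size):
        if labels[i] != SINUS or labels[i - 1] != SINUS:
            continue
        if any(s <= times[i] <= e or s <= times[i - 1] <= e for s, e in artifact_spans):
            continue
        nn_t.append(times[i])
        nn_v.append(times[i] - times[i - 1])
    rr = RrSeries(np.asarray(nn_t), np.asarray(nn_v))
    return rr, TachogramTruth(times, labels, artifact_spans, spec)


# ----------------------------------------------------------------------
# ECG rendering
# ----------------------------------------------------------------------

def qrs_template(fs: float, width_s: float = 0.08, amplitude: float = 1.0) -> np.ndarray:
    """Biphasic QRS-like template: a Mexican-hat (negative second
    derivative of a Gaussian) of total width ``width_s``."""
    half = int(round(width_s * fs / 2))
    t = np.arange(-half, half + 1) / fs
    sigma = width_s / 6.0
    u = (t / sigma) ** 2
    w = (1 - u) * np.exp(-u / 2)
    return amplitude * w / np.abs(w).max()


def render_ecg(rr: RrSeries, fs: float = 125.0, snr_db: float = np.inf,
               template: np.ndarray | None = None, duration_s: float | None = None,
               baseline_amp: float = 0.1, baseline_freq_hz: float = 0.3,
               seed: int = 0, ectopic_times: np.ndarray | None = None,
               ectopic_scale: float = 2.0) -> tuple[EcgRecord, np.ndarray]:
    """Render an ECG waveform from beat times.

    A QRS template is placed at each cumulative beat time of ``rr`` (and,
    doubled in amplitude and width, at each ``ectopic_times`` entry), on
    top of a slow sinusoidal baseline wander; white Gaussian noise is added
    to reach ``snr_db`` relative to the clean signal power. An empty series
    renders a flatline of ``duration_s``.

    Returns ``(record, truth_beat_times)`` where the truth includes the
    ectopic beats, sorted.

    Raises
    ------
    SpecError
        If fs < 100 Hz or the template is longer than the shortest RR.
    """
    if fs < 100:
        raise SpecError("rendering needs fs >= 100 Hz")
    if template is None:
        template = qrs_template(fs)
    beat_times = rr.times if len(rr) else np.empty(0)
    if len(rr) and template.size >= rr.intervals.min() * fs:
        raise SpecError("QRS template longer than the shortest RR interval")
    if duration_s is None:
        duration_s = (beat_times[-1] + 1.0) if beat_times.size else 10.0
    n = int(round(duration_s * fs))
    x = np.zeros(n)

    def _place(center_s: float, tmpl: np.ndarray) -> None:
        c = int(round(center_s * fs))
        half = tmpl.size // 2
        lo, hi = c - half, c - half + tmpl.size
        s_lo, s_hi = max(0, lo), min(n, hi)
        if s_hi > s_lo:
            x[s_lo:s_hi] += tmpl[s_lo - lo:s_hi - lo]

    for bt in beat_times:
        _place(bt, template)
    truth = list(beat_times)
    if ectopic_times is not None:
        wide = qrs_template(fs, width_s=0.16, amplitude=ectopic_scale)
        for et in ectopic_times:
            _place(et, wide)
            truth.append(float(et))

    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    clean_power = float(np.mean(x**2)) if np.any(x) else 0.0
    x = x + baseline_amp * np.sin(2 * np.pi * baseline_freq_hz * t)
    if np.isfinite(snr_db) and clean_power > 0:
        noise_power = clean_power / (10 ** (snr_db / 10))
        x = x + rng.normal(0.0, np.sqrt(noise_power), size=n)
    rec = EcgRecord(x, fs=fs, lead="II", record_id=f"synthetic-seed{seed}")
    return rec, np.asarray(sorted(truth))


# ----------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------

# Class-conditional means/SDs (negative = no event, positive = event within
# 72 h) patterned on a published critically ill ED cohort; units follow the
# feature-vector convention (intervals in s, powers in s^2, rates per min).
COHORT_ARREST_MOMENTS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    # feature: ((mean_neg, sd_neg), (mean_pos, sd_pos))
    "age": ((61.0, 16.0), (66.0, 16.0)),
    "heart_rate": ((96.0, 30.0), (106.0, 25.0)),
    "resp_rate": ((19.0, 5.0), (20.0, 5.0)),
    "sbp": ((136.0, 38.0), (125.0, 34.0)),
    "dbp": ((77.0, 22.0), (75.0, 20.0)),
    "spo2": ((96.0, 6.0), (93.0, 13.0)),
    "temperature": ((37.0, 1.0), (37.0, 1.0)),
    # GCS is reported as median (IQR) 15 (15-15) vs 15 (11-15); Gaussian
    # approximation chosen to reflect the heavier low tail among events.
    "gcs": ((14.6, 1.2), (13.0, 3.0)),
    "aRR": ((0.718, 0.177), (0.621, 0.149)),
    "STD": ((0.053, 0.033), (0.057, 0.047)),
    "avHR": ((89.004, 20.566), (102.692, 22.136)),
    "sdHR": ((6.463, 3.740), (8.152, 5.531)),
    "RMSSD": ((0.039, 0.041), (0.048, 0.054)),
    "nn50": ((571.0, 1268.0), (484.0, 748.0)),
    "pnn50": ((7.048, 12.268), (6.561, 9.667)),
    "tri_index": ((2.475, 1.000), (2.046, 0.736)),
    "TINN": ((0.217, 0.130), (0.189, 0.148)),
    "vlf_power": ((0.131, 0.102), (0.099, 0.084)),
    "lf_power": ((0.057, 0.042), (0.056, 0.045)),
    "hf_power": ((0.080, 0.070), (0.103, 0.083)),
    "total_power": ((0.268, 0.135), (0.259, 0.131)),
    "lf_norm": ((45.430, 18.489), (36.459, 15.798)),
    "hf_norm": ((54.566, 18.487), (63.541, 15.798)),
    "lf_hf_ratio": ((1.205, 1.284), (0.802, 1.171)),
}

#: Study-scale cohort defaults: 925 patients, 4.6% event prevalence.
DEFAULT_COHORT_N = 925
DEFAULT_PREVALENCE = 0.046


@dataclass
class CohortSpec:
    """Two-class Gaussian cohort model.

    ``moments`` maps each feature name to ``((mean_neg, sd_neg),
    (mean_pos, sd_pos))``; features absent from the map are drawn from
    N(0, 1) in both classes. ``correlated=True`` adds an equicorrelation
    (rho = 0.3) structure within each class instead of independent draws.
    """

    n: int = DEFAULT_COHORT_N
    prevalence: float = DEFAULT_PREVALENCE
    moments: dict[str, tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=lambda: dict(COHORT_ARREST_MOMENTS))
    correlated: bool = False
    rho: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise SpecError("prevalence must lie in (0, 1)")
        if self.n < 4 or self.n * self.prevalence < 2 or self.n * (1 - self.prevalence) < 2:
            raise SpecError("cohort too small to contain both classes")
        for name, ((m0, s0), (m1, s1)) in self.moments.items():
            if s0 <= 0 or s1 <= 0:
                raise SpecError(f"SDs must be positive for {name}")


def make_cohort(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``(X, y)``: features in :data:`FEATURE_NAMES` order and binary
    outcomes at the configured prevalence (expected count rounded, at least
    2 per class, assigned to a random subset)."""
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n * spec.prevalence))
    n_pos = min(max(n_pos, 2), spec.n - 2)
    y = np.zeros(spec.n, dtype=int)
    y[rng.choice(spec.n, size=n_pos, replace=False)] = 1

    d = len(FEATURE_NAMES)
    if spec.correlated:
        cov = np.full((d, d), spec.rho) + (1 - spec.rho) * np.eye(d)
        z = rng.multivariate_normal(np.zeros(d), cov, size=spec.n,
                                    method="cholesky")
    else:
        z = rng.normal(size=(spec.n, d))
    X = np.empty((spec.n, d))
    for j, name in enumerate(FEATURE_NAMES):
        (m0, s0), (m1, s1) = spec.moments.get(name, ((0.0, 1.0), (0.0, 1.0)))
        mean = np.where(y == 1, m1, m0)
        sd = np.where(y == 1, s1, s0)
        X[:, j] = mean + sd * z[:, j]
    return X, y


def null_cohort(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Same marginal structure but identical class means/SDs (pooled to the
    negative-class moments): no signal, for null calibration."""
    flat = {k: (v[0], v[0]) for k, v in spec.moments.items()}
    return make_cohort(replace(spec, moments=flat))
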
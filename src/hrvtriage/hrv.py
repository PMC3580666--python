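"""Short-term HRV parameters from an NN-interval tachogram.

Covers the standard short-term battery: time-domain statistics (aRR, STD,
avHR, sdHR, RMSSD, nn50, pnn50), geometric measures from the NN histogram
(RR triangular index, TINN) and frequency-domain band powers estimated with
the Lomb–Scargle periodogram, which handles the unevenly sampled tachogram
directly without interpolation or resampling.

All interval quantities are in seconds; band powers are in s^2 (the squared
unit of the interval series); normalized powers are in normalized units (nu)
on a 0–100 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy import signal as sps

from .ecg import RrSeries

# Conventional short-term frequency bands (Hz).
VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

#: Default Lomb-Scargle evaluation grid: 0.003-0.4 Hz in 1 mHz steps.
DEFAULT_FREQ_GRID = np.arange(0.003, 0.4 + 1e-12, 0.001)

#: Conventional NN-histogram bin width, 1/128 s.
DEFAULT_BIN_WIDTH_S = 1.0 / 128.0

#: Threshold defining nn50/pnn50 (seconds).
NN50_THRESHOLD_S = 0.050


class InsufficientDataError(ValueError):
    """Raised when a series is too short for the requested statistic."""


@dataclass
class HrvFeatures:
    """The full HRV parameter vector for one recording.

    Fields left at ``nan`` are undefined for the input (e.g. normalized
    powers of a constant tachogram).
    """

    aRR: float = math.nan            # mean NN interval (s)
    STD: float = math.nan            # SD of NN (s), n-1 denominator
    avHR: float = math.nan           # mean instantaneous heart rate (beats/min)
    sdHR: float = math.nan           # SD of instantaneous heart rate (beats/min)
    RMSSD: float = math.nan          # RMS of successive NN differences (s)
    nn50: float = math.nan           # count of successive diffs > 50 ms
    pnn50: float = math.nan          # percentage of successive diffs > 50 ms
    tri_index: float = math.nan      # total NN count / modal histogram bin
    TINN: float = math.nan           # triangular-fit base width (s)
    vlf_power: float = math.nan      # 0.003-0.04 Hz band power (s^2)
    lf_power: float = math.nan      # 0.04-0.15 Hz band power (s^2)
    hf_power: float = math.nan      # 0.15-0.40 Hz band power (s^2)
    total_power: float = math.nan    # VLF+LF+HF (s^2)
    lf_norm: float = math.nan        # 100*LF/(LF+HF) (nu)
    hf_norm: float = math.nan        # 100*HF/(LF+HF) (nu)
    lf_hf_ratio: float = math.nan    # LF/HF

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def feature_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


def time_domain(rr: RrSeries) -> HrvFeatures:
    """Time-domain statistics of the NN series.

    Raises
    ------
    InsufficientDataError
        With fewer than two intervals.
    """
    nn = rr.intervals
    if nn.size < 2:
        raise InsufficientDataError("time-domain HRV needs at least 2 intervals")
    hr = 60.0 / nn
    diffs = np.diff(nn)
    nn50 = int(np.sum(np.abs(diffs) > NN50_THRESHOLD_S))
    return HrvFeatures(
        aRR=float(np.mean(nn)),
        STD=float(np.std(nn, ddof=1)),
        avHR=float(np.mean(hr)),
        sdHR=float(np.std(hr, ddof=1)),
        RMSSD=float(np.sqrt(np.mean(diffs**2))),
        nn50=nn50,
        pnn50=100.0 * nn50 / diffs.size,
    )


def _nn_histogram(nn: np.ndarray, bin_width_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of NN on a fixed grid of ``bin_width_s`` bins aligned to 0."""
    lo = math.floor(nn.min() / bin_width_s)
    hi = math.floor(nn.max() / bin_width_s) + 1
    edges = np.arange(lo, hi + 1) * bin_width_s
    counts, _ = np.histogram(nn, bins=edges)
    return counts.astype(float), edges


def triangular_fit(counts: np.ndarray, edges: np.ndarray) -> tuple[float, float, float]:
    """Best least-squares triangular fit to an NN histogram.

    Searches all pairs of bin edges (N_base, M_base) bracketing the modal
    bin for the triangle (zero at both base endpoints, peak at the modal
    bin centre with the modal height) minimising the squared error against
    the histogram, counting the zero bins the triangle implies outside its
    base. Returns ``(n_edge, m_edge, base_width)``.
    """
    k = int(np.argmax(counts))
    peak_x = 0.5 * (edges[k] + edges[k + 1])
    peak_y = counts[k]
    best = (edges[0], edges[-1], math.inf)
    centers = 0.5 * (edges[:-1] + edges[1:])
    for i in range(0, k + 1):          # left base endpoint edge index
        for j in range(k + 1, edges.size):  # right base endpoint edge index
            n_edge, m_edge = edges[i], edges[j]
            tri = np.zeros_like(counts)
            left = (centers >= n_edge) & (centers <= peak_x)
            right = (centers > peak_x) & (centers <= m_edge)
            if peak_x > n_edge:
                tri[left] = peak_y * (centers[left] - n_edge) / (peak_x - n_edge)
            else:
                tri[left] = peak_y
            if m_edge > peak_x:
                tri[right] = peak_y * (m_edge - centers[right]) / (m_edge - peak_x)
            err = float(np.sum((counts - tri) ** 2))
            if err < best[2]:
                best = (n_edge, m_edge, err)
    n_edge, m_edge, _err = best
    return float(n_edge), float(m_edge), float(m_edge - n_edge)


def geometric(rr: RrSeries, bin_width_s: float = DEFAULT_BIN_WIDTH_S,
              min_intervals: int = 20) -> HrvFeatures:
    """Geometric HRV measures from the NN histogram.

    * RR triangular index: total interval count divided by the modal bin
      count of the histogram (fixed ``bin_width_s`` bins).
    * TINN: base width (s) of the best least-squares triangular
      interpolation of the histogram.

    Raises
    ------
    InsufficientDataError
        With fewer than ``min_intervals`` intervals the histogram is not
        meaningful.
    """
    nn = rr.intervals
    if nn.size == 0:
        raise InsufficientDataError("geometric HRV needs a non-empty series")
    if nn.size < min_intervals:
        raise InsufficientDataError(
            f"geometric HRV needs >= {min_intervals} intervals, got {nn.size}")
    counts, edges = _nn_histogram(nn, bin_width_s)
    tri_index = nn.size / counts.max()
    if np.count_nonzero(counts) == 1:
        tinn = 0.0
    else:
        n_edge, m_edge, _ = triangular_fit(counts, edges)
        tinn = m_edge - n_edge
    return HrvFeatures(tri_index=float(tri_index), TINN=float(tinn))


def lomb_scargle_psd(rr: RrSeries, freqs: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Lomb–Scargle power spectral density of the NN series.

    The periodogram is evaluated on ``freqs`` (Hz; default 0.003–0.4 Hz in
    1 mHz steps) for the mean-subtracted NN values at their actual beat
    times. The raw periodogram ``P`` is scaled by ``2 * t_span / n`` so that
    trapezoidal integration over a band approximates that band's
    contribution to the series variance (for a sinusoidal modulation of
    amplitude A, the integrated peak recovers ~A^2/2).

    Returns ``(freqs, psd)``.

    Raises
    ------
    InsufficientDataError
        With fewer than 10 intervals.
    ValueError
        If beat times are not strictly increasing (enforced by
        :class:`RrSeries`) or the grid leaves (0, 0.5] Hz.
    """
    if freqs is None:
        freqs = DEFAULT_FREQ_GRID
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs > 0.5):
        raise ValueError("frequency grid must lie in (0, 0.5] Hz")
    if len(rr) < 10:
        raise InsufficientDataError("Lomb-Scargle PSD needs at least 10 intervals")
    t = rr.times
    x = rr.intervals - rr.intervals.mean()
    if np.allclose(x, 0.0):
        return freqs, np.zeros_like(freqs)
    t_span = t[-1] - t[0]
    pgram = sps.lombscargle(t, x, 2.0 * np.pi * freqs)
    psd = pgram * 2.0 * t_span / x.size
    return freqs, psd


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    m = (freqs >= band[0]) & (freqs <= band[1])
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[m], freqs[m]))


def frequency_domain(rr: RrSeries, freqs: np.ndarray | None = None) -> HrvFeatures:
    """Band powers and normalized powers from the Lomb–Scargle PSD.

    VLF 0.003–0.04 Hz, LF 0.04–0.15 Hz, HF 0.15–0.40 Hz; total power is
    their sum. Normalized powers are 100·LF/(LF+HF) and 100·HF/(LF+HF); they
    and the LF/HF ratio are reported as ``nan`` when LF+HF is zero.
    """
    f, psd = lomb_scargle_psd(rr, freqs)
    vlf = _band_power(f, psd, VLF_BAND)
    lf = _band_power(f, psd, LF_BAND)
    hf = _band_power(f, psd, HF_BAND)
    out = HrvFeatures(vlf_power=vlf, lf_power=lf, hf_power=hf,
                      total_power=vlf + lf + hf)
    if lf + hf > 0:
        out.lf_norm = 100.0 * lf / (lf + hf)
        out.hf_norm = 100.0 * hf / (lf + hf)
        out.lf_hf_ratio = lf / hf if hf > 0 else math.inf
    return out


def compute_all(rr: RrSeries, bin_width_s: float = DEFAULT_BIN_WIDTH_S,
                freqs: np.ndarray | None = None) -> HrvFeatures:
    """Assemble the full HRV vector; undefined sub-blocks stay ``nan``.

    Time-domain statistics require >= 2 intervals (an error below that);
    geometric and frequency-domain blocks are filled only when their own
    preconditions hold, otherwise left missing.
    """
    out = time_domain(rr)
    try:
        geo = geometric(rr, bin_width_s)
        out.tri_index, out.TINN = geo.tri_index, geo.TINN
    except InsufficientDataError:
        pass
    try:
        fd = frequency_domain(rr, freqs)
    except InsufficientDataError:
        return out
    for name in ("vlf_power", "lf_power", "hf_power", "total_power",
                 "lf_norm", "hf_norm", "lf_hf_ratio"):
        setattr(out, name, getattr(fd, name))
    return out
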
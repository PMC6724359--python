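"""QRS detection, heart-rate and respiratory-rate estimation, and SNR scoring.

The detector is a Pan-Tompkins variant: 5-15 Hz band-pass, differentiation,
squaring, 150 ms moving-window integration, adaptive dual thresholds with
search-back and a 200 ms refractory period.  HR comes from cubic
interpolation of the instantaneous 60/RR-interval series; RR (respiratory
rate) is ECG-derived respiration read from the dominant spectral peak of the
band-passed R-amplitude series over sliding 30 s windows.

SNR follows the wearable-ECG convention: per 8 s window, the mean QRS
peak-to-trough amplitude versus the mean absolute amplitude of the residual
left after removing beats and median-filtering (99-sample kernel), as
``SNR_dB = 10 log10((A_signal / A_noise)^2)``, averaged over windows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig
from scipy.interpolate import CubicSpline, interp1d

from .signal_io import EcgRecord

__all__ = [
    "BeatEvent",
    "VitalsSeries",
    "SnrReport",
    "detect_qrs",
    "estimate_hr",
    "estimate_rr",
    "snr",
    "snr_db",
]

log = logging.getLogger(__name__)

REFRACTORY_S = 0.200
QRS_HALFWIDTH_S = 0.060


@dataclass
class BeatEvent:
    """A detected R-peak."""

    index: int
    time_s: float
    amp: float  # peak-to-trough amplitude of the complex, mV
    cls: str | None = None


@dataclass
class VitalsSeries:
    """Uniformly gridded vital-sign series (hr in bpm, rr in breaths/min)."""

    t: np.ndarray
    hr: np.ndarray | None = None
    rr: np.ndarray | None = None


@dataclass
class SnrReport:
    per_window_db: list[float]
    mean_db: float
    a_signal: float
    a_noise: float


def snr_db(a_signal: float, a_noise: float) -> float:
    """``10 log10((A_signal/A_noise)^2)``."""
    return 10.0 * np.log10((a_signal / a_noise) ** 2)


# ---------------------------------------------------------------------------
# QRS detection
# ---------------------------------------------------------------------------

def _bandpass(x: np.ndarray, fs: float, lo: float = 5.0, hi: float = 15.0):
    nyq = fs / 2.0
    hi = min(hi, 0.95 * nyq)
    sos = _sig.butter(2, [lo / nyq, hi / nyq], btype="band", output="sos")
    return _sig.sosfiltfilt(sos, x)


def _peak_to_trough(x: np.ndarray, idx: int, half: int) -> float:
    seg = x[max(0, idx - half): idx + half + 1]
    return float(seg.max() - seg.min())


def detect_qrs(rec: EcgRecord) -> list[BeatEvent]:
    """Detect QRS complexes; returns R-peak events in time order.

    Requires fs >= 100 Hz and at least 2 s of signal.  A flatline input
    yields an empty list with a warning.
    """
    fs = rec.fs
    if fs < 100:
        raise ValueError("detect_qrs requires fs >= 100 Hz")
    x = rec.samples
    if len(x) < 2 * fs:
        raise ValueError("detect_qrs requires at least 2 s of signal")
    if np.ptp(x) < 1e-12:
        warnings.warn("flatline input; no beats detected")
        return []

    bp = _bandpass(x, fs)
    deriv = np.gradient(bp) * fs
    sq = deriv ** 2
    mwi_len = max(int(round(0.150 * fs)), 1)
    kernel = np.ones(mwi_len) / mwi_len
    mwi = np.convolve(sq, kernel, mode="same")

    refr = int(round(REFRACTORY_S * fs))
    peaks, _ = _sig.find_peaks(mwi, distance=refr)
    if len(peaks) == 0:
        warnings.warn("no integrated peaks found")
        return []

    # adaptive dual thresholds (Pan-Tompkins running estimates)
    spki = float(np.max(mwi[: int(2 * fs)])) * 0.5
    npki = float(np.mean(mwi[: int(2 * fs)])) * 0.5
    accepted: list[int] = []
    rr_hist: list[float] = []

    def threshold1():
        return npki + 0.25 * (spki - npki)

    i = 0
    while i < len(peaks):
        p = peaks[i]
        a = mwi[p]
        if a > threshold1():
            if accepted and (p - accepted[-1]) < refr:
                if a > mwi[accepted[-1]]:
                    accepted[-1] = p
            else:
                if accepted:
                    rr_hist.append((p - accepted[-1]) / fs)
                    rr_hist[:] = rr_hist[-8:]
                accepted.append(p)
            spki = 0.125 * a + 0.875 * spki
        else:
            npki = 0.125 * a + 0.875 * npki
            # search-back: if too long since the last beat, accept the
            # largest missed peak above half threshold
            if accepted and rr_hist:
                rr_avg = float(np.mean(rr_hist))
                if (p - accepted[-1]) / fs > 1.66 * rr_avg:
                    window = [q for q in peaks
                              if accepted[-1] + refr <= q <= p
                              and mwi[q] > 0.5 * threshold1()]
                    if window:
                        best = max(window, key=lambda q: mwi[q])
                        rr_hist.append((best - accepted[-1]) / fs)
                        rr_hist[:] = rr_hist[-8:]
                        accepted.append(best)
                        spki = 0.25 * mwi[best] + 0.75 * spki
        i += 1

    # refine each event to the R-peak of the band-passed signal within
    # +-40 ms of the integrated peak
    search = int(round(0.040 * fs))
    half = int(round(QRS_HALFWIDTH_S * fs))
    events: list[BeatEvent] = []
    for p in accepted:
        lo, hi = max(0, p - search), min(len(x), p + search + 1)
        r = lo + int(np.argmax(np.abs(bp[lo:hi])))
        if events and (r - events[-1].index) < refr:
            continue
        events.append(BeatEvent(index=r, time_s=r / fs,
                                amp=_peak_to_trough(x, r, half)))
    return events


# ---------------------------------------------------------------------------
# HR estimation
# ---------------------------------------------------------------------------

def estimate_hr(beats: list[BeatEvent], grid_hz: float = 4.0) -> VitalsSeries:
    """Instantaneous HR from R-R intervals, cubic-interpolated to a uniform grid.

    HR(t) = 60/RR is assigned at interval midpoints and clamped to (0, 300).
    Requires at least three beats.
    """
    if len(beats) < 3:
        raise ValueError("insufficient beats (need >= 3)")
    t_beats = np.array([b.time_s for b in beats])
    rr = np.diff(t_beats)
    mid = t_beats[:-1] + rr / 2.0
    inst = 60.0 / rr
    grid = np.arange(mid[0], mid[-1], 1.0 / grid_hz)
    hr = CubicSpline(mid, inst)(grid)
    return VitalsSeries(t=grid, hr=np.clip(hr, 1e-9, 300.0))


# ---------------------------------------------------------------------------
# RR (respiratory rate) estimation
# ---------------------------------------------------------------------------

RR_BAND_HZ = (0.066, 0.7)  # 4 - 42 breaths per minute


def _dominant_freq(seg: np.ndarray, fs: float, prev_hz: float | None):
    """Dominant spectral frequency inside the respiratory band, with
    parabolic sub-bin refinement; ties (within 10% power) broken toward the
    previous window's estimate.  Returns (freq, peak/floor power ratio)."""
    n = len(seg)
    nfft = max(4096, 1 << int(np.ceil(np.log2(n))))
    w = np.hanning(n)
    spec = np.abs(np.fft.rfft(seg * w, nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    band = (freqs >= RR_BAND_HZ[0]) & (freqs <= RR_BAND_HZ[1])
    bf, bs = freqs[band], spec[band]
    if len(bs) == 0 or bs.max() <= 0:
        return None, 0.0
    pk, _ = _sig.find_peaks(bs)
    if len(pk) == 0:
        pk = np.array([int(np.argmax(bs))])
    powers = bs[pk]
    best = pk[powers >= 0.9 * powers.max()]
    if prev_hz is not None and len(best) > 1:
        j = best[int(np.argmin(np.abs(bf[best] - prev_hz)))]
    else:
        j = pk[int(np.argmax(powers))]
    # parabolic interpolation on log power
    jg = np.flatnonzero(band)[j]
    if 0 < jg < len(spec) - 1 and spec[jg] > 0:
        y0, y1, y2 = np.log(spec[jg - 1] + 1e-300), np.log(spec[jg] + 1e-300), \
            np.log(spec[jg + 1] + 1e-300)
        denom = (y0 - 2 * y1 + y2)
        delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    f = freqs[jg] + delta * (freqs[1] - freqs[0])
    floor = float(np.median(bs)) + 1e-300
    return float(f), float(bs[j] / floor)


def estimate_rr(rec: EcgRecord, beats: list[BeatEvent], grid_hz: float = 4.0,
                win_s: float = 30.0, step_s: float = 5.0,
                min_peak_ratio: float = 20.0) -> VitalsSeries:
    """ECG-derived respiration from R-peak amplitude modulation.

    The beat amplitude series is interpolated to a uniform ``grid_hz`` grid,
    band-passed to 0.066-0.7 Hz (4-42 breaths/min), and the respiratory rate
    is read from the dominant spectral peak over a sliding ``win_s`` window.
    Windows without a credible peak (power below ``min_peak_ratio`` times the
    band median, e.g. with no amplitude modulation) report NaN.
    """
    if rec.duration_s < win_s:
        raise ValueError(f"need at least {win_s:.0f} s of signal")
    if len(beats) < 20:
        raise ValueError("too few beats for respiration estimation (need >= 20)")
    t_b = np.array([b.time_s for b in beats])
    a_b = np.array([b.amp for b in beats])
    grid = np.arange(t_b[0], t_b[-1], 1.0 / grid_hz)
    amp = interp1d(t_b, a_b, kind="cubic")(grid)
    amp = amp - np.mean(amp)
    nyq = grid_hz / 2.0
    sos = _sig.butter(2, [RR_BAND_HZ[0] / nyq, RR_BAND_HZ[1] / nyq],
                      btype="band", output="sos")
    edr = _sig.sosfiltfilt(sos, amp)

    L = int(win_s * grid_hz)
    step = max(int(step_s * grid_hz), 1)
    t_out, rr_out = [], []
    prev_hz: float | None = None
    for start in range(0, len(edr) - L + 1, step):
        seg = edr[start:start + L]
        f, ratio = _dominant_freq(seg, grid_hz, prev_hz)
        t_out.append(grid[start] + win_s)
        if f is None or ratio < min_peak_ratio:
            rr_out.append(np.nan)
        else:
            rr_out.append(60.0 * f)
            prev_hz = f
    return VitalsSeries(t=np.asarray(t_out), rr=np.asarray(rr_out))


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------

def snr(rec: EcgRecord, win_s: float = 8.0, median_order: int = 99) -> SnrReport:
    """Windowed signal-to-noise ratio of an ECG recording.

    Per 8 s window: detect QRS complexes; ``A_signal`` is their mean
    peak-to-trough amplitude.  The complexes are excised (linear bridge over
    +-100 ms) and a ``median_order``-sample median filter isolates the slow
    baseline; the residual is the noise, ``A_noise`` its mean absolute
    amplitude.  Window SNRs are averaged over the recording.
    """
    fs = rec.fs
    L = int(round(win_s * fs))
    if len(rec.samples) < L:
        raise ValueError("record shorter than one SNR window")
    kernel = median_order if median_order % 2 == 1 else median_order + 1
    per_db, sig_amps, noise_amps = [], [], []
    for start in range(0, len(rec.samples) - L + 1, L):
        xw = rec.samples[start:start + L].copy()
        win = EcgRecord(xw, fs=fs, lead=rec.lead)
        try:
            beats = detect_qrs(win)
        except ValueError:
            beats = []
        if not beats:
            log.info("SNR: window at %.1f s skipped (no detectable beats)",
                     start / fs)
            continue
        a_signal = float(np.mean([b.amp for b in beats]))
        # excise whole complexes (P through T) so only inter-beat noise is
        # scored; the excision span scales down at high heart rate
        rr_med = (float(np.median(np.diff([b.index for b in beats]))) / fs
                  if len(beats) > 1 else 60.0 / 70.0)
        pre = int(round(min(0.30, 0.35 * rr_med) * fs))
        post = int(round(min(0.50, 0.58 * rr_med) * fs))
        keep = np.ones(len(xw), dtype=bool)
        # beats just beyond the window edges were not detected here; their
        # P/T waves leak into the margins, so the margins are not scored
        keep[:post] = False
        keep[len(xw) - pre:] = False
        xpr = xw.copy()
        for b in beats:
            lo = max(0, b.index - pre)
            hi = min(len(xpr), b.index + post + 1)
            keep[lo:hi] = False
            # linear bridge keeps the median filter continuous across gaps;
            # endpoints are local medians so the bridge is noise-robust
            v_lo = float(np.median(xpr[max(0, lo - 9):lo + 1]))
            v_hi = float(np.median(xpr[hi - 1:hi + 9]))
            xpr[lo:hi] = np.linspace(v_lo, v_hi, hi - lo)
        if not keep.any():
            log.info("SNR: window at %.1f s skipped (no inter-beat samples)",
                     start / fs)
            continue
        baseline = _sig.medfilt(xpr, kernel_size=kernel)
        noise = (xw - baseline)[keep]
        a_noise = float(np.mean(np.abs(noise)))
        if a_noise <= 0:
            continue
        per_db.append(snr_db(a_signal, a_noise))
        sig_amps.append(a_signal)
        noise_amps.append(a_noise)
    if not per_db:
        raise ValueError("no window with detectable beats")
    return SnrReport(per_window_db=per_db, mean_db=float(np.mean(per_db)),
                     a_signal=float(np.mean(sig_amps)),
                     a_noise=float(np.mean(noise_amps)))
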
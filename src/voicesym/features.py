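"""Frame-wise acoustic feature extraction.

Implements the prosody and frequency features used to separate the symptom
groups: fundamental frequency, harmonics-to-noise ratio, local jitter and
shimmer, FFT band powers (0-500, 500-1000, 1000-4000 Hz), spectral centroid
and flux, energy RMS, the first five formants via linear prediction, and
mel-frequency cepstral coefficients.

Conventions
-----------
* Frames: 25 ms Hamming windows with a 10 ms hop unless stated otherwise;
  F0/HNR use 40 ms frames so the lowest search frequency (60 Hz) fits at
  least two periods.
* Unvoiced or invalid frames carry NaN; aggregation later treats NaN as
  missing rather than silently propagating it.
* Autocorrelation-based F0/HNR divide the frame autocorrelation by the
  window autocorrelation (Boersma's correction) so a perfectly periodic
  frame scores r ~ 1 despite the taper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import rfft

from .audio import AudioRecording, FrameSeries, frame_signal

F0_MIN_DEFAULT = 60.0
F0_MAX_DEFAULT = 400.0
VOICING_THRESHOLD = 0.45
OCTAVE_COST = 0.25
HNR_CEILING_DB = 40.0
PITCH_FRAME_LEN = 0.040
FRAME_LEN = 0.025
HOP = 0.010


# ---------------------------------------------------------------------------
# autocorrelation pitch engine (shared by estimate_f0 and hnr)
# ---------------------------------------------------------------------------

def _corrected_acf(frames: np.ndarray) -> np.ndarray:
    """Window-corrected normalized autocorrelation per frame (Boersma):
    r_x(tau)/r_x(0) divided by r_w(tau)/r_w(0) for the Hamming window."""
    n = frames.shape[1]
    win = np.hamming(n)
    fw = frames * win[None, :]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(fw, nfft, axis=1)
    acf = np.fft.irfft(np.abs(spec) ** 2, nfft, axis=1)[:, :n]
    wspec = np.fft.rfft(win, nfft)
    wacf = np.fft.irfft(np.abs(wspec) ** 2, nfft)[:n]
    norm = acf[:, :1].copy()
    norm[norm <= 0] = np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        return (acf / norm) / (wacf / wacf[0])[None, :]


def _acf_pitch_frames(
    rec: AudioRecording, fmin: float, fmax: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame (f0, r, times) from ``PITCH_FRAME_LEN`` analysis frames.

    The pitch lag is picked on a low-passed copy of the signal — jitter
    decorrelates the high-frequency formant ringing at one-period lag,
    which would otherwise produce spurious peaks — while the returned
    correlation height ``r`` is evaluated on the full-band signal at that
    lag, so harmonicity still reflects the whole spectrum.
    """
    if not (0 < fmin < fmax < rec.rate / 2):
        raise ValueError("require 0 < fmin < fmax < Nyquist")
    cutoff = min(max(3.0 * fmax, 1200.0), 0.45 * rec.rate)
    sos = sps.butter(4, cutoff / (rec.rate / 2), output="sos")
    lp = AudioRecording(sps.sosfiltfilt(sos, rec.samples), rec.rate)

    frames_lp, times = frame_signal(lp, PITCH_FRAME_LEN, HOP, window=None)
    frames_lp = frames_lp - frames_lp.mean(axis=1, keepdims=True)
    frames_full, _ = frame_signal(rec, PITCH_FRAME_LEN, HOP, window=None)
    frames_full = frames_full - frames_full.mean(axis=1, keepdims=True)
    n = frames_lp.shape[1]

    r_lp = _corrected_acf(frames_lp)
    r_full = _corrected_acf(frames_full)

    lag_min = max(int(np.floor(rec.rate / fmax)), 2)
    lag_max = min(int(np.ceil(rec.rate / fmin)), n - 2)
    r_lp[:, :lag_min] = -np.inf
    r_lp[:, lag_max + 1 :] = -np.inf

    # subharmonic (octave) errors: under cycle-to-cycle jitter the
    # two-period acf peak is often sharper than the one-period peak
    # (summed intervals average the jitter out), so candidate peaks are
    # scored with a per-octave lag cost
    octave_cost = OCTAVE_COST
    lags = np.arange(r_lp.shape[1], dtype=float)
    lags[0] = 1.0
    score = r_lp - octave_cost * np.log2(lags / lag_min)[None, :]
    score[~np.isfinite(r_lp)] = -np.inf
    peak_lag = np.argmax(score, axis=1).astype(float)
    peak_r = r_full[np.arange(len(frames_lp)), peak_lag.astype(int)]
    for i in range(len(frames_lp)):
        k = int(peak_lag[i])
        if lag_min < k < lag_max:
            # lag refinement on the low-passed acf peak
            y0, y1, y2 = r_lp[i, k - 1], r_lp[i, k], r_lp[i, k + 1]
            denom = y0 - 2 * y1 + y2
            if np.isfinite(denom) and denom < 0:
                d = 0.5 * (y0 - y2) / denom
                if abs(d) < 1:
                    peak_lag[i] = k + d
            # full-band r at the (integer neighbourhood of the) same lag
            z0, z1, z2 = r_full[i, k - 1], r_full[i, k], r_full[i, k + 1]
            dz = z0 - 2 * z1 + z2
            if np.isfinite(dz) and dz < 0:
                dd = np.clip(0.5 * (z0 - z2) / dz, -1, 1)
                peak_r[i] = z1 - 0.25 * (z0 - z2) * dd
    f0 = rec.rate / peak_lag
    return f0, np.clip(peak_r, -1.0, 1.0 - 1e-9), times


def estimate_f0(
    rec: AudioRecording,
    fmin: float = F0_MIN_DEFAULT,
    fmax: float = F0_MAX_DEFAULT,
    voicing_threshold: float = VOICING_THRESHOLD,
) -> FrameSeries:
    """Per-frame autocorrelation F0 in Hz; unvoiced frames are NaN.

    A frame is voiced when the window-corrected normalized autocorrelation
    peak in the [fmin, fmax] lag band exceeds ``voicing_threshold``.
    """
    f0, r, times = _acf_pitch_frames(rec, fmin, fmax)
    voiced = r > voicing_threshold
    values = np.where(voiced, f0, np.nan)
    return FrameSeries(values=values, frame_times=times, voiced_mask=voiced)


def hnr(
    rec: AudioRecording,
    fmin: float = F0_MIN_DEFAULT,
    fmax: float = F0_MAX_DEFAULT,
    voicing_threshold: float = VOICING_THRESHOLD,
    ceiling_db: float = HNR_CEILING_DB,
) -> FrameSeries:
    """Per-voiced-frame harmonics-to-noise ratio, ``10*log10(r/(1-r))`` dB,
    clipped to ``ceiling_db``; r is the autocorrelation peak height."""
    f0, r, times = _acf_pitch_frames(rec, fmin, fmax)
    voiced = r > voicing_threshold
    vals = np.full(len(r), np.nan)
    rv = np.clip(r[voiced], 1e-6, None)
    vals[voiced] = np.minimum(10.0 * np.log10(rv / (1.0 - rv)), ceiling_db)
    return FrameSeries(values=vals, frame_times=times, voiced_mask=voiced)


# ---------------------------------------------------------------------------
# cycle-level prosody: jitter and shimmer
# ---------------------------------------------------------------------------

def jitter_local(periods: np.ndarray) -> float:
    """Local jitter: mean |consecutive period difference| / mean period."""
    p = np.asarray(periods, dtype=float)
    if len(p) < 2:
        raise ValueError("need at least 2 periods")
    return float(np.mean(np.abs(np.diff(p))) / np.mean(p))


def shimmer_local(amplitudes: np.ndarray) -> float:
    """Local shimmer: mean |consecutive amplitude difference| / mean amplitude."""
    a = np.asarray(amplitudes, dtype=float)
    if len(a) < 2:
        raise ValueError("need at least 2 amplitudes")
    return float(np.mean(np.abs(np.diff(a))) / np.mean(a))


def extract_cycles(
    rec: AudioRecording, f0_hint: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle (periods in s, peak amplitudes) from a voiced recording.

    Anchor peaks (one per cycle) come from a low-passed copy of the signal;
    each period is then refined by waveform matching on the raw signal —
    the lag maximizing the normalized cross-correlation between consecutive
    cycle-length windows, with parabolic interpolation for sub-sample
    precision.  The low-pass stage alone would smooth cycle-to-cycle period
    perturbations (the filter rings across cycles), underestimating jitter.
    Per-cycle amplitudes are the low-passed peak heights.
    Returns empty arrays when fewer than 3 cycles are found.
    """
    if f0_hint is None:
        f0s = estimate_f0(rec)
        v = f0s.voiced_values()
        if len(v) == 0:
            return np.array([]), np.array([])
        f0_hint = float(np.median(v))
    cutoff = min(1.5 * f0_hint, 0.45 * rec.rate)
    sos = sps.butter(4, cutoff / (rec.rate / 2), output="sos")
    x = sps.sosfiltfilt(sos, rec.samples)
    edge = min(int(0.02 * rec.rate), len(x) // 4)  # filtfilt edge transients
    x[:edge] = 0.0
    x[len(x) - edge :] = 0.0
    t0 = rec.rate / f0_hint
    min_dist = max(int(0.7 * t0), 1)
    # robust height: a percentile, not the max, so edge transients cannot
    # push the threshold above the real cycle peaks
    height = 0.3 * np.percentile(np.abs(x), 95)
    peaks, _ = sps.find_peaks(x, distance=min_dist, height=height)
    if len(peaks) < 3:
        return np.array([]), np.array([])

    raw = rec.samples
    w = max(int(0.4 * t0), 4)
    search = max(int(0.3 * t0), 3)
    periods = []
    amps = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        t_init = p1 - p0
        if not (0.5 * t0 < t_init < 1.8 * t0):
            continue
        if p0 - w < 0 or p1 + search + w >= len(raw):
            continue
        a = raw[p0 - w : p0 + w]
        lags = np.arange(t_init - search, t_init + search + 1)
        na = np.linalg.norm(a)
        # all candidate windows as one strided matrix -> single matvec
        B = raw[(p0 + lags[:, None]) + np.arange(-w, w)[None, :]]
        nb = np.linalg.norm(B, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ncc = np.where((na > 0) & (nb > 0), (B @ a) / (na * nb), 0.0)
        k = int(np.argmax(ncc))
        lag = float(lags[k])
        if 0 < k < len(lags) - 1:
            y0, y1, y2 = ncc[k - 1], ncc[k], ncc[k + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                lag += float(np.clip(0.5 * (y0 - y2) / denom, -1, 1))
        periods.append(lag / rec.rate)
        # parabolic refinement of the low-passed peak height at the cycle end
        if 0 < p1 < len(x) - 1:
            z0, z1, z2 = x[p1 - 1], x[p1], x[p1 + 1]
            denom = z0 - 2 * z1 + z2
            d = np.clip(0.5 * (z0 - z2) / denom, -1, 1) if denom < 0 else 0.0
            amps.append(float(z1 - 0.25 * (z0 - z2) * d))
        else:
            amps.append(float(x[p1]))
    return np.asarray(periods), np.asarray(amps)


# ---------------------------------------------------------------------------
# spectral features
# ---------------------------------------------------------------------------

BAND_EDGES = ((0.0, 500.0), (500.0, 1000.0), (1000.0, 4000.0))


def _power_spectra(rec: AudioRecording) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    frames, times = frame_signal(rec, FRAME_LEN, HOP, window="hamming")
    nfft = 1 << int(np.ceil(np.log2(frames.shape[1])))
    spec = rfft(frames, nfft, axis=1)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(nfft, 1.0 / rec.rate)
    return power, freqs, times


def spectral_features(rec: AudioRecording) -> dict[str, FrameSeries]:
    """Band powers over [0,500), [500,1000), [1000,4000) Hz, the power
    spectral centroid, spectral flux and energy RMS, per 25 ms frame.

    Flux is the Euclidean distance between consecutive magnitude spectra
    after each is normalized to unit total power; the first frame gets 0.
    """
    if rec.rate / 2 <= 4000.0:
        raise ValueError("sample rate too low for the 1000-4000 Hz band")
    power, freqs, times = _power_spectra(rec)
    out: dict[str, FrameSeries] = {}
    for name, (lo, hi) in zip(
        ("band_power_0_500", "band_power_500_1000", "band_power_1000_4000"), BAND_EDGES
    ):
        mask = (freqs >= lo) & (freqs < hi)
        out[name] = FrameSeries(values=power[:, mask].sum(axis=1), frame_times=times)

    total = power.sum(axis=1)
    safe = np.where(total > 0, total, np.nan)
    centroid = (power * freqs[None, :]).sum(axis=1) / safe
    out["spectral_centroid"] = FrameSeries(values=centroid, frame_times=times)

    mag = np.sqrt(power)
    norm = np.sqrt(np.where(total > 0, total, np.inf))
    unit = mag / norm[:, None]
    flux = np.zeros(len(times))
    if len(times) > 1:
        flux[1:] = np.linalg.norm(np.diff(unit, axis=0), axis=1)
    out["spectral_flux"] = FrameSeries(values=flux, frame_times=times)

    frames, t2 = frame_signal(rec, FRAME_LEN, HOP, window=None)
    out["energy_rms"] = FrameSeries(values=np.sqrt(np.mean(frames**2, axis=1)), frame_times=t2)
    return out


# ---------------------------------------------------------------------------
# linear prediction and formants
# ---------------------------------------------------------------------------

def lpc_coefficients(frame: np.ndarray, order: int) -> np.ndarray:
    """Autocorrelation-method LPC via Levinson-Durbin; returns [1, a1..ap]
    of the prediction error filter A(z).  Falls back to a flat model on
    degenerate frames."""
    x = np.asarray(frame, dtype=float)
    n = len(x)
    if n <= order:
        raise ValueError("frame shorter than LPC order")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    acf = np.fft.irfft(np.abs(np.fft.rfft(x, nfft)) ** 2, nfft)[: order + 1]
    if acf[0] <= 0:
        return np.concatenate(([1.0], np.zeros(order)))
    a = np.zeros(order + 1)
    a[0] = 1.0
    err = acf[0] * (1.0 + 1e-9)  # tiny ridge against singular frames
    for i in range(1, order + 1):
        acc = acf[i] + a[1:i] @ acf[i - 1 : 0 : -1]
        if err <= 0:
            break
        k = -acc / err
        a[1:i] = a[1:i] + k * a[i - 1 : 0 : -1]
        a[i] = k
        err *= 1.0 - k * k
    return a


def default_lpc_order(rate: float) -> int:
    return 2 + int(round(rate / 1000.0))


def formants(
    rec: AudioRecording,
    n: int = 5,
    order: int | None = None,
    bandwidth_cutoff: float = 400.0,
    freq_floor: float = 90.0,
    preemphasis: float = 0.97,
    voiced_mask: np.ndarray | None = None,
) -> list[FrameSeries]:
    """First ``n`` formant tracks from LPC root frequencies, voiced frames only.

    Roots of the prediction polynomial are mapped to (frequency, bandwidth);
    roots below ``freq_floor`` Hz or broader than ``bandwidth_cutoff`` Hz
    are discarded and the first ``n`` survivors reported in increasing
    order.  Frames with fewer than ``n`` survivors hold NaN in the missing
    slots.
    """
    if n > 5:
        raise ValueError("at most 5 formants supported")
    if order is None:
        order = default_lpc_order(rec.rate)
    voiced = estimate_f0(rec).voiced_mask if voiced_mask is None else np.asarray(voiced_mask, bool)
    x = np.append(rec.samples[0], rec.samples[1:] - preemphasis * rec.samples[:-1])
    pre = AudioRecording(samples=x, rate=rec.rate)
    frames, times = frame_signal(pre, FRAME_LEN, HOP, window="hamming")
    n_frames = min(len(frames), len(voiced))
    vals = np.full((n_frames, n), np.nan)
    vidx = [i for i in range(n_frames) if voiced[i]]
    if vidx:
        # batch the companion-matrix eigenvalue problems: one stacked
        # eigvals call is far cheaper than np.roots per frame
        comp = np.zeros((len(vidx), order, order))
        comp[:, np.arange(1, order), np.arange(order - 1)] = 1.0
        for j, i in enumerate(vidx):
            a = lpc_coefficients(frames[i], order)
            comp[j, 0, :] = -a[1:]
        roots = np.linalg.eigvals(comp)
        for j, i in enumerate(vidx):
            r = roots[j][np.imag(roots[j]) > 1e-6]
            freqs = np.angle(r) * rec.rate / (2 * np.pi)
            bws = -np.log(np.clip(np.abs(r), 1e-12, None)) * rec.rate / np.pi
            cand = np.sort(freqs[(freqs >= freq_floor) & (bws <= bandwidth_cutoff)])
            m = min(n, len(cand))
            vals[i, :m] = cand[:m]
    times = times[:n_frames]
    return [FrameSeries(values=vals[:, k], frame_times=times) for k in range(n)]


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------

def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, nfft: int, rate: float) -> np.ndarray:
    """Triangular mel filters spanning 0 Hz to Nyquist on rfft bins."""
    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(rate / 2), n_filters + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.fft.rfftfreq(nfft, 1.0 / rate)
    fb = np.zeros((n_filters, len(bins)))
    for j in range(n_filters):
        lo, ctr, hi = hz_pts[j], hz_pts[j + 1], hz_pts[j + 2]
        up = (bins >= lo) & (bins <= ctr)
        down = (bins > ctr) & (bins <= hi)
        if ctr > lo:
            fb[j, up] = (bins[up] - lo) / (ctr - lo)
        if hi > ctr:
            fb[j, down] = (hi - bins[down]) / (hi - ctr)
    return fb


def mfcc(
    rec: AudioRecording,
    n_coeff: int = 12,
    n_filters: int = 26,
    log_floor: float = 1e-10,
) -> list[FrameSeries]:
    """MFCCs 1..n_coeff per 25 ms frame (energy coefficient 0 excluded).

    Log mel-filterbank energies (floored at ``log_floor``) followed by an
    orthonormal DCT-II.  Excluding coefficient 0 makes the result invariant
    to global amplitude scaling.
    """
    if n_coeff < 1:
        raise ValueError("n_coeff must be at least 1")
    power, freqs, times = _power_spectra(rec)
    fb = mel_filterbank(n_filters, 2 * (power.shape[1] - 1), rec.rate)
    energies = power @ fb.T
    log_e = np.log(np.maximum(energies, log_floor))
    # orthonormal DCT-II basis, rows 1..n_coeff
    k = np.arange(1, n_coeff + 1)[:, None]
    j = np.arange(n_filters)[None, :]
    basis = np.sqrt(2.0 / n_filters) * np.cos(np.pi * k * (2 * j + 1) / (2 * n_filters))
    coeffs = log_e @ basis.T
    return [FrameSeries(values=coeffs[:, i], frame_times=times) for i in range(n_coeff)]
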
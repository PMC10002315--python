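"""Glottal flow estimation by iterative adaptive inverse filtering (IAIF)
and the per-cycle amplitude/opening quotients NAQ and QOQ.

IAIF alternates a low-order model of the glottal source with a higher-order
linear-prediction model of the vocal tract: the source contribution is
inverse-filtered away before estimating the tract, and the tract inverse
filter then exposes the glottal flow derivative, which is integrated to the
flow.  Two iterations (glottal pre-model orders 1 then 4) follow the
standard formulation.  Filters are estimated per voiced frame and the
per-frame flow-derivative segments are overlap-added back into a continuous
signal; glottal closure instants are the negative peaks of the derivative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .audio import AudioRecording, frame_signal
from .features import default_lpc_order, estimate_f0, lpc_coefficients

IAIF_FRAME_LEN = 0.064
IAIF_HOP = 0.032


@dataclass
class GlottalFlow:
    """Estimated glottal volume-velocity waveform and detected cycles."""

    flow: np.ndarray
    flow_derivative: np.ndarray
    cycle_boundaries: np.ndarray
    rate: float
    voiced: bool = True

    def __post_init__(self) -> None:
        self.flow = np.asarray(self.flow, dtype=float)
        self.flow_derivative = np.asarray(self.flow_derivative, dtype=float)
        self.cycle_boundaries = np.asarray(self.cycle_boundaries, dtype=int)
        if len(self.flow) and len(self.flow_derivative) != len(self.flow) - 1:
            raise ValueError("flow_derivative must have length len(flow) - 1")
        if len(self.cycle_boundaries) > 1 and np.any(np.diff(self.cycle_boundaries) <= 0):
            raise ValueError("cycle_boundaries must be strictly increasing")


def _leaky_integrate(x: np.ndarray, d: float = 0.99) -> np.ndarray:
    return sps.lfilter([1.0], [1.0, -d], x)


def iaif(
    rec: AudioRecording,
    tract_order: int | None = None,
    glottal_order: int = 4,
    f0_hint: float | None = None,
) -> GlottalFlow:
    """Estimate the glottal flow of a voiced recording.

    Returns an empty :class:`GlottalFlow` with ``voiced=False`` (and a
    warning) when no voiced frames are found.  ``f0_hint`` skips the
    internal pitch pass when the caller already knows the median F0.
    """
    if tract_order is None:
        tract_order = default_lpc_order(rec.rate)

    if f0_hint is None:
        f0_series = estimate_f0(rec)
        voiced_vals = f0_series.voiced_values()
        if len(voiced_vals) == 0:
            warnings.warn("iaif: input appears unvoiced; returning empty flow")
            return GlottalFlow(
                flow=np.array([]), flow_derivative=np.array([]),
                cycle_boundaries=np.array([], dtype=int), rate=rec.rate, voiced=False,
            )
        f0_med = float(np.median(voiced_vals))
    else:
        f0_med = float(f0_hint)

    # high-pass preprocessing to remove rumble below the voice band
    sos = sps.butter(4, 40.0 / (rec.rate / 2), btype="highpass", output="sos")
    x = sps.sosfiltfilt(sos, rec.samples)
    hp = AudioRecording(samples=x, rate=rec.rate)

    frames, times = frame_signal(hp, IAIF_FRAME_LEN, IAIF_HOP, window=None)
    n_frame = frames.shape[1]
    n_hop = int(round(IAIF_HOP * rec.rate))
    win = np.hanning(n_frame)
    analysis_win = np.hamming(n_frame)

    dglot = np.zeros(len(x))
    wsum = np.zeros(len(x))
    def _fir(b: np.ndarray, x: np.ndarray) -> np.ndarray:
        return np.convolve(x, b)[: len(x)]  # inverse filters are FIR

    for i in range(len(frames)):
        fr = frames[i]
        wfr = fr * analysis_win
        # iteration 1: order-1 glottal pre-model, then vocal tract
        g1 = lpc_coefficients(wfr, 1)
        y1 = _fir(g1, fr)
        vt1 = lpc_coefficients(y1 * analysis_win, tract_order)
        dg1 = _fir(vt1, fr)
        g1_est = _leaky_integrate(dg1)
        # iteration 2: refined glottal model from the first estimate
        g2 = lpc_coefficients(g1_est * analysis_win, glottal_order)
        y2 = _fir(g2, fr)
        y2 = _leaky_integrate(y2)
        vt2 = lpc_coefficients(y2 * analysis_win, tract_order)
        dg = _fir(vt2, fr)
        start = i * n_hop
        dglot[start : start + n_frame] += dg * win
        wsum[start : start + n_frame] += win
    dglot = dglot / np.maximum(wsum, 1e-6)
    dglot[wsum < 0.1] = 0.0  # un-covered edges would otherwise amplify transients

    flow = _leaky_integrate(dglot)
    flow_derivative = np.diff(flow)

    min_dist = max(int(0.7 * rec.rate / f0_med), 1)
    neg = -flow_derivative
    peaks, _ = sps.find_peaks(neg, distance=min_dist, height=0.25 * np.max(neg))
    return GlottalFlow(
        flow=flow, flow_derivative=flow_derivative,
        cycle_boundaries=peaks, rate=rec.rate, voiced=True,
    )


@dataclass
class QuotientSeries:
    """Per-cycle NAQ and QOQ values plus the count of degenerate cycles."""

    naq: np.ndarray
    qoq: np.ndarray
    n_skipped: int = 0


def glottal_quotients(gf: GlottalFlow) -> QuotientSeries:
    """Per-cycle normalized amplitude quotient and quasi-open quotient.

    NAQ = (peak-to-peak flow) / (|most negative flow derivative| x cycle
    duration); QOQ = fraction of the cycle during which the flow exceeds
    the cycle minimum plus half the peak-to-peak amplitude.  The derivative
    is the per-sample first difference and durations are in samples, so the
    product is in the same time units and both quotients are dimensionless.
    Degenerate cycles (zero duration, flat flow or zero derivative peak)
    are skipped and counted.
    """
    b = gf.cycle_boundaries
    if len(b) < 2:
        raise ValueError("need at least one complete cycle")
    naqs, qoqs = [], []
    skipped = 0
    for s, e in zip(b[:-1], b[1:]):
        t = e - s
        seg = gf.flow[s:e]
        dseg = gf.flow_derivative[s:e]
        if t <= 0 or len(seg) == 0 or len(dseg) == 0:
            skipped += 1
            continue
        p2p = float(np.max(seg) - np.min(seg))
        # first differences live at sample midpoints; extrapolate half a
        # sample along the local slope to recover node values, otherwise the
        # sharp negative peak at glottal closure is underestimated
        if len(dseg) >= 2:
            dnode = 1.5 * dseg[1:] - 0.5 * dseg[:-1]
            dmin = float(min(np.min(dnode), np.min(dseg)))
        else:
            dmin = float(np.min(dseg))
        if p2p <= 0 or dmin >= 0:
            skipped += 1
            continue
        naqs.append(p2p / (abs(dmin) * t))
        thresh = np.min(seg) + 0.5 * p2p
        qoqs.append(float(np.count_nonzero(seg > thresh)) / t)
    return QuotientSeries(naq=np.asarray(naqs), qoq=np.asarray(qoqs), n_skipped=skipped)
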
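"""Source-filter voice synthesis with a Rosenberg glottal pulse train.

The generator is the test-bed oracle for the acoustic feature extractors:
every perceptual dimension the features measure (F0 and its variability,
open quotient, jitter, shimmer, aspiration noise, formant structure) is a
controllable parameter, so extractor outputs can be checked against the
parameters that produced the waveform.

Model
-----
Glottal flow is a train of Rosenberg pulses (polynomial "type C" shape):
within a cycle of period T with open quotient OQ, the open phase lasts
``OQ*T`` and splits into a rising phase ``Tp = 2/3 * OQ*T`` with
``g = 3u^2 - 2u^3`` (u = t/Tp) and a falling phase ``Tn = 1/3 * OQ*T`` with
``g = 1 - v^2`` (v = (t-Tp)/Tn); the rest of the cycle is closed (g = 0).
The abrupt stop of the falling phase gives the negative flow-derivative
peak that excites the vocal tract.

Per-cycle period and amplitude perturbations are Gaussian and scaled so the
*expected local jitter/shimmer* (mean absolute consecutive difference over
mean) equals the requested percentage.  Aspiration noise is white Gaussian
added to the source at a given periodic-to-noise power ratio.  The vocal
tract is a cascade of two-pole resonators (one per formant), and lip
radiation is a first difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .audio import AudioRecording

# E|z1 - z2| for iid standard normals is 2/sqrt(pi); dividing the requested
# perturbation by it makes the expected local jitter/shimmer match the request.
_GAUSS_ABS_DIFF = 2.0 / math.sqrt(math.pi)


@dataclass
class GlottalParams:
    """Parameters of the glottal source.

    f0_mean / f0_sd : Hz — mean and slow-drift SD of the fundamental.
    open_quotient : fraction of the cycle the glottis is open, in (0, 1).
    jitter_pct / shimmer_pct : expected cycle-to-cycle local jitter/shimmer, %.
    noise_snr_db : periodic-to-aspiration-noise power ratio in dB
        (``inf`` for a noiseless source).
    amplitude : linear gain before the anti-clipping normalization.
    """

    f0_mean: float = 120.0
    f0_sd: float = 2.0
    open_quotient: float = 0.6
    jitter_pct: float = 1.0
    shimmer_pct: float = 3.0
    noise_snr_db: float = 25.0
    amplitude: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.open_quotient < 1.0):
            raise ValueError("open_quotient must be in (0, 1)")
        if self.f0_mean <= 0:
            raise ValueError("f0_mean must be positive")
        if self.jitter_pct < 0 or self.shimmer_pct < 0:
            raise ValueError("jitter_pct and shimmer_pct must be non-negative")


@dataclass
class FormantSpec:
    """Vocal-tract resonances: five center frequencies (Hz, strictly
    increasing) and matching bandwidths (Hz, positive)."""

    centers: tuple[float, ...] = (660.0, 1200.0, 2550.0, 3500.0, 4500.0)
    bandwidths: tuple[float, ...] = (80.0, 110.0, 160.0, 220.0, 300.0)

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        b = np.asarray(self.bandwidths, dtype=float)
        if len(c) != len(b):
            raise ValueError("centers and bandwidths must have equal length")
        if np.any(np.diff(c) <= 0):
            raise ValueError("formant centers must be strictly increasing")
        if np.any(b <= 0):
            raise ValueError("bandwidths must be positive")

    def validate_rate(self, rate: float) -> None:
        if max(self.centers) >= rate / 2:
            raise ValueError("formant center at or above Nyquist")


def rosenberg_flow(phase: np.ndarray, open_quotient: float) -> np.ndarray:
    """Rosenberg flow evaluated at normalized cycle phase in [0, 1).

    Closed form used both by the synthesizer and by the analytic NAQ/QOQ
    oracles; flow rises 0 -> 1 over the first two thirds of the open phase
    and falls parabolically to 0 over the last third, then stays closed.
    """
    if not (0.0 < open_quotient < 1.0):
        raise ValueError("open_quotient must be in (0, 1)")
    t = np.asarray(phase, dtype=float)
    tp = 2.0 / 3.0 * open_quotient
    tn = open_quotient - tp
    g = np.zeros_like(t)
    rise = (t >= 0) & (t < tp)
    u = t[rise] / tp
    g[rise] = 3 * u**2 - 2 * u**3
    fall = (t >= tp) & (t < open_quotient)
    v = (t[fall] - tp) / tn
    g[fall] = 1.0 - v**2
    return g


def rosenberg_pulse(open_quotient: float, n_samples: int) -> np.ndarray:
    """One Rosenberg flow pulse sampled on ``n_samples`` points of one cycle."""
    return rosenberg_flow(np.arange(n_samples) / n_samples, open_quotient)


def _resonator_ba(center: float, bandwidth: float, rate: float):
    """Two-pole resonator with unit DC gain (Klatt formulation)."""
    r = math.exp(-math.pi * bandwidth / rate)
    theta = 2 * math.pi * center / rate
    a = [1.0, -2 * r * math.cos(theta), r * r]
    b = [1.0 + a[1] + a[2]]
    return b, a


def glottal_source(
    glottal: GlottalParams, duration: float, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Generate the noiseless glottal flow train and its cycle start indices."""
    n_total = int(round(duration * rate))
    flow = np.zeros(n_total + int(2 * rate / glottal.f0_mean) + 4)
    starts = []
    # slow f0 drift: smoothed white noise, unit variance, scaled by f0_sd
    n_cycles_max = int(duration * glottal.f0_mean * 1.5) + 8
    drift = rng.standard_normal(n_cycles_max)
    if n_cycles_max >= 5:
        kernel = np.ones(5) / 5.0
        drift = np.convolve(drift, kernel, mode="same") * math.sqrt(5.0)
    jit_sigma = glottal.jitter_pct / 100.0 / _GAUSS_ABS_DIFF
    shim_sigma = glottal.shimmer_pct / 100.0 / _GAUSS_ABS_DIFF
    pos = 0.0
    i = 0
    while pos < n_total:
        f0_i = glottal.f0_mean + glottal.f0_sd * drift[min(i, n_cycles_max - 1)]
        f0_i = max(f0_i, 20.0)
        shape_period = rate / f0_i
        # jitter perturbs the cycle *spacing*, not the pulse shape: glottal
        # events (closures) then carry the designed cycle-to-cycle jitter
        period = shape_period * max(1.0 + jit_sigma * rng.standard_normal(), 0.2)
        amp = max(1.0 + shim_sigma * rng.standard_normal(), 0.0)
        # continuous-time evaluation: cycle start and period stay fractional
        # so sampling adds no artificial period quantization jitter
        s0 = int(math.ceil(pos))
        s1 = min(int(math.ceil(pos + min(shape_period, period))), len(flow))
        if s1 > s0:
            phase = (np.arange(s0, s1) - pos) / shape_period
            flow[s0:s1] += amp * rosenberg_flow(phase, glottal.open_quotient)
        starts.append(s0)
        pos += period
        i += 1
    if starts and starts[-1] >= n_total:
        starts = starts[:-1]
    return flow[:n_total], np.asarray(starts)


def synthesize_voice(
    glottal: GlottalParams,
    tract: FormantSpec,
    duration: float,
    rate: float = 11025.0,
    seed: int | np.random.Generator = 0,
) -> AudioRecording:
    """Synthesize a sustained-phonation waveform.

    Rosenberg pulse train -> additive aspiration noise at ``noise_snr_db``
    -> resonator cascade -> first-difference radiation -> gain with
    anti-clipping normalization.  Deterministic given the seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate < 8000:
        raise ValueError("rate must be at least 8000 Hz")
    tract.validate_rate(rate)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    flow, _ = glottal_source(glottal, duration, rate, rng)
    src = flow - np.mean(flow)

    def _vocal_tract(x: np.ndarray) -> np.ndarray:
        for c, bw in zip(tract.centers, tract.bandwidths):
            b, a = _resonator_ba(c, bw, rate)
            x = sps.lfilter(b, a, x)
        return np.diff(x, prepend=0.0)  # lip radiation

    y = _vocal_tract(src)
    if np.isfinite(glottal.noise_snr_db):
        # the SNR is defined on the radiated output: aspiration noise passes
        # through the same tract, so scale after filtering
        noise = _vocal_tract(rng.standard_normal(len(src)))
        p_sig = np.mean(y**2)
        p_noise = np.mean(noise**2)
        if p_noise > 0:
            target = p_sig / 10.0 ** (glottal.noise_snr_db / 10.0)
            y = y + noise * math.sqrt(target / p_noise)

    peak = np.max(np.abs(y))
    if peak > 0:
        y = y / peak
    y = glottal.amplitude * y
    over = np.max(np.abs(y))
    if over > 0.95:
        y = y * (0.95 / over)
    return AudioRecording(samples=y, rate=rate)
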
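"""Chest-vibration and radar-baseband simulator.

The chest surface of a resting subject moves as the superposition of three
displacement components,

    m(t) = m_heart(t) + m_resp(t) + w(t),

a small sinusoidal heartbeat component (~0.5 mm at ~1 Hz), a much larger
non-sinusoidal respiration component (0.5–20 mm at ~0.25 Hz with
odd-dominant harmonics), and white measurement noise.  A continuous-wave
Doppler radar pointed at the chest returns this displacement encoded in the
phase of its quadrature baseband pair

    B_I(t) = A_I cos(4*pi*(m(t)+d0)/lambda + theta + dphi(t)),
    B_Q(t) = A_Q sin(4*pi*(m(t)+d0)/lambda + theta + dphi(t)),

where lambda is the carrier wavelength, d0 the standoff distance and dphi
residual phase noise.  This module generates both the displacement scene
(with known true beat times) and the corresponding I/Q baseband, so the
whole extraction pipeline can be exercised and scored without hardware.

The signal-to-interference ratio of a scene is defined on amplitudes,

    SNR = 20 * log10( RMS(m_heart) / RMS(m_resp + w) )   [dB],

and scenes are calibrated to a target SNR by rescaling the respiration
amplitude only, leaving heartbeat and noise untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.constants import c as _SPEED_OF_LIGHT

from .signals import IQBaseband, SampledSignal

__all__ = [
    "RespModelParams",
    "HeartModelParams",
    "ScenarioParams",
    "RadarParams",
    "ChestScene",
    "RESP_PRESETS",
    "resp_waveform",
    "heart_waveform",
    "heart_peak_times",
    "measure_snr",
    "compose_chest_vibration",
    "synthesize_baseband",
    "simulate_scene",
]

#: Tolerance (dB) within which SNR calibration must land on the target.
SNR_CALIBRATION_TOL_DB = 0.01


@dataclass(frozen=True)
class RespModelParams:
    """Two-branch respiration displacement model.

    One breath of period ``T = Ti + Te`` rises from zero to the peak
    displacement ``Kb`` along a quadratic during inspiration (``[0, Ti]``)
    and relaxes back to zero along an exponential with time constant ``tau``
    during expiration (``[Ti, T]``).  The two branches join continuously at
    ``Ti`` (value ``Kb``) and at the period boundary (value 0), which is what
    gives the waveform its odd-dominant harmonic structure.

    Defaults describe quiet breathing at 15 breaths/min (0.25 Hz) with a
    10 mm peak excursion.
    """

    Kb: float = 10e-3  # peak displacement, m
    T: float = 4.0  # breath period, s
    Ti: float = 2.0  # inspiration time, s
    Te: float = 2.0  # expiration time, s
    tau: float = 0.8  # expiration time constant, s

    def __post_init__(self) -> None:
        for name in ("Kb", "T", "Ti", "Te", "tau"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not math.isclose(self.T, self.Ti + self.Te, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(f"T must equal Ti + Te, got T={self.T}, Ti+Te={self.Ti + self.Te}")

    def scaled(self, factor: float) -> "RespModelParams":
        """Same breathing pattern with the amplitude multiplied by *factor*."""
        return replace(self, Kb=self.Kb * factor)


#: Named respiration presets.  ``"15bpm"`` is the default quiet-breathing
#: configuration (0.25 Hz fundamental); ``"table1"`` keeps the 2.5 s period
#: variant of the same model (0.4 Hz fundamental).
RESP_PRESETS: dict[str, RespModelParams] = {
    "15bpm": RespModelParams(),
    "table1": RespModelParams(Kb=10e-3, T=2.5, Ti=1.25, Te=1.25, tau=0.8),
}


@dataclass(frozen=True)
class HeartModelParams:
    """Sinusoidal heartbeat displacement: peak ``amplitude`` at ``rate`` bpm."""

    amplitude: float = 0.5e-3  # peak displacement, m
    rate: float = 60.0  # beats per minute
    phase: float = 0.0  # initial phase, rad

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")
        if not 30.0 <= self.rate <= 220.0:
            raise ValueError(f"rate must lie in [30, 220] bpm, got {self.rate}")

    @property
    def frequency(self) -> float:
        """Fundamental frequency in Hz."""
        return self.rate / 60.0


@dataclass(frozen=True)
class ScenarioParams:
    """Scene composition: duration, clock, noise level and SNR target.

    ``target_snr`` of ``None`` keeps the respiration amplitude exactly as
    given by the respiration parameters; otherwise the respiration component
    is rescaled so the amplitude-ratio SNR hits the target.
    """

    duration: float = 20.0  # s
    fs: float = 100.0  # Hz
    target_snr: float | None = None  # dB
    noise_amplitude: float = 0.1e-3  # white-noise displacement std, m
    seed: int = 0
    resp_phase: float = 0.0  # respiration phase offset, s
    heart_phase: float = 0.0  # heartbeat phase offset, rad

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be non-negative")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"duration * fs must be an integer sample count, got {n}")

    @property
    def n_samples(self) -> int:
        return round(self.duration * self.fs)


@dataclass(frozen=True)
class RadarParams:
    """CW radar front-end description.

    Defaults model a 24 GHz sensor (lambda ~ 12.5 mm) half a metre from the
    chest with balanced channels and no phase noise.
    """

    carrier_freq: float = 24e9  # Hz
    d0: float = 0.5  # radar-to-chest distance, m
    theta: float = 0.0  # constant phase offset, rad
    amp_i: float = 1.0
    amp_q: float = 1.0
    phase_noise_std: float = 0.0  # rad

    def __post_init__(self) -> None:
        if not self.carrier_freq > 0:
            raise ValueError("carrier_freq must be positive")
        if not (self.amp_i > 0 and self.amp_q > 0):
            raise ValueError("channel amplitudes must be positive")
        if self.phase_noise_std < 0:
            raise ValueError("phase_noise_std must be non-negative")

    @property
    def wavelength(self) -> float:
        """Carrier wavelength lambda = c / f in metres."""
        return _SPEED_OF_LIGHT / self.carrier_freq


def _resp_values(params: RespModelParams, t: np.ndarray) -> np.ndarray:
    """Evaluate the two-branch respiration displacement at times *t* (s)."""
    tp = np.mod(t, params.T)
    out = np.empty_like(tp)
    insp = tp <= params.Ti
    ti, te, tau, kb = params.Ti, params.Te, params.tau, params.Kb
    # inspiration: quadratic rising 0 -> Kb on [0, Ti]
    x = tp[insp]
    out[insp] = -(kb / (ti * te)) * x**2 + (kb * params.T / (ti * te)) * x
    # expiration: exponential decay Kb -> 0 on [Ti, T]
    x = tp[~insp] - ti
    scale = kb / (1.0 - math.exp(-te / tau))
    out[~insp] = scale * (np.exp(-x / tau) - math.exp(-te / tau))
    return out


def resp_waveform(
    params: RespModelParams,
    fs: float,
    duration: float,
    phase_offset: float = 0.0,
) -> SampledSignal:
    """Generate the periodic respiration displacement waveform.

    Parameters
    ----------
    params : RespModelParams
        Breathing-pattern constants.
    fs, duration : float
        Sample rate (Hz) and length (s) of the generated series.
    phase_offset : float
        Time shift in seconds applied inside the breathing cycle, so scenes
        can start at an arbitrary point of the breath.

    Returns
    -------
    SampledSignal
        Displacement in metres, non-negative, peaking at ``Kb``.
    """
    n = round(duration * fs)
    t = np.arange(n) / fs + phase_offset
    return SampledSignal(_resp_values(params, t), fs=fs, unit="m")


def heart_waveform(
    params: HeartModelParams, fs: float, duration: float, phase: float | None = None
) -> SampledSignal:
    """Generate the sinusoidal heartbeat displacement (zero mean)."""
    n = round(duration * fs)
    t = np.arange(n) / fs
    ph = params.phase if phase is None else phase
    values = params.amplitude * np.sin(2.0 * np.pi * params.frequency * t + ph)
    return SampledSignal(values, fs=fs, unit="m")


def heart_peak_times(
    params: HeartModelParams, duration: float, phase: float | None = None
) -> np.ndarray:
    """True beat times: the maxima of the heartbeat sinusoid in [0, duration)."""
    ph = params.phase if phase is None else phase
    f = params.frequency
    first = ((np.pi / 2.0 - ph) / (2.0 * np.pi * f)) % (1.0 / f)
    return np.arange(first, duration, 1.0 / f)


def measure_snr(heart: SampledSignal, resp: SampledSignal, noise: SampledSignal) -> float:
    """Amplitude-ratio SNR in dB: ``20*log10(RMS(heart)/RMS(resp+noise))``.

    Returns ``inf`` when the interference is identically zero and ``-inf``
    for a vanishing heartbeat, rather than raising.
    """
    if not (heart.n == resp.n == noise.n):
        raise ValueError("heart, resp and noise must have equal length")
    if not (heart.fs == resp.fs == noise.fs):
        raise ValueError("heart, resp and noise must share a sample rate")
    num = heart.rms()
    den = float(np.sqrt(np.mean(np.square(resp.values + noise.values))))
    if den == 0.0:
        return math.inf
    if num == 0.0:
        return -math.inf
    return 20.0 * math.log10(num / den)


@dataclass(frozen=True)
class ChestScene:
    """A fully specified synthetic measurement scene.

    Carries the composite displacement plus its components, the achieved
    SNR, the ground-truth beat times and (optionally) the synthesized radar
    baseband, so downstream accuracy can be scored against exact truth.
    """

    displacement: SampledSignal
    heart: SampledSignal
    resp: SampledSignal
    noise: SampledSignal
    achieved_snr: float
    true_beat_times: np.ndarray
    heart_params: HeartModelParams
    resp_params: RespModelParams
    scenario: ScenarioParams
    iq: IQBaseband | None = None
    radar: RadarParams | None = None

    @property
    def fs(self) -> float:
        return self.displacement.fs


def _respiration_scale(
    heart_v: np.ndarray, resp_v: np.ndarray, noise_v: np.ndarray, target_snr: float
) -> float:
    """Scalar alpha >= 0 such that RMS(alpha*resp + noise) hits the target.

    Solves the quadratic ``alpha^2*Pr + 2*alpha*C + Pn = D^2`` where
    ``D = RMS(heart) / 10^(target/20)``; raises when even a zero-amplitude
    respiration leaves the noise floor above the target.
    """
    pr = float(np.mean(resp_v**2))
    pn = float(np.mean(noise_v**2))
    cross = float(np.mean(resp_v * noise_v))
    d2 = float(np.mean(heart_v**2)) / 10.0 ** (target_snr / 10.0)
    if pr == 0.0:
        raise ValueError("respiration waveform is identically zero; cannot calibrate SNR")
    disc = cross**2 - pr * (pn - d2)
    if disc < 0:
        raise ValueError(
            f"target SNR {target_snr:.2f} dB is unreachable: the white-noise floor "
            f"alone ({pn:.3e} m^2) already exceeds the required interference power"
        )
    alpha = (-cross + math.sqrt(disc)) / pr
    if alpha < 0:
        raise ValueError(
            f"target SNR {target_snr:.2f} dB is unreachable: the white-noise floor "
            "alone already exceeds the required interference power"
        )
    return alpha


def compose_chest_vibration(
    heart_p: HeartModelParams,
    resp_p: RespModelParams,
    scen: ScenarioParams,
) -> tuple[SampledSignal, float]:
    """Compose ``m(t) = m_heart + m_resp + w`` calibrated to the target SNR.

    Only the respiration amplitude is rescaled to reach
    ``scen.target_snr``; heartbeat and noise amplitudes are untouched.
    Returns the composite displacement and the achieved SNR (within
    0.01 dB of the target when one was requested).
    """
    scene = simulate_scene(heart_p, resp_p, scen)
    return scene.displacement, scene.achieved_snr


def simulate_scene(
    heart_p: HeartModelParams | None = None,
    resp_p: RespModelParams | None = None,
    scen: ScenarioParams | None = None,
    radar: RadarParams | None = None,
    include_respiration: bool = True,
) -> ChestScene:
    """Build a complete scene; optionally synthesize the radar baseband.

    ``include_respiration=False`` produces the heartbeat-plus-noise control
    scene (the respiration component is identically zero and no SNR
    calibration is attempted).
    """
    heart_p = heart_p or HeartModelParams()
    resp_p = resp_p or RespModelParams()
    scen = scen or ScenarioParams()

    heart = heart_waveform(heart_p, scen.fs, scen.duration, phase=scen.heart_phase)
    rng = np.random.default_rng(scen.seed)
    noise_v = rng.normal(0.0, scen.noise_amplitude, heart.n) if scen.noise_amplitude else np.zeros(heart.n)
    noise = SampledSignal(noise_v, fs=scen.fs, unit="m")

    if include_respiration:
        resp = resp_waveform(resp_p, scen.fs, scen.duration, phase_offset=scen.resp_phase)
        if scen.target_snr is not None:
            alpha = _respiration_scale(
                heart.values, resp.values, noise.values, scen.target_snr
            )
            resp = resp.with_values(alpha * resp.values)
            resp_p = resp_p.scaled(alpha)
    else:
        resp = SampledSignal(np.zeros(heart.n), fs=scen.fs, unit="m")

    achieved = measure_snr(heart, resp, noise)
    if scen.target_snr is not None and include_respiration:
        if abs(achieved - scen.target_snr) > SNR_CALIBRATION_TOL_DB:
            raise RuntimeError(
                f"SNR calibration failed: achieved {achieved:.4f} dB for target "
                f"{scen.target_snr:.4f} dB"
            )

    total = heart.with_values(heart.values + resp.values + noise.values)
    beats = heart_peak_times(heart_p, scen.duration, phase=scen.heart_phase)

    iq = None
    if radar is not None:
        iq = synthesize_baseband(total, radar, seed=scen.seed + 1)
    return ChestScene(
        displacement=total,
        heart=heart,
        resp=resp,
        noise=noise,
        achieved_snr=achieved,
        true_beat_times=beats,
        heart_params=heart_p,
        resp_params=resp_p,
        scenario=scen,
        iq=iq,
        radar=radar,
    )


def synthesize_baseband(x: SampledSignal, radar: RadarParams, seed: int = 0) -> IQBaseband:
    """Encode a displacement series into the radar's I/Q baseband pair.

    The common phase argument is ``4*pi*(x + d0)/lambda + theta`` plus
    per-sample Gaussian phase noise of std ``radar.phase_noise_std`` (drawn
    once, seeded); the channels are its cosine and sine scaled by the
    channel amplitudes.
    """
    lam = radar.wavelength
    arg = 4.0 * np.pi * (x.values + radar.d0) / lam + radar.theta
    if radar.phase_noise_std > 0:
        rng = np.random.default_rng(seed)
        arg = arg + rng.normal(0.0, radar.phase_noise_std, x.n)
    return IQBaseband(
        i_values=radar.amp_i * np.cos(arg),
        q_values=radar.amp_q * np.sin(arg),
        fs=x.fs,
        t0=x.t0,
    )
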
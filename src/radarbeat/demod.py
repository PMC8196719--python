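"""Arctangent demodulation of quadrature radar baseband.

The chest displacement is recovered from the I/Q pair as

    x(t) = (lambda / 4*pi) * unwrap(atan2(B_Q, B_I)) - mean,

using the four-quadrant arctangent (robust at in-phase zero crossings and
immune to the single-channel null-point problem) followed by standard phase
unwrapping, so excursions beyond +-lambda/8 are tracked.  The standoff
distance d0 only contributes an arbitrary phase constant, hence the mean
removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .signals import IQBaseband, SampledSignal

__all__ = ["DemodResult", "ArctangentDemodulator", "arctangent_demodulate"]

# samples where both channels are this close to zero carry no phase
_ZERO_ATOL = 1e-12


@dataclass(frozen=True)
class DemodResult:
    """Demodulation output.

    Attributes
    ----------
    displacement : SampledSignal
        Mean-removed chest displacement in metres.
    raw_phase : numpy.ndarray
        Unwrapped phase series in radians (before scaling / mean removal).
    flagged : numpy.ndarray
        Indices of samples where both channels vanished; their phase was
        linearly interpolated from the neighbours.
    """

    displacement: SampledSignal
    raw_phase: np.ndarray
    flagged: np.ndarray


class ArctangentDemodulator(BaseEstimator, TransformerMixin):
    """Transformer mapping :class:`IQBaseband` to chest displacement.

    Parameters
    ----------
    wavelength : float
        Radar carrier wavelength in metres (12.5 mm for a 24 GHz sensor).

    Notes
    -----
    The stage is stateless; ``fit`` only validates parameters.  Channel
    imbalance and DC offsets are assumed absent (balanced-receiver
    assumption), so scaling both channels by a common positive factor
    leaves the output unchanged.
    """

    def __init__(self, wavelength: float = 0.0125):
        self.wavelength = wavelength

    def _validate(self) -> None:
        if not self.wavelength > 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")

    def fit(self, X: IQBaseband, y=None) -> "ArctangentDemodulator":
        self._validate()
        self.n_samples_in_ = X.n
        return self

    def transform(self, X: IQBaseband) -> SampledSignal:
        """Demodulate and return the mean-removed displacement."""
        return self.demodulate(X).displacement

    def demodulate(self, X: IQBaseband) -> DemodResult:
        """Full demodulation, keeping the raw phase and flagged samples."""
        self._validate()
        i, q = X.i_values, X.q_values
        dead = (np.abs(i) < _ZERO_ATOL) & (np.abs(q) < _ZERO_ATOL)
        phase = np.arctan2(q, i)
        flagged = np.flatnonzero(dead)
        if flagged.size:
            good = np.flatnonzero(~dead)
            if good.size == 0:
                raise ValueError("all samples have zero amplitude on both channels")
            phase[dead] = np.interp(flagged, good, phase[good])
        phase = np.unwrap(phase)
        disp = (self.wavelength / (4.0 * np.pi)) * phase
        disp = disp - disp.mean()
        return DemodResult(
            displacement=SampledSignal(disp, fs=X.fs, unit="m", t0=X.t0),
            raw_phase=phase,
            flagged=flagged,
        )


def arctangent_demodulate(iq: IQBaseband, wavelength: float = 0.0125) -> DemodResult:
    """Functional form of :class:`ArctangentDemodulator`."""
    return ArctangentDemodulator(wavelength=wavelength).demodulate(iq)
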